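"""Sorting strategies: cost arithmetic, DP oracle, reductions, assembly."""

import numpy as np
import pytest

from cinesort import indices, phantom, sorting
from cinesort.errors import ConfigError, SortingError

from conftest import SMALL_CONFIG


class TestWeightConfig:
    def test_default_thirds(self):
        w = sorting.WeightConfig()
        assert w.amplitude == pytest.approx(1 / 3)
        assert w.phase == pytest.approx(1 / 3)
        assert w.rma == pytest.approx(1 / 3)

    def test_from_ratio_normalises(self):
        w = sorting.WeightConfig.from_ratio(1, 1, 2)
        assert w.phase == pytest.approx(0.25)
        assert w.amplitude == pytest.approx(0.25)
        assert w.rma == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ConfigError):
            sorting.WeightConfig.from_ratio(0, 0, 0)

    def test_negative_rejected(self):
        with pytest.raises(ConfigError):
            sorting.WeightConfig.from_ratio(-1, 1, 1)


class TestTotalError:
    def test_all_ones(self):
        w = sorting.WeightConfig()
        assert sorting.total_error(1.0, 1.0, 1.0, w) == pytest.approx(1.0)

    def test_hand_value(self):
        """amp 0.3, phase 0.4, rma 0: sqrt((0.09 + 0.16)/3)."""
        w = sorting.WeightConfig()
        expected = np.sqrt((0.3**2 + 0.4**2) / 3.0)
        assert sorting.total_error(0.3, 0.4, 0.0, w) == pytest.approx(expected)
        assert expected == pytest.approx(0.28867513, abs=1e-6)

    def test_zero(self):
        assert sorting.total_error(0.0, 0.0, 0.0, sorting.WeightConfig()) == 0.0


class TestBinCentres:
    def test_ten_bins(self):
        np.testing.assert_allclose(sorting.bin_centres(10), np.arange(10) / 10.0)


TABLE_RATIOS = [
    (1, 1, 1), (0, 1, 1), (1, 0, 1), (1, 1, 2), (2, 1, 1),
    (1, 2, 1), (0, 1, 2), (0, 2, 1), (1, 0, 2), (2, 0, 1),
]


class TestViterbiOracle:
    @pytest.mark.parametrize("ratio", TABLE_RATIOS)
    def test_dp_equals_brute_force(self, ratio):
        """DP total cost equals the exhaustive minimum on 10 random instances
        per ratio (>= 100 instance-ratio pairs in total)."""
        w = sorting.WeightConfig.from_ratio(*ratio)
        for seed in range(10):
            r = np.random.default_rng(1000 * TABLE_RATIOS.index(ratio) + seed)
            n = int(r.integers(2, 7))
            m = int(r.integers(2, 5))
            amp = r.uniform(0, 1, (n, m))
            ph = r.uniform(0, 1, (n, m))
            rma = r.uniform(0, 1, (n - 1, m, m))
            c_dp, cost_dp = sorting.viterbi_chain(amp, ph, rma, w)
            c_bf, cost_bf = sorting.brute_force_chain(amp, ph, rma, w)
            assert cost_dp == pytest.approx(cost_bf, abs=1e-10)
            # recompute the DP selection's cost independently
            check = np.sqrt(w.amplitude * amp[0, c_dp[0]] ** 2
                            + w.phase * ph[0, c_dp[0]] ** 2)
            for i in range(1, n):
                rr = rma[i - 1, c_dp[i - 1], c_dp[i]]
                check += np.sqrt(w.amplitude * amp[i, c_dp[i]] ** 2
                                 + w.phase * ph[i, c_dp[i]] ** 2
                                 + w.rma * rr**2)
            assert check == pytest.approx(cost_bf, abs=1e-10)

    def test_brute_force_guard(self):
        amp = np.zeros((10, 6))
        ph = np.zeros((10, 6))
        rma = np.zeros((9, 6, 6))
        with pytest.raises(ConfigError):
            sorting.brute_force_chain(amp, ph, rma, sorting.WeightConfig())

    def test_rma_couples_choice(self):
        """A large boundary penalty flips the independent optimum."""
        w = sorting.WeightConfig.from_ratio(1, 0, 1)  # phase + rma only
        ph = np.array([[0.0, 0.5], [0.1, 0.2]])
        rma = np.zeros((1, 2, 2))
        rma[0, 0, 0] = 0.9          # candidate (0, 0) pairs badly
        amp = np.zeros_like(ph)
        choice, _ = sorting.viterbi_chain(amp, ph, rma, w)
        # independent optimum would be (0, 0); the coupling moves couch 1 to 1
        assert choice.tolist() == [0, 1]


class TestPhaseSort:
    def test_picks_nearest_phase(self, small_cine_study):
        st = small_cine_study
        inputs = sorting.prepare_inputs(st)
        sels = sorting.phase_sort(st, inputs=inputs)
        assert len(sels) == st.config.n_phase_bins
        for sel in sels:
            for i in range(st.n_couch):
                errs = np.array([
                    np.inf if not np.isfinite(inputs.phases[i, j])
                    else 2 * min(abs(inputs.phases[i, j] - sel.bin_centre) % 1.0,
                                 1 - abs(inputs.phases[i, j] - sel.bin_centre) % 1.0)
                    for j in range(st.m_per_couch)])
                assert errs[sel.choice[i]] == pytest.approx(errs.min())

    def test_tie_breaks_to_earlier_timestamp(self):
        """Equidistant candidates: the earlier (lower-index) one is chosen."""
        # candidates at phases 0.25 and 0.75 are equidistant from centre 0.0
        # (both distances exactly representable, so the tie is exact)
        inputs = sorting.SortingInputs(
            phases=np.array([[0.25, 0.75, 0.3]]),
            amp_err=np.zeros((1, 3)),
            ref=None, rpm_range=(0.0, 1.0))

        class _Cfg:
            n_phase_bins = 1

        class _Study:
            config = _Cfg()

        for _ in range(3):  # deterministic across repeated runs
            sels = sorting.phase_sort(_Study(), n_bins=1, inputs=inputs)
            # errors (0.5, 0.5, 0.6): tie between 0 and 1 -> lower index 0
            assert sels[0].choice[0] == 0

    def test_no_trace_raises(self, small_bh_study):
        with pytest.raises(SortingError):
            sorting.prepare_inputs(small_bh_study)


class TestReductionChain:
    """Criterion-style reductions on 20 seeded studies (small geometry)."""

    @pytest.fixture(scope="class")
    @classmethod
    def studies(cls):
        out = []
        for seed in range(20):
            p = phantom.BreathingParams(seed=seed)
            out.append(phantom.simulate_cine_scan(p, SMALL_CONFIG))
        return out

    def test_amp_w_a0_equals_phase(self, studies):
        w = sorting.WeightConfig.from_ratio(1, 0, 0)   # phase-only
        for st in studies:
            inputs = sorting.prepare_inputs(st)
            ph = sorting.phase_sort(st, inputs=inputs)
            aw = sorting.amp_w_sort(st, w=w, inputs=inputs)
            for s1, s2 in zip(ph, aw):
                assert s1.choice.tolist() == s2.choice.tolist()

    def test_amp_sim_w_c0_equals_amp_w(self, studies):
        w = sorting.WeightConfig.from_ratio(1, 1, 0)   # no rma term
        for st in studies:
            table = indices.build_index_table(st, index="n_rmsd")
            inputs = sorting.prepare_inputs(st)
            aw = sorting.amp_w_sort(st, w=w, inputs=inputs)
            asw = sorting.amp_sim_w_sort(st, table, w=w, inputs=inputs)
            for s1, s2 in zip(aw, asw):
                assert s1.choice.tolist() == s2.choice.tolist()


class TestAmpSimW:
    def test_table_shape_checked(self, small_cine_study):
        bad = indices.IndexTable(index="n_rmsd", values=np.zeros((1, 2, 2)))
        with pytest.raises(ConfigError):
            sorting.amp_sim_w_sort(small_cine_study, bad)

    def test_requires_table(self, small_cine_study):
        with pytest.raises(SortingError):
            sorting.amp_sim_w_sort(small_cine_study, None)

    def test_selection_provenance(self, small_cine_study):
        st = small_cine_study
        table = indices.build_index_table(st, index="n_rmsd")
        sels = sorting.amp_sim_w_sort(st, table)
        for sel in sels:
            assert sel.rma_err[0] == 0.0
            rma = table.error_values()
            for i in range(1, st.n_couch):
                expected = rma[i - 1, sel.choice[i - 1], sel.choice[i]]
                assert sel.rma_err[i] == pytest.approx(expected)

    def test_deterministic(self, small_cine_study):
        st = small_cine_study
        table = indices.build_index_table(st, index="n_rmsd")
        a = sorting.amp_sim_w_sort(st, table)
        b = sorting.amp_sim_w_sort(st, table)
        for s1, s2 in zip(a, b):
            assert s1.choice.tolist() == s2.choice.tolist()


class TestAssembleVolume:
    def test_shapes_and_provenance(self, small_cine_study):
        st = small_cine_study
        sels, vols = sorting.sort_study(st, "phase")
        assert len(vols) == st.config.n_phase_bins
        cfg = st.config
        for sel, vol in zip(sels, vols):
            assert vol.data.shape == (cfg.n_couch * cfg.slices_per_block,
                                      *cfg.pixel_grid)
            assert vol.n_couch == cfg.n_couch
            assert len(vol.provenance) == cfg.n_couch
            for i, p in enumerate(vol.provenance):
                assert p["couch_index"] == i
                assert p["candidate_index"] == int(sel.choice[i])
                j = p["candidate_index"]
                assert p["timestamp_s"] == pytest.approx(st.timestamps[i, j])

    def test_blocks_copied_verbatim(self, small_cine_study):
        st = small_cine_study
        sels, vols = sorting.sort_study(st, "phase")
        s = st.config.slices_per_block
        for sel, vol in zip(sels, vols):
            for i in range(st.n_couch):
                np.testing.assert_array_equal(
                    vol.data[i * s:(i + 1) * s], st.blocks[i, sel.choice[i]])

    def test_unknown_method(self, small_cine_study):
        with pytest.raises(ConfigError):
            sorting.sort_study(small_cine_study, "random")
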