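"""Candidate-block selection strategies for cine-mode 4DCT.

Three retrospective sorting strategies, each choosing one candidate block
per couch position for every reconstructed phase bin:

* **phase sorting** — the clinical default: minimise the phase error alone;
* **Amp-w** — amplitude-weighted phase sorting: minimise
  ``sqrt(A * amp_err^2 + B * phase_err^2)`` per couch position;
* **Amp-sim-w** — amplitude-weighted phase sorting with image similarity:
  minimise the summed per-couch total error
  ``sqrt(A * amp_err^2 + B * phase_err^2 + C * rma^2)`` where the RMA term
  of couch i is the boundary lookup-table entry for the chosen pair at
  boundary (i-1, i) (couch 1 has no RMA term).

Because the RMA term only couples neighbouring couch positions, the
m^n-candidate search decomposes over the couch chain and is solved exactly
by dynamic programming (Viterbi); an exhaustive search is provided as an
oracle for small instances. Ties are broken by lowest candidate index,
which — timestamps being increasing within a couch position — is also the
earliest acquisition.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from . import resp
from .errors import ConfigError, SortingError
from .indices import IndexTable

__all__ = [
    "WeightConfig",
    "Selection",
    "SortedVolume",
    "total_error",
    "bin_centres",
    "phase_sort",
    "amp_w_sort",
    "amp_sim_w_sort",
    "viterbi_chain",
    "brute_force_chain",
    "assemble_volume",
    "sort_study",
]


@dataclass(frozen=True)
class WeightConfig:
    """Weights of the three cost terms (amplitude, phase, RMA).

    Defaults to the equal weighting A = B = C = 1/3. ``from_ratio`` accepts
    the ratio convention phase : amplitude : rma and renormalises to sum 1.
    """

    amplitude: float = 1.0 / 3.0   # A
    phase: float = 1.0 / 3.0       # B
    rma: float = 1.0 / 3.0         # C

    def __post_init__(self) -> None:
        for name in ("amplitude", "phase", "rma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"weight {name}={v} outside [0, 1]")

    @classmethod
    def from_ratio(cls, phase: float, amplitude: float, rma: float) -> "WeightConfig":
        total = phase + amplitude + rma
        if total <= 0:
            raise ConfigError("at least one weight ratio must be positive")
        return cls(amplitude=amplitude / total, phase=phase / total, rma=rma / total)


def total_error(amp, phase, rma, w: WeightConfig | None = None):
    """Per-image total error: root of the weighted sum of squared terms."""
    if w is None:
        w = WeightConfig()
    amp = np.asarray(amp, dtype=float)
    phase = np.asarray(phase, dtype=float)
    rma = np.asarray(rma, dtype=float)
    return np.sqrt(w.amplitude * amp**2 + w.phase * phase**2 + w.rma * rma**2)


def bin_centres(n_bins: int) -> np.ndarray:
    """Phase-bin centres k / n_bins, k = 0..n_bins-1 (0 = end inhale)."""
    return np.arange(n_bins) / n_bins


@dataclass
class Selection:
    """One candidate choice per couch position for a single phase bin."""

    bin_index: int
    bin_centre: float
    method: str
    choice: np.ndarray                     # (n_couch,) candidate indices
    total_cost: float
    amp_err: np.ndarray                    # (n_couch,) chosen amplitude errors
    phase_err: np.ndarray                  # (n_couch,) chosen phase errors
    rma_err: np.ndarray | None = None      # (n_couch,) 0 for couch 0


@dataclass
class SortedVolume:
    """Assembled per-bin volume with selection provenance."""

    data: np.ndarray                       # (n_couch * slices_per_block, rows, cols)
    z_origin: float
    slice_thickness: float
    slices_per_block: int
    bin_index: int
    bin_centre: float
    method: str
    provenance: list = field(default_factory=list)

    @property
    def n_couch(self) -> int:
        return self.data.shape[0] // self.slices_per_block


@dataclass
class SortingInputs:
    """Per-candidate phase and amplitude errors shared by every strategy."""

    phases: np.ndarray        # (n, m), NaN where phase undefined
    amp_err: np.ndarray       # (n, m) normalised amplitude errors
    ref: resp.RepresentativeSignal
    rpm_range: tuple[float, float]


def prepare_inputs(study, ref: resp.RepresentativeSignal | None = None,
                   K: int = 2) -> SortingInputs:
    """Phase / amplitude errors of every candidate block of a study.

    Fits the representative signal on the pooled acquisition points unless
    one is supplied.
    """
    if study.trace is None:
        raise SortingError("study has no surrogate trace: cannot sort")
    phases, amps = resp.acquisition_phase_amplitude(study.trace,
                                                    study.timestamps.ravel())
    phases = phases.reshape(study.timestamps.shape)
    amps = amps.reshape(study.timestamps.shape)
    valid = np.isfinite(phases)
    if ref is None:
        ref = resp.fit_representative(phases[valid], amps[valid], K=K)
    rpm_min = float(amps[valid].min())
    rpm_max = float(amps[valid].max())
    amp_err = np.full(amps.shape, np.nan)
    amp_err[valid] = resp.amplitude_error(amps[valid], phases[valid], ref,
                                          rpm_min, rpm_max)
    return SortingInputs(phases=phases, amp_err=amp_err, ref=ref,
                         rpm_range=(rpm_min, rpm_max))


def _per_bin_errors(inputs: SortingInputs, centre: float):
    """Amplitude/phase error arrays plus the invalid-candidate mask.

    Candidates without an assigned phase get zero error terms here; callers
    must mask their cost to infinity using ``invalid`` (keeping zeros avoids
    0 * inf = NaN when a weight is zero).
    """
    invalid = ~np.isfinite(inputs.phases)
    ph_err = resp.phase_error(np.where(invalid, 0.0, inputs.phases), centre)
    amp_err = np.where(invalid, 0.0, inputs.amp_err)
    ph_err[invalid] = 0.0
    return amp_err, ph_err, invalid


def _check_feasible(cost: np.ndarray, method: str):
    bad = [int(i) for i in range(cost.shape[0]) if not np.isfinite(cost[i]).any()]
    if bad:
        raise SortingError(
            f"{method}: no phase-assigned candidate at couch position(s) {bad}"
        )


def _independent_sort(study, inputs: SortingInputs, w: WeightConfig,
                      n_bins: int, method: str,
                      use_amp: bool) -> list[Selection]:
    sels = []
    for b, centre in enumerate(bin_centres(n_bins)):
        amp_err, ph_err, invalid = _per_bin_errors(inputs, centre)
        if use_amp:
            cost = np.sqrt(w.amplitude * amp_err**2 + w.phase * ph_err**2)
        else:
            cost = ph_err.copy()
        cost[invalid] = np.inf
        _check_feasible(cost, method)
        choice = np.argmin(cost, axis=1)   # first minimum = lowest index
        rows = np.arange(cost.shape[0])
        ae = amp_err[rows, choice]
        pe = ph_err[rows, choice]
        sels.append(Selection(
            bin_index=b, bin_centre=float(centre), method=method,
            choice=choice, total_cost=float(cost[rows, choice].sum()),
            amp_err=ae, phase_err=pe))
    return sels


def phase_sort(study, n_bins: int | None = None,
               inputs: SortingInputs | None = None, K: int = 2) -> list[Selection]:
    """Clinical default: per couch position, the candidate with minimal phase error."""
    if n_bins is None:
        n_bins = study.config.n_phase_bins
    if inputs is None:
        inputs = prepare_inputs(study, K=K)
    return _independent_sort(study, inputs, WeightConfig(), n_bins,
                             "phase", use_amp=False)


def amp_w_sort(study, ref: resp.RepresentativeSignal | None = None,
               w: WeightConfig | None = None, n_bins: int | None = None,
               inputs: SortingInputs | None = None, K: int = 2) -> list[Selection]:
    """Amplitude-weighted phase sorting (no image-similarity term)."""
    if n_bins is None:
        n_bins = study.config.n_phase_bins
    if w is None:
        w = WeightConfig()
    if inputs is None:
        inputs = prepare_inputs(study, ref=ref, K=K)
    return _independent_sort(study, inputs, w, n_bins, "amp_w", use_amp=True)


def viterbi_chain(amp_err: np.ndarray, ph_err: np.ndarray,
                  rma: np.ndarray, w: WeightConfig,
                  invalid: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Exact minimiser of the chain-decomposable total cost.

    ``amp_err``/``ph_err`` are (n, m); ``rma`` is (n-1, m, m) in error form.
    Returns (choice, cost) where cost = sum_i sqrt(A a_i^2 + B p_i^2 +
    C r_i^2), r_0 = 0 and r_i = rma[i-1, choice[i-1], choice[i]].
    ``invalid`` marks candidates excluded from selection.
    """
    n, m = amp_err.shape
    node = w.amplitude * amp_err**2 + w.phase * ph_err**2
    if invalid is not None:
        node = np.where(invalid, np.inf, node)
    dp = np.sqrt(node[0])
    back = np.zeros((n, m), dtype=int)
    for i in range(1, n):
        # candidate cost matrix (j -> k)
        step = np.sqrt(node[i][None, :] + w.rma * rma[i - 1] ** 2)
        cand = dp[:, None] + step
        back[i] = np.argmin(cand, axis=0)
        dp = np.min(cand, axis=0)
    if not np.isfinite(dp).any():
        raise SortingError("no feasible selection for this phase bin")
    choice = np.zeros(n, dtype=int)
    choice[-1] = int(np.argmin(dp))
    for i in range(n - 1, 0, -1):
        choice[i - 1] = back[i, choice[i]]
    return choice, float(dp[choice[-1]])


def brute_force_chain(amp_err: np.ndarray, ph_err: np.ndarray,
                      rma: np.ndarray, w: WeightConfig) -> tuple[np.ndarray, float]:
    """Exhaustive m^n search over all selections (oracle; small instances only)."""
    n, m = amp_err.shape
    if m**n > 2_000_000:
        raise ConfigError("instance too large for exhaustive search")
    best_cost = np.inf
    best = None
    for sel in itertools.product(range(m), repeat=n):
        cost = np.sqrt(w.amplitude * amp_err[0, sel[0]] ** 2
                       + w.phase * ph_err[0, sel[0]] ** 2)
        for i in range(1, n):
            r = rma[i - 1, sel[i - 1], sel[i]]
            cost += np.sqrt(w.amplitude * amp_err[i, sel[i]] ** 2
                            + w.phase * ph_err[i, sel[i]] ** 2
                            + w.rma * r**2)
        if cost < best_cost:
            best_cost = cost
            best = sel
    if best is None or not np.isfinite(best_cost):
        raise SortingError("no feasible selection")
    return np.asarray(best), float(best_cost)


def amp_sim_w_sort(study, table: IndexTable,
                   ref: resp.RepresentativeSignal | None = None,
                   w: WeightConfig | None = None, n_bins: int | None = None,
                   inputs: SortingInputs | None = None, K: int = 2) -> list[Selection]:
    """Amplitude-weighted phase sorting with image similarity (the full cost)."""
    if table is None:
        raise SortingError("amp_sim_w requires an index lookup table")
    if n_bins is None:
        n_bins = study.config.n_phase_bins
    if w is None:
        w = WeightConfig()
    if inputs is None:
        inputs = prepare_inputs(study, ref=ref, K=K)
    n, m = inputs.phases.shape
    if table.values.shape != (n - 1, m, m):
        raise ConfigError(
            f"index table shape {table.values.shape} does not match study ({n - 1}, {m}, {m})"
        )
    rma = table.error_values()
    sels = []
    for b, centre in enumerate(bin_centres(n_bins)):
        amp_err, ph_err, invalid = _per_bin_errors(inputs, centre)
        feas = np.sqrt(w.amplitude * amp_err**2 + w.phase * ph_err**2)
        feas[invalid] = np.inf
        _check_feasible(feas, "amp_sim_w")
        choice, cost = viterbi_chain(amp_err, ph_err, rma, w, invalid=invalid)
        rows = np.arange(n)
        rma_chosen = np.zeros(n)
        rma_chosen[1:] = rma[np.arange(n - 1), choice[:-1], choice[1:]]
        sels.append(Selection(
            bin_index=b, bin_centre=float(centre), method="amp_sim_w",
            choice=choice, total_cost=cost,
            amp_err=amp_err[rows, choice], phase_err=ph_err[rows, choice],
            rma_err=rma_chosen))
    return sels


def assemble_volume(study, selection: Selection) -> SortedVolume:
    """Concatenate the chosen blocks in couch order into one volume.

    Validates z-contiguity and records full provenance per couch position.
    """
    cfg = study.config
    expected = study.couch_z_origins[0] + np.arange(study.n_couch) * cfg.block_extent
    if not np.allclose(study.couch_z_origins, expected):
        raise ConfigError("couch positions are not contiguous in z")
    chosen = [study.blocks[i, selection.choice[i]] for i in range(study.n_couch)]
    data = np.concatenate(chosen, axis=0)
    provenance = []
    for i in range(study.n_couch):
        j = int(selection.choice[i])
        provenance.append({
            "couch_index": i,
            "candidate_index": j,
            "timestamp_s": float(study.timestamps[i, j]),
            "z_origin_mm": float(study.couch_z_origins[i]),
            "amp_err": float(selection.amp_err[i]),
            "phase_err": float(selection.phase_err[i]),
            "rma_err": (float(selection.rma_err[i])
                        if selection.rma_err is not None else None),
        })
    return SortedVolume(data=data, z_origin=float(study.couch_z_origins[0]),
                        slice_thickness=cfg.slice_thickness,
                        slices_per_block=cfg.slices_per_block,
                        bin_index=selection.bin_index,
                        bin_centre=selection.bin_centre,
                        method=selection.method, provenance=provenance)


def sort_study(study, method: str, table: IndexTable | None = None,
               w: WeightConfig | None = None, n_bins: int | None = None,
               K: int = 2) -> tuple[list[Selection], list[SortedVolume]]:
    """Run one strategy end to end and assemble the per-bin volumes."""
    inputs = prepare_inputs(study, K=K)
    if method == "phase":
        sels = phase_sort(study, n_bins=n_bins, inputs=inputs)
    elif method == "amp_w":
        sels = amp_w_sort(study, w=w, n_bins=n_bins, inputs=inputs)
    elif method == "amp_sim_w":
        sels = amp_sim_w_sort(study, table, w=w, n_bins=n_bins, inputs=inputs)
    else:
        raise ConfigError(f"unknown sorting method {method!r}")
    volumes = [assemble_volume(study, s) for s in sels]
    return sels, volumes


def write_provenance(volume: SortedVolume, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "bin_index": volume.bin_index,
            "bin_centre": volume.bin_centre,
            "method": volume.method,
            "z_origin_mm": volume.z_origin,
            "slice_thickness_mm": volume.slice_thickness,
            "slices_per_block": volume.slices_per_block,
            "selections": volume.provenance,
        }, fh, indent=2, sort_keys=True)
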