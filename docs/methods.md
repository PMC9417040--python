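# Methods

This document defines the models and estimators implemented by `cinesort`,
lists every tunable parameter with its unit, default and rationale, and
records the reasoning behind the design choices that were genuinely open.

## 1. Acquisition model

Cine-mode 4DCT acquires, at each of `n_couch` couch positions, `m_per_couch`
repetitions of a block of `slices_per_block` contiguous slices while the
patient breathes freely. A 3D volume for a given breathing phase is assembled
retrospectively by choosing exactly one repetition per couch position and
stacking the chosen blocks in couch order. Because adjacent couch positions
are scanned at different times, a poor pairing leaves an anatomic step — a
residual motion artifact (RMA) — at the inter-block boundary.

`AcquisitionConfig` defaults (mirroring a common clinical cine protocol):

| parameter          | default  | unit | rationale |
|--------------------|----------|------|-----------|
| `n_couch`          | 10       | —    | thorax coverage at 2 cm per couch position |
| `m_per_couch`      | 15       | —    | 4.5 s window / 0.3 s cine interval |
| `slices_per_block` | 8        | —    | 8-slice detector |
| `slice_thickness`  | 2.5      | mm   | standard cine reconstruction |
| `cine_interval`    | 0.3      | s    | gantry rotation + reconstruction stride |
| `cine_duration`    | 4.5      | s    | one breathing cycle + margin per couch position |
| `pixel_grid`       | (64, 64) | px   | enough in-plane structure for the indices at tractable cost |
| `n_phase_bins`     | 10       | —    | standard 10-phase 4DCT reconstruction |

## 2. Breathing model and phantom

### 2.1 Surrogate and internal motion

The surrogate (an RPM-style external marker trace) is a quasi-periodic
oscillation `0.5 * A_k * (1 + cos)` built cycle by cycle:

* cycle periods: `mean_period` + Gaussian jitter (`period_jitter_sd`);
* cycle depths `A_k`: a lognormal random walk with step `amplitude_drift_sd`
  around `mean_amplitude`;
* a linear baseline drift (`baseline_drift_rate`) and white sensor noise
  (`noise_sd`).

Internal (organ) motion is a smooth mixture of the (optionally lagged)
surrogate with an independent smooth process; the mixing weight
`surrogate_internal_correlation` ∈ [0, 1] controls how faithfully the
external marker tracks the anatomy (1 = perfect, 0 = uninformative). The
internal channel, mapped affinely to ±`motion_mm` (default 8 mm) of
diaphragm displacement, is the ground truth stored with every simulated
study.

`BreathingParams` defaults: `mean_period` 4.0 s, `period_jitter_sd` 0.4 s,
`mean_amplitude` 10 (arbitrary units), `amplitude_drift_sd` 0.15,
`baseline_drift_rate` 0.02 /s, `noise_sd` 0.2, correlation 0.9, lag 0 s —
a mildly irregular, well-tracked breather.

### 2.2 Torso phantom

The phantom is an analytic attenuation field over a fixed 200 mm z support:
an elliptical body with partial-volume soft edges, two z-cylindrical lungs,
a diaphragm dome (smooth tanh profile) whose apex translates with the
internal motion signal, a Gaussian lung nodule riding on the dome, and
traveling-wave soft-tissue/parenchyma textures whose in-plane phase advances
with z so that genuinely adjacent slices differ in plane. Slices are
rendered by averaging sub-samples across the slice thickness (partial
volume) and adding CT noise.

What the phantom *does* emulate: superior–inferior respiratory displacement
of the diaphragm and a lesion, realistic HU ranges, partial-volume blur,
slice-to-slice in-plane decorrelation, imperfect surrogate–anatomy coupling.
What it does *not* emulate: in-plane (AP/LR) motion and rotation, hysteresis,
cardiac motion, scanner-specific reconstruction artifacts, scatter/beam
hardening. These omissions bias all strategies equally and do not affect the
comparative claims tested against it.

### 2.3 Acquisition simulation

The trace is padded by two mean periods on both ends so every CT acquisition
instant lies strictly inside the detected peak range. Each repetition at
couch position `i` is rendered at its acquisition instant
`t = pad + i * cine_duration + j * cine_interval` from the displaced
phantom. A breath-hold (BH) study freezes the phantom at mid displacement:
its boundaries carry *only* anatomy and noise, making it the artifact-free
reference (measured boundary means on the default BH study: N-NCC 0.99919,
N-DCC 0.99986, N-RMSD 0.0225).

## 3. Respiratory signal analysis

**Peak detection.** End-inhale maxima via `scipy.signal.find_peaks` with a
1 s minimum separation and a prominence floor of 5 × a robust noise estimate
(1.4826 × median absolute successive difference / √2). The noise level —
not the session amplitude range — is the right reference scale: noise-ripple
prominence scales with sensor noise while genuine cycles scale with
breathing depth, so a range-relative threshold silently drops real cycles
whenever depth drifts strongly (one deep late cycle inflates the range and
erases early shallow peaks), whereas the noise-relative floor keeps every
cycle resolvable above the noise.

**Phase.** Retrospective phase assignment divides each peak-to-peak
interval linearly into [0, 1); phase is undefined (NaN) outside the first
and last peak. Phase-bin centres are `k / n_bins` with 0 = end inhale.

**Representative signal.** A truncated sinusoidal series in phase,
`a0 + Σ_k a_k cos(2πkp) + b_k sin(2πkp)`, least-squares fitted to the
(phase, amplitude) cloud of the study's CT acquisition points. `K = 2` by
default: `K = 1` cannot represent the inhale/exhale asymmetry of real
breathing, while higher orders begin fitting cycle-to-cycle irregularity —
the very deviation the amplitude error is supposed to measure.

**Amplitude error** of an acquisition point `x`:
`|RPM(x) − REF(phase(x))| / (max RPM − min RPM)`, the reference evaluated at
the point's *own* phase and the range taken over the acquisition-point
population. It is a regularity penalty — how far this repetition's depth
sits from the typical depth at its phase — clipped to [0, 1] (clipping is
logged).

**Phase error**: the circular distance `min(|p − c|, 1 − |p − c|)` doubled,
so the theoretical maximum (antipodal phases, distance 0.5) maps to 1. This
puts the phase term on the same [0, 1] scale as the amplitude and RMA terms;
without the factor 2 the phase term would be implicitly half-weighted.

## 4. RMA indices

All indices are computed between the two facing slices of adjacent couch
blocks, inside the union of the two slices' body masks (threshold −400 HU,
largest connected component, holes filled).

* **NCC** — Pearson correlation of in-mask pixels.
* **RMSD** — root-mean-square difference after min–max rescaling each slice
  over the union mask (removes global level/window differences).
* **DCC** — min/max of the two in-mask attenuation sums after adding
  1000 HU (so air ≈ 0 and the sums are positive); 1 means equal in-mask
  "mass".

**Normalised variants** divide the boundary value by the mean of the two
within-block values adjacent to the boundary (the pair just inside each
block), cancelling the anatomy-dependent baseline: a boundary is only
flagged as artifactual if it is worse than the natural slice-to-slice
change of the local anatomy. Ideal values: N-NCC = N-DCC = 1, N-RMSD = 0.

*N-RMSD folding.* The raw N-RMSD ratio can fall below 1 when the paired
slices are *more* similar than genuine neighbours — anatomy duplicated
across the boundary, which is also an artifact (a missing-tissue /
overlapping-structure error). N-RMSD is therefore stored as |ratio − 1|, so
both too-different and too-similar boundaries score positive. On the
motion-free reference study the folded value is ≈ 0.02, confirming the ideal
sits at 0.

**Lookup table.** `build_index_table` evaluates the chosen index for *all*
`m²` candidate pairings at each of the `n − 1` boundaries — an
`(n−1) × m × m` table, i.e. `m² × (n−1)` entries (15² × 9 = 2025 at the
default geometry). Within-block baselines and body masks are cached, so the
table costs one mask per slice and one baseline per block side.
`error_values()` maps the table to the common error form (similarity indices
→ `1 − min(v, 1)`, N-RMSD clipped to [0, 1]); entries whose mask is empty
become NaN in the table and 1.0 (worst case) in error form.

## 5. Sorting strategies

For each phase bin with centre `c`, each couch position contributes one
candidate per repetition with amplitude error `a`, phase error `p` and —
for the coupled strategy — boundary error `r` against the previous couch
position's chosen candidate. The per-couch cost is

```
E = sqrt(A·a² + B·p² + C·r²),   A = B = C = 1/3 by default,
```

and a volume's objective is the **sum** of its per-couch costs. Candidates
with undefined phase are excluded; a couch position with no valid candidate
raises `SortingError` rather than silently degrading.

* `phase` — per couch position, the candidate nearest the bin centre
  (A = C = 0). Ties break to the earlier repetition (lowest index),
  deterministically.
* `amp_w` — per couch position, minimises `sqrt(A·a² + B·p²)` (C = 0).
* `amp_sim_w` — the full coupled objective. Because `r` depends on the
  *previous* couch position's choice, the objective is a chain with pairwise
  couplings and is minimised **exactly** by dynamic programming over couch
  positions (a Viterbi pass, `O(n·m²)`); `brute_force_chain` enumerates all
  `mⁿ` assemblies (guarded to ≤ 2·10⁶) and verifies the DP optimum in tests.

Setting C = 0 reduces `amp_sim_w` to `amp_w`; additionally setting A = 0
reduces `amp_w` to `phase` — these reductions are tested selection-for-
selection and anchor all three strategies to one objective family.

*Sum vs max aggregation.* The sum was chosen over the max (bottleneck)
objective because every boundary of the assembled volume is clinically
visible: trading three slightly worse boundaries to fix the single worst one
(what a bottleneck objective does) does not match how volumes are read. The
sum is also strictly ordered by the reductions above, and its DP is the
standard Viterbi recursion.

Weight ratios are specified as `phase : amplitude : rma` triples and
normalised to sum to 1 (`WeightConfig.from_ratio`); the evaluation sweep
covers the ten ratios (1,1,1), (0,1,1), (1,0,1), (1,1,2), (2,1,1), (1,2,1),
(0,1,2), (0,2,1), (1,0,2), (2,0,1).

## 6. Evaluation

* **Quality report**: every boundary of every sorted volume scored with the
  normalised indices inside a rectangular mid-body ROI (default width
  200 px, clipped to the image); mean ± sd per method and index, plus the
  relative improvement over the `phase` baseline.
* **Pearson r** (`scipy.stats.pearsonr`) with the conventional strength
  bands for relating index values to ground-truth displacement mismatch.
* **Weighted kappa** (`sklearn.metrics.cohen_kappa_score`) with **linear**
  weights for inter-method agreement on ordinal quality categories: linear
  weights penalise category distance proportionally, which matches an
  ordinal "quality grade" scale; quadratic weights would nearly ignore
  one-step disagreements, the most common kind here. Identical ratings
  return exactly 1.0.

## 7. Irregular-breathing test conditions

The comparative tests (amplitude weighting vs phase sorting, similarity
weighting vs amplitude weighting) need breathing irregular enough for the
extra cost terms to have signal, and a cine window long enough to contain
an alternative cycle to select from:

* `mean_period = 3.0 s`: the protocol's guarantee is ≥ 1.25 cycles per
  couch position (cine = cycle + 1 s). With the 4.5 s cine window fixed by
  the acquisition model, only a period ≤ 3.5 s reproduces that coverage; at
  the default 4 s period the window holds ~1.05 cycles, there is no
  alternative cycle, and the strategies cannot differ except by chance.
* `period_jitter_sd = 0.3 s` (10 % of the period) and
  `amplitude_drift_sd = 0.4`: a markedly irregular breather, the regime the
  amplitude-weighted strategies exist for. Measured over 20 seeds at
  surrogate correlation 0.9, amplitude weighting improves the mean boundary
  N-RMSD in 16/20 studies; at correlation 0.5 similarity weighting improves
  on amplitude weighting in 10/10 studies with large margins (e.g. 0.054 vs
  0.251), because a poorly tracking surrogate misleads the amplitude term
  while the image-based similarity term measures the boundary directly.

## 8. Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical studies, tables and volumes.
* Slices are rendered in float64 and stored unquantised; the indices are
  scale-sensitive and HU quantisation would add a needless noise floor.
* Ties in per-couch minimisation break to the lowest candidate index
  (`np.argmin` first-minimum semantics) — deterministic and documented.
* Studies round-trip through NIfTI (blocks, volumes) + JSON (config,
  provenance, schema version) + CSV (trace, tables) with bit-exact
  equality tested; readers validate schema version, required keys and
  shapes, and reject unknown configuration keys.
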