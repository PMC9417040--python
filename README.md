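# cinesort

Residual-motion-artifact (RMA) quantification and retrospective slice
sorting for cine-mode 4DCT.

In cine-mode 4DCT the scanner acquires many image repetitions at each couch
position and a 3D volume per breathing phase is assembled retrospectively by
picking one repetition per couch position. A bad pick shows up as an anatomic
discontinuity — a *residual motion artifact* — at the boundary between
adjacent couch positions. This package provides:

* **Quantitative RMA indices** computed between the facing slices of adjacent
  blocks inside an automatic body mask: normalised cross correlation (NCC),
  root-mean-square difference on min–max rescaled images (RMSD) and the
  density-change coefficient (DCC, the ratio of in-mask attenuation sums).
  Each index also has a *normalised* variant (N-NCC, N-RMSD, N-DCC) that
  divides the boundary value by the mean of the two within-block values next
  to it, cancelling the anatomy-dependent baseline. Ideal values are 1 for
  N-NCC/N-DCC and 0 for N-RMSD (stored as |ratio − 1|).
* **Three sorting strategies**: classic nearest-phase sorting (`phase`),
  amplitude-weighted sorting (`amp_w`) that adds a normalised amplitude-error
  term measured against a fitted representative breathing signal, and
  amplitude-similarity-weighted sorting (`amp_sim_w`) that additionally
  couples adjacent couch positions through a precomputed m²×(n−1) lookup
  table of pairwise boundary indices. The coupled objective is minimised
  *exactly* by dynamic programming over the couch-position chain (a Viterbi
  pass), with a brute-force oracle for verification.
* **A synthetic breathing-torso phantom** that renders cine and breath-hold
  studies with a configurable quasi-periodic breathing model (period jitter,
  depth drift, baseline drift, imperfect surrogate–internal correlation), so
  every claim in the test suite is checked against known ground truth.
* **Evaluation utilities**: per-boundary quality reports, weight-ratio
  sweeps, Pearson correlation and linearly weighted kappa with the usual
  agreement bands.

## Quick start (CLI)

```sh
cat > breathing.yaml <<'YAML'
breathing:
  seed: 7
  mean_period: 3.0
  period_jitter_sd: 0.3
  amplitude_drift_sd: 0.4
YAML

cinesort simulate --config breathing.yaml --out study/
cinesort index    --study study/ --index n_rmsd --out nrmsd.csv
cinesort sort     --study study/ --method phase     --out sorted_phase/
cinesort sort     --study study/ --method amp_sim_w --index n_rmsd --out sorted_sim/
cinesort evaluate --sorted sorted_phase/ --sorted sorted_sim/ --out report.csv
```

Output of the final command for this exact configuration:

```
   method  index     mean      std  n  relative_improvement
amp_sim_w  n_ncc 0.999875 0.001897 90              0.001819
amp_sim_w n_rmsd 0.052513 0.062291 90              0.631291
    phase  n_ncc 1.001698 0.005508 90              0.000000
    phase n_rmsd 0.142424 0.196156 90              0.000000
```

i.e. for this markedly irregular breather, similarity-weighted sorting cuts
the mean boundary N-RMSD from 0.142 to 0.053 (a 63 % improvement) relative
to phase sorting. `cinesort sweep` evaluates a grid of weight ratios, and
`cinesort simulate --mode bh` produces a motion-free breath-hold study
(useful as the artifact-free reference: its boundary indices sit at their
ideal values, e.g. mean N-DCC ≈ 0.9999).

## Quick start (API)

```python
from cinesort import evaluate, indices, phantom, sorting

params = phantom.BreathingParams(seed=7, mean_period=3.0,
                                 period_jitter_sd=0.3, amplitude_drift_sd=0.4)
study = phantom.simulate_cine_scan(params, phantom.AcquisitionConfig())

table = indices.build_index_table(study, index="n_rmsd")
selections, volumes = sorting.sort_study(study, "amp_sim_w", table=table)
frame, summary = evaluate.quality_report({"amp_sim_w": volumes})
print(summary)
```

Studies and sorted volumes round-trip through NIfTI + JSON + CSV bundles via
`cinesort.studyio` (`write_study` / `read_study`, `write_volume` /
`read_volume`); all randomness is seeded and every artifact records its
provenance (chosen repetition, timestamp, phase, per-term errors).

## Documentation

See `docs/methods.md` for the model and estimator definitions, parameter
tables with units and defaults, the design rationale for the open choices
(cost aggregation, phase-error normalisation, N-RMSD folding, kappa
weights), and what the phantom does and does not emulate.
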