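# ecogmark

Inter-ictal **intra-operative electrocorticography (ioECoG) biomarkers** for
localizing epileptogenic tissue, evaluated against a resection-outcome ground
truth, together with a synthetic cohort generator that makes the whole
framework testable end-to-end.

## The problem

During epilepsy surgery, recordings from subdural grids and strips are made
on the cortex before and after the resection. If a patient is seizure-free
**off medication** one year later ("cured"), whatever tissue the surgeon left
behind evidently cannot trigger seizures — so biomarker values measured on
the post-resection recordings of cured patients bound the range of *normal*
tissue. A biomarker localizes epileptogenic tissue in a patient when at least
one pre-resection value, on a channel that was eventually resected, exceeds
that normal-tissue reference.

`ecogmark` implements this framework for seven inter-ictal signal
biomarkers computed on one artefact-free minute per electrode arrangement
("situation"), sampled at 2048 Hz, split into 5 s segments that are
detrended, demeaned and z-scored, under a bipolar (grid rows + columns,
strip chains) or common-average montage:

| biomarker | type | definition (per derived channel) |
|---|---|---|
| ARR | univariate | robust modulation of windowed AR(2) residual SDs: median(\|s − med s\|)/med s, 40-sample windows, 50 % overlap |
| PAC | univariate | amplitude-normalised mean vector length \|⟨a·e^{iφ}⟩\|/⟨a⟩ between theta (3–4 Hz) phase and high-gamma (80–500 Hz) amplitude |
| PLV | bivariate | \|⟨e^{i(φ_x−φ_y)}⟩\| in the gamma band (30–80 Hz) |
| PLI | bivariate | \|⟨sign sin(φ_x−φ_y)⟩\| in the gamma band |
| h² | bivariate, directed | nonlinear correlation via equal-count binned piecewise-linear regression, maximised over delays ±0.0332 s in steps of 0.0083 s |
| GC | multivariate, directed | pairwise-conditional time-domain Granger causality, ln(σ²_reduced/σ²_full), VAR pooled over segments, AIC order selection |
| sdDTF | multivariate, directed | short-time direct directed transfer function: full-frequency-normalised DTF × partial coherence from a per-segment VAR(30), averaged over 30–80 Hz |

Connectivity matrices reduce to per-channel (out-)strengths; values are
averaged over the 12 segments (GC: one pooled fit). Group-level effects use
a one-sided two-sample Kolmogorov–Smirnov test ("pre-resection resected
values stochastically larger than post-resection values", α = 0.01,
uncorrected); patient-level detection uses the strict maximum threshold
described above, per biomarker and cumulatively (any biomarker), with
optional re-thresholding within temporal / extra-temporal subgroups and a
mesiotemporal-versus-neocortical contrast.

Since clinical ioECoG is not redistributable, the package ships a synthetic
cohort generator (1/f² background + 10 Hz rhythm; epileptogenic channels
carry tunable phase-amplitude coupling, sharp transients, and lagged
coupling) with full ground truth, so every stage — file layout, montage,
estimators, thresholds, detection — is exercised and validated end to end.

## Worked example

```bash
ecogmark simulate demo_cohort --seed 7 --patients 12 --config small.yaml
ecogmark run demo_cohort --out demo_out
```

With a strong-signature 12-patient cohort (2×3 grid + 1×6 strip, 20 s
situations — `small.yaml` holding those values) this prints:

```
[all] cumulative detection: 12/12 patients
[T] cumulative detection: 6/6 patients
[E] cumulative detection: 6/6 patients
outputs in demo_out
```

meaning every patient had, for at least one biomarker, a pre-resection
resected channel above that biomarker's cured-patient reference, in the
whole-cohort and in both subgroup re-thresholdings. `demo_out/` contains
`biomarkers.tsv` (one value per patient × situation × derived channel ×
biomarker), `thresholds.json`, `detections.tsv` (per patient × biomarker:
flag, number of channels above, argmax channel) and `group_stats.json`
(pooled and max-per-patient KS statistics, detection counts per scope).

The same can be driven from Python:

```python
from ecogmark import CohortConfig, RunConfig, generate_cohort, read_cohort
from ecogmark.pipeline import compute_biomarker_table
from ecogmark.evaluate import evaluate_cohort

cfg = CohortConfig(n_patients=12, duration=20.0, grid_shape=(2, 3), seed=7)
generate_cohort(cfg, "demo_cohort")
cohort = read_cohort("demo_cohort")
table = compute_biomarker_table(cohort, RunConfig())
report = evaluate_cohort(table, cohort.patients)["all"]
print(report.n_cumulative_detected, "/", report.n_patients)
```

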