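# Methods

## Recording model and preprocessing

A cohort is a set of patients, each contributing one or more pre-resection
and post-resection *situations*: multichannel recordings from a subdural
grid (default 4×5) and strips (default 1×6) at 2048 Hz. All patients are
assumed Engel 1A one year after surgery ("improved"); the subset that also
stopped medication is "cured". Analysis uses one artefact-free minute per
situation, taken as the last clean window (`select_minute`) to stay clear of
anaesthesia-induction effects.

Channels with visually marked noise are excluded before montage
construction. The bipolar montage differences adjacent electrodes along grid
rows *and* columns (both orientations retained so that sources of either
orientation under the array are represented) and along strips. A bipolar
channel is labelled `resected` only when both parents were resected,
`not_resected` when neither was, and `cut` when the pair straddles the
resection border; `cut` and `unknown` channels never enter the evaluation
pools. A derived channel is mesiotemporal only when all parents are. The
common-average montage subtracts the mean of all good channels, labels pass
through one-to-one, and `cut` cannot occur.

The minute is cut into 5 s segments; each channel-segment is linearly
detrended, demeaned, and z-scored (tolerances: |mean| < 1e-10, |SD−1| <
1e-8). A channel with a zero-variance segment (relative floor 1e-10 of the
recording's amplitude) is dropped for that situation and logged. Filtering
inside biomarkers uses a Hamming windowed-sinc FIR of order 3·fs/low-cutoff
applied zero-phase (forward–backward, implemented as one FFT convolution
with the filter autocorrelation and odd edge reflection, numerically
identical to `filtfilt`); zero-phase application squares the stop-band
attenuation, giving > 40 dB one octave outside the band. The order in which
normalization and band-filtering compose is fixed as: normalize once per
segment, then filter inside each biomarker on the normalized segment. The
Granger-causality chain additionally first-differences each detrended
segment before the z-score.

## Estimators

Exact per-channel definitions are in the README table; choices that were
genuinely open and are fixed here:

* **ARR** — AR order 2, per-window least squares. Window (40 samples) and
  overlap (50 %) are fixed; the low order captures the locally harmonic
  background cheaply so that the residual tracks non-harmonic (spiky,
  HFO-like) content. The estimator is a ratio of residual spreads and hence
  scale-invariant. The published description of this measure leaves the
  exact formula to supplementary material we reconstruct: windowed residual
  SDs s_w, statistic median(|s_w − median s|)/median s.
* **PAC** — amplitude-normalised mean vector length, chosen because it is
  scale-invariant, bounded in [0, 1] and desk-verifiable against the closed
  form (a ≡ 1+cos φ with uniform φ gives exactly ½). One phase-filter
  length is trimmed from each segment edge before averaging. This too is a
  reconstruction of a supplementary formula from the estimator family the
  source literature cites.
* **h²** — 10 equal-count bins (robust to amplitude outliers), regression
  curve through the (mean x, mean y) bin centroids with linear extension
  beyond the outer centroids; negative variance-ratio artefacts clamp to 0.
  Delay grid ±68 samples in steps of 17 (±0.0332 s / 0.0083 s at 2048 Hz),
  maximised per ordered pair.
* **GC** — VAR fitted by the lagged-autocovariance (Yule–Walker) normal
  equations, pooled over segments with no lag product crossing a segment
  boundary; AIC order search over 1..20 (bounded to keep desk-scale
  runtime); pairwise-conditional statistic clamped at 0. Under the null its
  entries sit at the χ²_p/T scale, verified against the asymptotic bound.
* **sdDTF** — one VAR(30) per 5 s segment ("short-time" = the pipeline's
  natural segment; no sub-segment sliding), spectral transfer matrix on a
  257-point grid over [0, fs/2], full-frequency normalisation per sink,
  weighted by partial coherence (which suppresses cascade-mediated paths),
  averaged over the gamma band 30–80 Hz (the integration band is not fixed
  by the source literature; gamma matches the band used by the other
  bivariate measures, 80–250 Hz is available in config). The spectral
  matrix inverse uses a 1e-12 relative ridge; a genuinely singular fit
  raises.

Directed matrices reduce to out-strength = mean of a channel's outgoing
entries (mean, not sum, so situations with different channel counts remain
comparable); undirected ones to the mean connection weight.

## Evaluation framework

Pools per biomarker: *pre* = all values of resected derived channels in
pre-resection situations of all (improved) patients — cured patients'
own pre-resection data included; *post* = all channel values of
post-resection situations of cured patients only. Group-level testing is a
one-sided two-sample KS test of "pre stochastically larger"
(D⁺ = sup[F_post − F_pre]), exact for small pools, at α = 0.01 with
deliberately no multiple-comparison correction; the same test is applied to
per-patient maxima. The detection threshold per biomarker is the maximum of
the post pool — the worst-case universal reference (any subset of cured
patients could only lower it). Detection is *strictly* above threshold
(ties, measure-zero for continuous values, deterministically do not
detect). A leave-one-out threshold mode (withholding a cured patient's own
post data) exists behind a flag, off by default. The cumulative biomarker
is the OR over the pool of seven. Subgroup analyses recompute thresholds
within temporal / extra-temporal patients; the mesiotemporal contrast runs
the one-sided KS of mesiotemporal vs neocortical pre-resection values in
temporal patients.

Sensitivity/specificity against resected vs non-resected channels is
deliberately out of scope: resections are larger than the epileptogenic
zone and spatial coverage is partial, so those quantities would measure the
resection strategy more than epileptogenicity.

## Synthetic cohorts

The generator emulates the *structure* of an intra-operative cohort, not
its biophysics. Background per channel: 1/f² -weighted Gaussian noise
(envelope flattened below 1 Hz) plus a 10 Hz rhythm at SNR 1 — the minimal
caricature giving a realistic spectral slope and a dominant rhythm under
anaesthesia. Epileptogenic electrodes form a contiguous block (so bipolar
derivations inherit the signature; injections use independent noise per
electrode and therefore do not cancel in the difference) and are always
resected, together with a margin electrode that creates genuine `cut`
pairs. Post-resection situations are a fresh full-array placement with pure
background for cured patients; improved patients can optionally retain a
scaled residual signature (off by default — cured tissue left in place is
assumed unable to trigger seizures).

Signatures and their defaults (`EffectConfig`): theta-phase-modulated
high-gamma noise with modulation depth 0.8 and unit-background-SD carrier
amplitudes; biphasic Gaussian-derivative transients (~40 ms) at 1/s with
8 SD peaks, Poisson-timed by thinning a fixed 2/s base process (event sets
are nested across rates); lagged linear mixing source→targets with gain 0.8
at 10 samples. These are calibration knobs of the test-bed, not empirical
claims about epileptogenic tissue — no quantitative signature model exists
to emulate. All randomness is keyed per (seed, patient, situation,
electrode, component), so cohorts are bit-reproducible and changing one
knob leaves every other draw untouched: knob sweeps are common-random-number
comparisons, and the all-zero effect configuration yields an exchangeable
pre/post null by construction.

What passing tests on these cohorts do **not** show: robustness to volume
conduction, electrode localization error, anaesthetic drift, artefact
leakage, inter-subject variability of baseline rhythms, or any real
electrophysiology of epileptogenic tissue. They validate the machinery —
estimators, montage algebra, thresholds, statistics — not clinical
performance.

## Validation design and problem sizes

The package's validation runs at desk scale by shrinking cohort geometry,
never effect sizes or replicate counts: small grids (2×2 / 2×3 plus a 1×6
strip), 10–20 s situations (2–4 segments), 3–12 patients, always at 2048 Hz
with 5 s segments. Directed-structure recovery uses the full 60 s / 2048 Hz
stated conditions.

The null-calibration study (200 all-zero-effect cohort replicates) runs
under the common-average montage, where derived channels are exchangeable
by construction; under the bipolar montage the resected derivations share
parent electrodes with different numbers of neighbouring pairs than the
pooled post set, so the bivariate strengths of the two pools differ
structurally even without any signature — a property of the montage worth
keeping in mind when interpreting pooled pre/post comparisons on real
recordings too. With the exact small-sample KS test the rejection rate at
α = 0.01 is conservative by discreteness, so the acceptance band is
[0, 0.035]. This calibration is asserted for the channel-local biomarkers
(ARR, PAC, PLV, PLI, h²). It cannot hold for GC and sdDTF: all channel
strengths of a situation derive from one joint VAR fit, so their null
values are clustered by situation (measured intraclass correlation ≈ 0.83–
0.95 across 2–12 segments), and a KS test that takes the nominal channel
count as its sample size is anti-conservative on such pools at any
desk-scale geometry (and conservative in the infinite-data limit). The
corresponding check documents the nominal requirement and fails by design
until the pooled comparison accounts for that clustering; the same caveat
applies to the pooled group-level test on real multivariate biomarker
values.

The knob-sensitivity sweep measures each signature through its matched
biomarker (PAC for modulation depth, ARR for transient rate, h² for
coupling gain — the conditional-GC and renormalised-sdDTF strengths are
diluted by the collinearity the bipolar montage induces, an effect faithful
to the method rather than a defect) and allows a one-patient dip per step
as the Monte-Carlo tolerance. On null cohorts, per-biomarker detections
still occur through the max-of-samples overlap mechanism (a patient's pre
maximum exceeding the pooled post maximum by chance); this rate is
reported, not asserted, as it is a property of the max statistic itself.

## Known limitations

* The seven estimator formulas reconstruct supplementary material that is
  not publicly archived; parameter-level divergence from the original
  MATLAB implementations is possible even though every fixed constant
  (window lengths, bands, delay grid, model orders) is matched.
* Yule–Walker VAR estimates differ from lag-stacked least squares at
  O(p/N); immaterial at the segment lengths used.
* The theta band-pass (3–4 Hz) at order 3·fs/low has a transition band
  wider than the band itself; phase extraction is effectively broad-theta.
  This mirrors the standard windowed-sinc practice at these parameters.
* Common-average recordings of a situation share one reference, so derived
  channels are not independent; no correction is attempted (nor in the
  emulated analysis).
* EDF export is not implemented; the cohort layout stores float32 raw
  binaries with JSON sidecars as documented in `ecogmark.io`.
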