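# Methods

`ecgkit` implements a harmonization pipeline for 12-lead ECG waveforms and a
set of audit statistics for multilabel ECG classifiers — discrimination and
calibration metrics, an equalized-odds fairness audit, a membership-inference
privacy probe, and the two contrastive objectives used in self-supervised ECG
pre-training — together with a synthetic generator that makes every stage
testable without access to clinical data. This note records the models, the
numerical choices, and what the synthetic study conditions do and do not show.

## The harmonization pipeline

ECGs acquired on different hardware differ in three systematic ways the
pipeline targets: sub-1 Hz baseline wander from motion and electrode drift,
narrowband mains interference at 50/60 Hz, and amplitude/unit drift (e.g. a
site exporting microvolts where millivolts are expected). The pipeline runs
three stages in a fixed order; every decision is logged in a per-record
report.

**Stage 1 — gated zero-phase high-pass.** For each lead the one-sided rFFT
amplitude spectrum is computed, with band energies `E_low` over [0, 1) Hz
(DC bin included — a DC offset is baseline pathology) and `E_diag` over the
inclusive 1–30 Hz diagnostic band, the range carrying most clinically
relevant ECG content. Per-bin energies are normalized so they sum to the
time-domain energy (Parseval; checked to 1e-6 relative in tests). The gate
triggers when `max over leads of E_low / E_diag > 10` (strict; an infinite
ratio counts as exceeding), i.e. when low-frequency energy exceeds the
diagnostic band by more than an order of magnitude on any lead; the filter is
then applied to **all** leads for inter-lead consistency (per-lead gating is
not offered — masking and downstream models index leads positionally).

The filter itself is a 1 Hz high-pass with the squared magnitude response of
an order-4 Butterworth design, `|H(f)|^2 = (f/fc)^8 / (1 + (f/fc)^8)` — the
response of one forward plus one backward pass, hence zero phase. It is
*realized in the DFT domain*: the rFFT of each lead is multiplied by this
response and inverted. A time-domain forward–backward (filtfilt) realization
with reflective edge padding was evaluated and rejected: with only ~3 cycles
of a 0.3 Hz component in a 10 s window, the padded reflection leaves edge
transients that splash roughly 0.1% of the wander amplitude *broadband*
across the spectrum. Against the noiseless synthetic cohorts used here
(whose spectra contain near-zero bins between beat-train harmonics), that
splash is detected as spurious "narrowband artefact" by stage 2 and breaks
the pipeline's idempotence. The DFT realization has the identical magnitude
response (verified against the closed form to machine precision in tests),
exactly zero phase, no transients, and composes exactly with the spectral
detection stage. Its one trade-off is circular (rather than reflected)
boundary handling, immaterial for the 10 s AC-coupled records the pipeline
targets. Records shorter than ~3 cutoff periods are refused.

**Stage 2 — cohort-referenced narrowband suppression.** A reference cohort
(>= 10 records, polyphase-resampled to a common rate) provides per-lead,
per-bin mean `mu_f` and SD `sigma_f` of amplitude spectra computed after the
gate/high-pass stage. A *band* is a maximal run of contiguous bins whose
amplitude exceeds `mu_f + k * sigma_f` (default k = 2); runs wider than 2 Hz
are discarded — broadband exceedance (wrong units, global gain error) is not
mains interference and is the business of stage 3. Two numerical guards:

* an absolute floor of `1e-7 x` the lead's maximum mean amplitude is added to
  the threshold, so bins whose cohort amplitude is numerically zero (between
  exact harmonics of a noiseless comb) cannot be flagged on machine-epsilon
  fluctuations; the floor is orders of magnitude below any physically
  meaningful amplitude;
* suppression refuses to act when flagged bins cover more than half of a
  lead's spectrum (degenerate baseline fit).

Flagged bins are replaced by a LOESS baseline: a degree-1 local regression
(statsmodels `lowess`, span 0.1 of the frequency axis, fitted on the
*unflagged* bins of the log-amplitude spectrum and interpolated at the
flagged bins). Amplitudes are replaced, phases kept, and the signal is
rebuilt by inverse rFFT — so unflagged bins are bitwise untouched and
diagnostic-band energy outside the flagged bands is conserved exactly.
Detection is per lead and per bin; alternatives (per-band statistics, a
smoothed envelope) were considered and set aside as less transparent.

**Stage 3 — amplitude scaling.** The robust amplitude of a record is the
median over leads of the per-lead 99th-minus-1st percentile of samples; the
reference target `T` is the cohort median of that statistic. The default
`per_dataset` mode applies one factor `T / median(record statistics)` to the
whole cohort, computed *after* stages 1–2, so between-record voltage ratios —
clinically meaningful (hypertrophy, low-voltage states) — are preserved
exactly. A `per_record` mode (one factor per record) is provided for
completeness but erases those differences and is not the default.

**Stage-order limitation.** Suppression precedes scaling. A record carrying
*both* a x1000 unit drift and a mains tone therefore bypasses narrowband
suppression on the first pass (the drifted spectrum exceeds the threshold as
one giant band, dropped by the width rule), and the tone — three decades
smaller after rescaling — survives into the output. A second pass would then
flag it. This composition is a property of the fixed stage order; the
idempotence experiment below therefore exercises wander and mains corruptions
(unit drift is exercised end-to-end in the rescue experiment, where the
residual tone is negligible by construction).

## The synthetic generator

Beats are sums of Gaussian bumps (P, Q, R, S, T; default R amplitude 1 mV,
widths 12–60 ms) placed on an R-peak train at a fixed heart rate with
optional bounded RR jitter, projected onto the 12 leads by a fixed
coefficient vector (aVR and V1 negative). Signals are mean-subtracted per
lead (AC coupling), so clean records carry < 5% of diagnostic-band energy
below 1 Hz and never trip the gate. Artefacts are injected explicitly:
sub-1 Hz sinusoidal wander with random phase, fixed-frequency mains tones,
multiplicative scale drift, and additive white noise — each restricted to a
chosen lead subset, with unspecified leads bitwise unchanged.

Two deliberate departures from realism, both load-bearing:

* **No broadband noise by default.** Across a cohort, additive noise makes
  per-bin amplitudes Rayleigh-distributed at noise-dominated bins, and the
  exceedance probability of `mu + 2 sigma` for a Rayleigh tail is ~3.7% *per
  bin regardless of the noise level*. With ~15 000 (lead, bin) pairs, any
  in-distribution record would then always carry spurious narrow flags, and a
  per-bin 2-SD rule could never certify a clean record. Real cohorts are
  large enough that the rule tolerates this; a desk-scale emulation is not.
  White noise therefore exists only as an injectable artefact class.
* **Bounded amplitude variation in reference cohorts.** Reference cohorts
  vary by a common uniform multiplier (U(0.8, 1.2)); records audited against
  them stay inside a narrower band (U(0.9, 1.1)). For bounded variation the
  maximum sits below mean + 2 SD (a uniform maximum is ~1.73 SD above its
  mean), so the detection rule has genuine headroom and zero false positives
  on in-distribution records — the property the idempotence experiment
  certifies. Heart rates are chosen off the FFT grid (e.g. 64 or 85 bpm on a
  10 s window) so spectral leakage fills inter-harmonic bins and broadband
  exceedance is recognized as one wide band rather than fragments.

The audit-cohort generator draws per-label Bernoulli truths and Gaussian
latent scores (positives at +1, negatives at −1 by default) mapped through a
logistic sigmoid into (0, 1); since every metric here is rank-based or
probability-scale-explicit, the closed-form AUROC
`Phi(delta_mu / sqrt(sigma_p^2 + sigma_n^2))` is preserved and serves as the
coverage oracle. Group shifts (age/sex) and a membership shift act additively
on the latent scale, giving controllable equalized-odds gaps and
membership-inference signal.

What passing these tests shows: the pipeline's spectral mathematics, gating
logic, and statistics behave exactly as specified under controlled spectra
and amplitudes. What it does not show: performance on real morphologies
(disease patterns, pacing artefacts, muscle noise), non-sinusoidal wander, or
electrode-specific artefact coupling.

## Designed experiments (study conditions)

* **Rescue** (`rescue_experiment`): two sites of 2000 records each at 85 bpm
  (fundamental 1.42 Hz, where the filter's squared response is 0.94 — far
  enough from the 1 Hz cutoff that filtering perturbs morphology-dependent
  band energy only mildly). Binary labels multiply all wave amplitudes by
  1.6 (vs 1.0) with lognormal jitter (sigma = 0.18); label-independent T
  amplitude/width and R width jitter make band energy the noisier feature.
  Site B is corrupted with 0.3 Hz wander at U(5, 10) mV — label-independent,
  guaranteeing a low/diagnostic energy ratio >= 20 — plus a 60 Hz tone and a
  x1000 unit drift. A logistic scorer on two features (log robust
  peak-to-peak, log diagnostic-band energy) is trained on half of site A.
  The wander scrambles the peak-to-peak feature (raw site-B AUROC ~0.5);
  harmonization against site A's references restores it to within 0.02 of
  the site-A AUROC (observed gap ~0.01 at n = 2000, tracking the clean-site-B
  score to < 0.001).
* **Gate recovery**: 1000 records, wander injected into a random 30% with
  amplitude set from Parseval's relation (`a = sqrt(2 * 20 * E_diag / N)`,
  +10% margin) so corrupted ratios are >= 20 while clean records sit below
  0.05; the gate recovers the subset exactly.
* **Narrowband**: the reference cohort includes a 20% minority carrying
  60 Hz tones of varied strength (0.01–0.05 mV), as field data would, so the
  cohort SD at the mains bin dwarfs a clean record's own 60 Hz content; an
  injected tone at mean + 3 SD then clears the mean + 2 SD threshold with a
  full SD of margin and is detected in 100/100 seeded trials, suppressed to
  the LOESS baseline, with off-band diagnostic energy conserved to machine
  precision.
* **Idempotence**: 500 records (clean / wander / 60 Hz thirds), harmonized
  twice; the second pass applies no filter, flags no bands, and rescales by
  exactly 1 (the per-dataset factor is median-equivariant).
* **Fairness**: cohorts of 15 000 records (~5000 per age stratum), three
  labels, latent separation 3.3 (AUROC ~0.99 — the operating regime of the
  high-discrimination classifiers this audit targets, where TPR ~0.95 and
  binomial noise in group rates is small). Null (delta = 0) gaps stay below
  0.02 in 20/20 seeds; mean gaps grow monotonically in the injected group
  shift.
* **Membership inference**: 2000 records per class with 77-dimensional
  outputs; exchangeable classes give tenfold attack accuracy in [0.45, 0.55],
  a disjoint-support +10 shift in one feature gives accuracy ~1.0 with that
  feature ranked first in forest importance.
* **Contrastive objectives**: closed-form symmetry values (`ln(K+1)` for the
  token loss with all cosines equal; `ln(2B-1)` for the segment loss with
  identical embeddings) hold to 1e-12; explicit double-loop oracles agree to
  1e-10; 500 steps of finite-difference descent on 2-D embeddings (4
  patients x 2 segments, temperature 0.1) drive the segment loss below
  `ln(2B-1)/10` and cluster embeddings by patient (silhouette 1.0).

## Statistics: definitions and tie-breaks

* **AUROC** is computed from average ranks, identical to pairwise concordance
  counting with ties worth 1/2 (exact agreement with a brute-force oracle is
  asserted, not approximated). **AUPRC** is average precision (step
  integration of the precision–recall curve). **Micro-averaging** flattens
  the (record x label) matrices before computing; macro averages per-label
  values.
* **Resampling CIs**: 1000 iterations drawing ceil(0.7 n) records *with
  replacement*, percentile 2.5/97.5 endpoints. A without-replacement mode
  (true 70% subsets) is provided but documented as under-covering: the
  subsample statistic's variance is only `(1/0.7 - 1) ~= 0.43x` the
  estimator's sampling variance, so its nominal 95% interval covers the
  population value ~80% of the time (the with-replacement interval covers
  ~97%, measured against the generator's analytic AUROC). Intervals are
  clamped to contain the full-sample point estimate. A metric undefined on
  > 20% of resamples raises an instability error rather than returning a
  quietly biased interval.
* **DeLong**: placement-value covariance of paired AUROCs, two-sided normal
  reference; identical score vectors return delta = 0, p = 1. No
  multiple-testing correction is applied anywhere.
* **Thresholds**: per label, candidates are midpoints of consecutive distinct
  scores plus 0/1 guards; the winner minimizes |sensitivity − specificity|,
  ties broken by the larger Youden index, then the smaller threshold.
  Decisions use `score >= threshold`.
* **NRI** is category-free: `[P(up|event) − P(down|event)] + [P(down|nonevent)
  − P(up|nonevent)]`, "up" strict; ties move nothing.
* **Weighted Brier** is the normalized weighted mean of per-label Brier
  scores with inverse-prevalence weights by default. This weighting is this
  package's interpretation — the cited formulation is not reproduced in the
  source — and any nonnegative weight vector may be supplied instead.
* **Equalized odds**: decisions pooled over all labels per group (micro),
  TPR = TP/(TP+FN), FPR = FP/(FP+TN); the gap per partition is the maximum
  absolute pairwise difference (the simple difference for two sexes). Ages
  55 and 75 fall in the middle stratum ("under 55"/"over 75" leave the
  endpoints to the middle bin). Groups with undefined rates are flagged and
  excluded from that gap with a warning.
* **MIA**: ten independent balanced rounds (majority class downsampled per
  round) rather than ten disjoint partitions — class counts rarely allow
  fully disjoint balanced folds; each round splits 80/20 stratified, fits a
  50-tree random forest (sqrt-features per split, unlimited depth) and scores
  held-out accuracy and AUROC. The attack sees output vectors only, never
  waveforms. The separation index is mean between-class pairwise distance
  over pooled mean within-class distance; the optional 2-D embedding is PCA
  (deterministic) and carries no contract beyond determinism.
* **Contrastive losses**: cosine similarity at temperature tau (default 0.1);
  token-loss negatives are drawn uniformly without replacement from other
  positions in the same segment (K = 4 default); segment-loss positives are
  "same recording" (segment-id suffix stripped) or "same patient", with
  anchors lacking a positive excluded. Quantization/codebooks and encoders
  are out of scope; masked leads are replaced by a constant (default 0), not
  a learned token.

## I/O conventions

The canonical unit is the millivolt; microvolt inputs are divided by 1000 on
read, and unknown "raw" units pass through with a logged warning for stage 3
to fix. Lead order is normalized to I, II, III, aVR, aVL, aVF, V1–V6;
records without the full 12-lead set are rejected unless explicitly allowed.
The matrix dialect (tab-separated columns per lead + JSON sidecar) is the
package's own fixture format; WFDB support covers single-segment format-16
records via a minimal built-in reader/writer whose round-trip error is the
ADC quantization step (gain chosen per record, at most 1000 ADC units/mV).

## Problem sizes and reproducibility

All randomness flows from integer seeds through named `SeedSequence` streams;
identical seeds give bitwise-identical records, cohorts, resamples, and fold
assignments. The designed experiments run at the sizes stated above (2 x 2000
records for the rescue, 1000 for the gate, 100 seeded trials for detection,
100 cohorts x 1000 resamples for coverage, 20 seeds x 15 000 records for
fairness, 2 x 2000 x 77 for the attack, 500 records for idempotence) — sizes
chosen so each claim's stochastic margin is comfortably resolved on a single
CPU.
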