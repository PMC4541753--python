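# Methods

`prognostrack` implements the computational core of a 12-month prognostic
study in chronic low back pain: does a brief screening questionnaire (the
STarT Back Screening Tool, SBST) or a set of physiologic trunk-muscle
measures better identify patients who will still present disability, pain
or fear of movement at follow-up?  The package covers four layers — a
synthetic-data generator standing in for the unreleased participant data,
the EMG feature-extraction chain, clinical scoring, and the association/
discrimination statistics — plus a pipeline that composes them.

## Synthetic cohort

Participant data are generated from a Gaussian copula over a small factor
model.  A latent *severity* factor loads on the nine SBST item indicators,
on the clinical outcomes (ODI, NRS, TSK) at all five timepoints, and —
weakly, with opposite sign — on the physical-capacity variables; one
*instrument* factor per outcome carries within-instrument correlation
across follow-ups, and *strength*/*endurance* factors tie the force tests
together.  Because every downstream statistic is rank- or threshold-based,
the copula correlation is the operative quantity; Greiner's relation
τ = (2/π)·arcsin(ρ) links a programmed copula correlation ρ to the Kendall
τ the analysis estimates, which the calibration tests exploit directly.

Marginals map the copula's uniform scores onto instrument scales:

* ODI, NRS, TSK — truncated normals on [0, 100], [0, 100] and [17, 68].
  The location parameter is solved numerically so the *realized* mean of
  the truncated distribution equals the target (truncation at the floor
  would otherwise inflate means by several points for NRS).  Baseline
  targets: ODI 18.38 ± 10.33 %, NRS 27.61 ± 22.94, TSK 36.42 ± 8.75;
  follow-up means drift mildly toward improvement (most participants in
  such cohorts receive some treatment), a modeling choice since no
  follow-up marginal summaries are available.
* SBST items — thresholded indicators with endorsement probabilities
  0.32 (somatic items 1–4) and 0.30 (psychosocial items 5–9), calibrated
  once so the default loadings reproduce a low:medium:high split near
  35:11:7 at the default association strength.
* PGIC — seven ordered categories with probabilities
  (0.18, 0.27, 0.20, 0.20, 0.09, 0.04, 0.02), i.e. ~45 % report
  improvement; weakly coupled to severity so the global-impression outcome
  carries little prognostic signal, matching the pattern the analysis is
  designed to exhibit.
* Force tests — truncated normals with targets prone MVC 147.90 ± 64.58 N,
  lateral MVC 112.67 ± 49.93 N, prone endurance 57.46 ± 27.10 s, lateral
  endurance 31.73 ± 15.40 s (right and left lateral drawn separately and
  averaged downstream); motor variability 0.35 ± 0.15 cm and NMFslope
  −0.30 ± 0.15 %·s⁻¹ are plausible values chosen by us, as no summary
  statistics exist for them.

Dropout is missing-completely-at-random at 13 % per follow-up (so ≥87 %
completion in expectation), independent across follow-ups; baseline is
never dropped.  MCAR is justified by the finding that completers and
lost-to-follow-up did not differ at baseline.  Two pre-built
configurations exist: `default_cohort_config` (moderate associations
producing τ in the 0.2–0.4 range between SBST and outcomes) and
`contrast_cohort_config` (strong questionnaire–outcome coupling, null
physiology), the latter encoding the study's headline qualitative
contrast as a known ground truth.

## Synthetic grid EMG

The generator is not a motor-unit simulator.  It produces exactly the two
properties the estimators rely on: (i) per 0.5-s block, each channel is
flat-band noise (random phase) whose spectral median equals the programmed
median frequency MF(t) = MF₀ + slope·t, scaled exactly to the channel's
target RMS; (ii) the target RMS across the 13 × 5 grid (12.5 mm pitch) is
a Gaussian spatial profile (σ = 1.5 cm) whose centre follows the
programmed CoG trajectory.  Line interference (60 Hz) and broadband noise
are added at amplitudes *relative to the local channel envelope* (defaults
0.05 each), so signal-to-noise is uniform across the grid; an absolute
line amplitude would make channels far from the activity centre
unrecoverable, which is a property of the amplitude model, not of real
recordings, whose dynamic range across a grid is far smaller.  For the
MVC task the spatial profile is uniform — a maximal effort activates the
muscle volume broadly — which makes MVC normalization cancel channel gain
without reshaping endurance maps.

The spectral band half-width is 15 Hz.  A wider band interacts with the
fixed analysis filters: as the band slides down during fatigue, the
60/120 Hz notches and the 20-Hz high-pass edge clip different parts of it
at different times, biasing the estimated MF slope toward zero (about
−20 % at a 40-Hz half-width versus −5 % at 15 Hz).  The narrow band keeps
the generator's median-tracking contract clean; it is not a realistic EMG
bandwidth, and the methods here make no claim about spectral shape.

A programmed trajectory that would leave the grid is rejected at
validation: near the boundary the truncated spatial profile compresses
CoG displacement and the ground truth would no longer mean what it says.
Recovery checks therefore programme drifts that stay ≥2σ inside the grid
(e.g. 0.1 cm/window over 30 s rather than 60 s).

## EMG feature chain

* **Filtering** — 2nd-order Butterworth band-pass 20–450 Hz plus notches
  at 60 Hz and harmonics up to 420 Hz (Q = 30), all applied zero-phase
  (forward–backward, doubling effective order) so no group delay shifts
  window alignment.  Requires fs > 900 Hz.
* **Windows** — non-overlapping 0.5 s; window k covers samples
  [k·0.5·fs, (k+1)·0.5·fs), trailing partial windows discarded; window
  observations are indexed by their start time, so the regression
  intercept is the value at t = 0.
* **RMS maps** — per-window, per-channel RMS, normalized to % of the
  per-channel MVC reference (RMS over the central 3 s of the best MVC
  trial; the reference segment is unspecified in the protocol, and the
  central segment avoids ramp-up/release).  Channels with ~zero reference
  are excluded and logged.
* **CoG** — amplitude-weighted mean electrode position, channel (1,1) at
  the cranial-medial origin, reported in cm.  Windows with <80 % valid
  channels are missing.  **Motor variability** is the mean Euclidean
  distance between CoGs of consecutive valid windows, per side, then
  averaged across sides.  The source protocol says migration "was
  quantified" without a formula; the consecutive-step mean matches the
  "mean migration" phrasing and is translation-invariant; a
  displacement-from-start variant can be computed from the exposed CoG
  series.
* **MF** — Hann-tapered periodogram per window; the median is located by
  linear interpolation of cumulative power within the crossing bin (no
  estimator is named in the protocol; the periodogram keeps the
  half-power definition exact on its own spectrum).  **NMFslope** — per
  channel, least-squares slope of MF over time divided by the intercept
  (iMF), ×100, in %·s⁻¹; channels with iMF ≤ 0 or <3 valid windows are
  excluded; side value = mean over channels; global = mean of sides.  All
  windows enter the regression (no transient trimming).
* Input channels are treated as hardware-bipolar; a software
  single-differential mode along the cranio-caudal axis (13×5 → 12×5) is
  available for monopolar input.

## Clinical scoring

SBST: total = sum of nine 0/1 items; total ≤ 3 → low risk; total ≥ 4
with psychosocial subscale (items 5–9) ≤ 3 → medium; subscale ≥ 4 → high.
The medium/high split follows the tool's published scoring system (the
study itself uses only the total).  Missing items invalidate the score —
no imputation.  Dichotomies (inclusive thresholds): disability ODI ≥ 24 %,
pain NRS ≥ 37, fear TSK ≥ 41, subjective improvement PGIC ∈ {1, 2}.  For
the discrimination analysis the PGIC positive class is *absence* of
change (PGIC ≥ 3).  Lateral force-test values are the mean of right and
left sides, missing if either side is missing.  MVC = maximum of ≤3
trials, with the completion reason (threshold failure vs three trials)
recorded.

## Statistics

* **Kendall τ** — tau-b (tie-corrected) with the asymptotic tie-corrected
  normal p-value, pairwise deletion per analysis; every reported cell
  carries its n.  Pearson equivalence r = sin(π·τ/2); effect categories
  on |τ|: > 0.34 large, ≥ 0.20 moderate, else small (the published bands
  leave (0.19, 0.20) unassigned; the boundary is taken at 0.20).
* **ROC/AUC** — tie-corrected rank statistic; 95 % CI from the
  Hanley–McNeil standard error with a two-sided z-test against 0.5
  (DeLong variance available via `ci_method="delong"`).  Strength labels:
  0.7–0.8 acceptable, 0.8–0.9 excellent, ≥0.9 outstanding.  At n ≈ 50
  with ~10 positives the Hanley–McNeil interval is mildly anticonservative
  (null coverage ≈ 92 % in simulation), which the end-to-end checks
  account for by asserting majority behaviour across seeds rather than
  nominal coverage.
* **Cutoffs** — test-positive means score ≥ cutoff; LR+ = sens/(1−spec)
  (+∞ at spec = 1), LR− = (1−sens)/spec (undefined at spec = 0); LR+ > 10
  or LR− < 0.1 labels a decisive test, otherwise "sometimes useful".
* **Sample size** — Fisher-z: n₀ = ((z₁₋α/2 + z₁₋β)/atanh r)² + 3 kept
  unrounded, then inflated by (1 + attrition) and rounded half-up.  The
  order matters: it reproduces the published design values 51 (r = 0.40)
  and 32 (r = 0.50) at α = 0.05, power 0.80, attrition 10 %, whereas
  ceiling before inflating gives 52.
* **Baseline comparisons** — Welch t-test by default (pooled variant
  available); two constant equal groups return p = 1 by convention.
* No multiplicity correction is applied, mirroring the original analysis.

## Pipeline

`run_pipeline` is deterministic per seed and emits CSV tables (the tested
surface) plus a provenance block (seed, version, config hash, exclusion
counts).  Optionally the EMG summary variables of a configurable number
of participants are replaced by values measured by the full feature chain
on synthetic recordings whose programmed ground truth is that
participant's own cohort value, so the analysed columns pass through the
measurement path at its native scale; the default measures 4 participants
at 20 s per recording to keep a full run in seconds.

## Problem sizes and what the tests show

Recovery and calibration checks run at: 60-s recordings over 20 seeds for
NMFslope (recovered −0.48 for a programmed −0.5 %·s⁻¹), 30-s recordings
for CoG drift (0.100 for a programmed 0.1 cm/window), 2 000 null
replicates at n = 50 for τ type-I error, 5 000 copula draws for the
Greiner relation, and 12–20 seeds of n = 53 cohorts for the end-to-end
contrast.  Passing these shows the chain and the statistics are correct
*under the generator's assumptions* — Gaussian-copula dependence, MCAR
dropout, median-tracking band noise.  Real grid EMG adds nonstationary
motor-unit content, conduction-velocity changes, electrode artifacts and
channel-quality heterogeneity that the generator deliberately omits, and
real cohorts may have informative dropout; none of these are validated
here.

## Known limitations

* The Hanley–McNeil interval is anticonservative at this study's n; the
  DeLong option is preferable for small samples but is not the default,
  to match common practice in the screening-tool literature.
* The grid is modeled as a full 13 × 5 = 65-channel matrix; commercial
  64-electrode adapters omit one corner pad.  A missing channel can be
  represented by excluding it via the normalization rule.
* The bothersomeness SBST item must be pre-mapped to 0/1; item-level
  scoring of ODI/TSK/NRS questionnaires is out of scope (scores are
  inputs).
* Follow-up marginal trajectories are a modeling choice; only their rank
  dependence structure is anchored to reported statistics.
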