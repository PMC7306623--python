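# Methods

This note documents the models, conventions, and numerical choices behind
`errmon`, and what the synthetic-data tests do and do not establish about
real recordings.

## Task model and behavioral generator

The paradigm is a color Go/Nogo task: 360 trials in six blocks, 80:20
go/nogo ratio, one nogo color among eight. Each trial lasts 2000 ms
(100 ms stimulus, 1100 ms blank, 800 ms fixation) with a 600–1000 ms
inter-trial interval; detected nogo errors are signaled by a second press
in the 1200–2000 ms post-stimulus window (after fixation onset).

The behavioral agent is intentionally minimal:

* **RTs** are shifted lognormal, `rt = shift + LogN(mu, sigma)` with
  defaults shift = 150 ms, e^mu = 270 ms, sigma = 0.35, giving a median
  correct-go RT of 420 ms. A full evidence-accumulation model would add
  parameters without changing anything the downstream analysis measures.
* **Errors** occur on nogo trials with probability `p_nogo_error`
  (default 0.20 — the difficulty the task is calibrated to) and are drawn
  `error_rt_shift` = −70 ms faster, reproducing the canonical error < correct
  RT ordering.
* **Detection** is Bernoulli `p_detect` (default 0.78) with the second
  press uniform in the signaling window.
* **Post-error slowing** is additive: the go trial immediately after an
  error gets `pes_increment` (default 75 ms) added to its RT draw. This is
  deliberately matched to the one-trial-back ΔPES definition the analysis
  uses, so the measured ΔPES converges to the increment.

Group profiles carry the clinical calibration anchors (controls: 24.3 %
errors, 78.3 % detection, 416 ms baseline RT, 86 ms ΔPES; patients:
22.1 %, 77.8 %, 433 ms, 65 ms) and are fully overridable.

## EEG forward model

Each ERP component is a Gaussian-windowed half-sine: support
`latency ± width/2`, peak value exactly `amplitude` at `latency`, spatial
weighting `exp(-ang²/2σ²)` around a peak electrode (weight exactly 1
there). This waveform was chosen because it is smooth, unimodal, and makes
parameter recovery analytic: in the noise-free limit, peak extraction
returns the embedded amplitude and latency *exactly*, provided the latency
sits on the 2 ms sample grid and the component's support does not reach
into the baseline window or another measured peak. Default latencies are
therefore grid-aligned (e.g. the patient N2 default is 302 ms, snapping a
303 ms anchor to the grid).

Condition routing: N2/P3 are stimulus-locked with separate go/nogo
amplitudes; Ne/Pe attach to error presses, CRN/Pc to correct presses.
Background noise is 1/f^α (α = 1, 10 µV RMS per channel by default);
blinks are Hanning-shaped 400 ms events (4/min, ~200 µV) entering the
vertical EOG and propagating to anterior scalp channels with a factor
scaled by the square of the electrode's anterior (y) coordinate. An
optional 50 Hz line component is available.

What the generator does **not** emulate: realistic single-trial ERP
variability structure (only Gaussian latency jitter), muscle/movement
artifacts, channel drift or bad channels, volume-conducted source mixing
beyond the Gaussian topography, or distinct morphology for undetected
errors. Passing recovery and calibration tests therefore demonstrates the
*analysis code* is correct and internally consistent — not that the
pipeline is robust to every pathology of clinical EEG.

## Preprocessing conventions

Stage order is enforced: ocular regression → epoching + baseline →
amplitude rejection → CSD; the CSD refuses un-screened input, and the
screening refuses CSD input.

* **Ocular correction** is whole-recording least-squares regression of
  each scalp channel on all EOG channels (with intercept). The original
  blink-triggered algorithm is not described in enough detail to
  reimplement; regression is the simplest method with the same contract.
* **Epochs** are half-open `[t_min, t_max)` at 500 Hz so sample counts are
  exact: stimulus −100–800 ms → 450 samples, response −100–600 ms → 350,
  decoding −100–300 ms → 200 = 40 × 5. Time 0 is the lock-event sample;
  baseline is `[-100, 0)`. Epochs that run past the recording edge are
  flagged `rejected:edge`, never silently dropped.
* **Artifact rejection** flags epochs whose scalp samples *strictly*
  exceed ±150 µV ("exceeding" read literally; boundary samples pass; EOG
  channels are not screened because they enter no analysis).
* **CSD** is a Perrin-style spherical spline: G and H matrices from a
  Legendre series (default 50 terms), spline stiffness m = 4,
  regularization λ = 1e-5 added to G's diagonal, sum-to-zero coefficient
  constraint solved as a KKT system, output scaled by `head_radius⁻²`
  (0.09 m default) in µV/m². The transform is linear, exactly
  reference-free, and matches both the analytic surface-Laplacian
  eigenvalue l(l+1)/r² on spherical harmonics (≤ 2 % at interior
  electrodes with small λ) and MNE's implementation to machine precision.
  These parameters are not documented for the original analysis; they are
  common literature defaults, recorded in every run log, and configurable.

## ERP measurement

Peaks are the *global* extremum of the subject's condition-average
waveform within the closed window (N2/Ne/CRN negative, P3/Pe/Pc
positive), ties resolved to the earliest sample, latency at 2 ms
resolution. AUC is the signed trapezoidal integral over the same window —
signed rather than rectified so that negative-going and positive-going
area comparisons keep their direction; this choice is configurable in
spirit (the function operates on whatever window/electrode it is given).
Difference scores are withhold − correct (ΔN2, ΔP3) and error − correct
(ΔNe/ERN, ΔPe); peak-to-peak is Pe − Ne (or Pc − CRN) on amplitude and
latency. Any display smoothing is plotting-only and never enters
measurement.

## Decoding

Features are channel-major concatenations of all scalp channels' 5 samples
per 10 ms window (305 features for 61 channels). Folds are
*class-stratified* — a deliberate deviation from a plain random 90/10
split, because with small balanced samples unstratified folds can lose a
class entirely. The shuffled-label null permutes the *training* labels
independently for every cross-validation step, leaving test labels intact,
which yields an unbiased empirical chance level per subject. Decoding runs
on CSD-transformed epochs by default (`decode_on_csd` switches to
voltage); the SVM is `sklearn.svm.SVC(kernel="linear", C=1)` with a
tightened solver tolerance so refits are reproducible, and no feature
standardisation by default. One master seed expands through
`numpy.random.SeedSequence` into per-subject, per-repeat, and per-shuffle
streams; every decode is bit-reproducible.

## Statistics

The independent t is pooled-variance Student's (df = n1 + n2 − 2), with
Welch behind a flag. The JZS Bayes factor integrates the noncentral-t
likelihood over a zero-centered Cauchy(0.707) effect-size prior by
adaptive quadrature (split at the likelihood peak); the paired form uses
n = pairs. The 2 × 2 mixed ANOVA uses the classical decomposition —
between effect against subjects-within-groups, within/interaction against
the subject × condition residual — which makes two identities exact and
testable: group F equals the squared pooled t on subject means, and
interaction F equals the squared pooled t on difference scores.
Greenhouse–Geisser epsilon comes from the double-centered covariance
eigenvalues (identically 1 for two levels). Correlation analyses use a
fixed alpha of 0.025, decoding group comparisons 0.05/40 = 0.00125.

A note on published Bayes factors: reported t statistics in the
performance-monitoring literature are sometimes Welch-style while the
accompanying JZS Bayes factors derive from the pooled Student t of the raw
data. The acceptance suite therefore recomputes the Student t from
published group means/SEMs before applying the JZS integral; one published
value whose summary statistics are printed to only one decimal can only be
bracketed by the interval that rounding induces, not point-reproduced.

Bayesian repeated-measures ANOVA Bayes factors are out of scope (they
require g-prior model averaging disproportionate to their role); the
report marks those cells as not reproduced.

## Problem sizes in tests

Monte-Carlo tests run at sizes chosen to keep the suite fast while leaving
tolerances honest: 100 sessions for behavioral calibration and ΔPES
recovery (tolerances scale with the Monte-Carlo standard error), 40 runs
for decoding chance calibration, 200 synthetic-curve cohorts of 8 + 8
subjects for family-wise error control, and a 2 + 2-subject, 120-trial
cohort for the end-to-end pipeline check. Full-scale runs (24 + 32
subjects, 360 trials) use the identical code path via `RunConfig`
defaults.

## Known limitations

* The ocular stand-in removes any scalp signal linearly predictable from
  EOG, which can attenuate genuine frontal ERP variance.
* The CSD is applied to epoched (not continuous) data; with the default
  windows this is equivalent up to baseline handling.
* The behavioral agent has no sequential structure beyond one-trial-back
  slowing (no learning, fatigue, or time-on-task trends).
* `classify_phase` splits sub-acute vs chronic at 28 days; recruitment
  below 4 days is rejected rather than modelled.
* The inclusion rule for ΔPES attrition (subjects with no qualifying
  post-error pair return NaN and drop out of that comparison) is this
  package's reading; the field has no single convention.
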