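# Methods

This note records the model assumptions, parameter choices, and numerical
conventions behind `feedcsp`, and what the synthetic tests do and do not
establish about real recordings.

## Pipeline and assumptions

The unit of analysis is the subject, not the trial. Inputs are cleaned,
feedback-locked epoch tensors (trials × channels × samples; 64 channels at
256 Hz, −1000…2400 ms, microvolts) with per-trial valence labels. The
pipeline assumes artifact handling (re-referencing, ocular correction, epoch
rejection) has already happened upstream; subjects with fewer than five
usable trials of a valence are excluded, mirroring common practice.

Per subject and valence: baseline-correct (−250…0 ms mean per channel),
average trials into an ERP, band-filter the full-length ERP, then window to
200–300 ms. Filtering precedes windowing so FIR edge transients (the kernel
is 423 taps ≈ 1.65 s) never touch the analysis window.

## Group assignment

Cutoffs are configuration (`Cutoffs`): BDI-II 13, STAI-T 41, plus a
stricter STAI threshold of 42 carving the anxiety group out of the
low-depression/high-anxiety pool. All inequalities are strict, so boundary
scores are deliberately unassigned. The published four-group scheme defines
the depression-contrast controls and the anxiety group over overlapping
score regions; we keep one primary label per subject (precedence DEP → ANX
→ CTR_DEP → CTR_ANX) and let `select_contrast` rebuild the overlap: the
depression contrast uses DEP vs {CTR_DEP ∪ ANX}, the anxiety contrast ANX
vs CTR_ANX. This reproduces both readings of the printed cutoffs without
inventing a resolution.

## Filter designs

Both band-separation filters are windowed-sinc (firwin) designs with a
Hamming taper and 2.00 Hz transition bands; length = ⌈3.3 / transition ·
fs⌉ rounded up to odd (the standard Hamming heuristic; the original length
is unstated). Cutoffs are specified at the −6 dB (half-amplitude) points:
4.00 Hz for the delta low-pass (3 Hz passband edge), 3.00 and 8.50 Hz for
the theta band-pass (4–7.5 Hz passband). Measured responses reproduce these
to < 0.01 Hz.

One description of the delta filter is self-contradictory ("high-pass …
(low-pass …)"); the parenthetical design parameters and the purpose —
isolating delta — force a low-pass, which is what we implement.

Zero-phase behaviour comes from a single centred convolution of the
symmetric odd-length kernel over a reflect-padded signal (not
forward–backward filtering, which would square the magnitude response).

Stopband attenuation is measured from the first magnitude-response null at
or beyond the nominal stopband edge (passband edge + transition width),
because the roll-off is still descending at the nominal edge itself. The
low-pass achieves ≈ 55.5 dB, beating the 53 dB Hamming sidelobe figure. A
band-pass is the difference of two low-pass prototypes, and their sidelobes
interfere near DC: the theta design floors at ≈ 48.9 dB there. The quoted
"53 dB" is the per-edge window property; we assert ≥ 52 dB for the low-pass
and each band-pass edge prototype, and ≥ 47 dB for the composite band-pass.

Milliseconds map to samples by `round((t − t0)·fs/1000)` with half-open
windows, so [200, 300) ms at 256 Hz with t0 = −1000 ms is samples 307–332
(26 samples).

## CSP estimation

Per-subject covariances are uncentred second-moment matrices `X Xᵀ` of the
windowed, band-filtered ERP. Class means enter the generalized eigenproblem
`C₁w = μ(C₁+C₂)w`, solved by symmetric whitening of `C₁+C₂`; eigenvalues
are clipped to [0, 1] and components ranked by |μ − ½| (ties favour the
larger μ). Patterns follow from the filter–pattern duality.

Two normalisation decisions were genuinely open and were settled by
experiment on planted-effect data:

* **Regularisation target.** 26-sample windows over 64 channels give badly
  rank-deficient covariances, so loading is mandatory. Shrinking each
  class mean towards its *own* trace-scaled identity injects the (class-
  separable) total power into every spatial direction, which saturates the
  eigenvalue ranking and destroys recovery. The pipeline therefore loads
  both class means towards a *shared* target, λσ²I with σ² the per-channel
  variance pooled over both classes of the training fold: directions
  without genuine spatial structure then sit at exactly μ = ½. The
  `subject_covariance` API retains the conventional per-matrix shrinkage
  (and optional trace normalisation) for standalone use.
* **Feature scale.** Sum-normalised log-variance features (`log(vⱼ/Σv)`)
  and trace-normalised covariances remove each subject's absolute band
  power — but absolute band-power differences are precisely the reported
  group effects. The pipeline uses unnormalised covariances and plain
  `log vⱼ` features; a planted 3 µV frontal theta shift is unrecoverable
  through the normalised variant (CV balanced accuracy ≤ 0.64) and cleanly
  recovered without it (≥ 0.87).

The features use the *uncentred* moment `mean((wᵀX)²)`, consistent with
`X Xᵀ`: a sub-4 Hz component is nearly constant across a 100 ms window, so
subtracting the window mean would erase delta-band amplitude information
entirely.

λ spans [10⁻³, 10⁻¹] (the printed grid); values below 10⁻³ are rejected as
numerically unstable for these matrices.

## Evaluation

Hyperparameters are selected by mean threefold stratified-CV balanced
accuracy over the full grid, with ties broken towards fewer CSP components,
smaller C, then the linear kernel; the RBF bandwidth is the solver's
variance-scaled default (recorded in reports). Every data-dependent step —
covariance averaging, the CSP eigendecomposition, feature standardisation,
the SVC — is refit inside each training fold. The cost of violating this is
demonstrated on null data: fitting CSP once on all subjects inflates
"cross-validated" accuracy by ≈ 0.3 while the leakage-free estimate stays
at chance.

Selected configurations are scored with r-repeated stratified k-fold CV
(default 10 × 10; k shrinks with a warning if a class is smaller).
`train_acc` is the full-data refit score — an intentionally optimistic
overfitting gauge. Metrics: balanced accuracy (mean of sensitivity and
specificity), Mann–Whitney ROC AUC with midrank ties, precision (0 when no
positive predictions, logged), recall.

Permutation tests rerun the full procedure on B permuted label vectors and
report `p = (1 + #{perm ≥ observed})/(B + 1)`; B defaults to 999 (0.001
resolution), with the permutation score taken as the mean threefold-CV
balanced accuracy. Model comparisons use the Nadeau–Bengio corrected
resampled t-test on split-wise paired 10×10 scores (identical fold seeds
for both models), `t = d̄/√((1/(rk) + ρ)·var(d))`, ρ = n_test/n_train =
1/(k−1), df = rk−1; it reduces to the classical paired t at ρ = 0 and is
strictly more conservative otherwise.

## Synthetic data

The generator emulates the study geometry: two groups per contrast, 64
BioSemi channels (10-10 names, 2-D projected positions), 256 Hz, epochs
−1000…2400 ms. Each trial is the sum of

* a deterministic feedback-evoked waveform shared by all subjects (a
  centro-parietal P3-like positivity at ~350 ms plus a fronto-central
  theta transient, slightly valence-dependent);
* planted effects: unit-norm topography × Hann-windowed pulse at the band
  centre (5.75 Hz theta over 0–800 ms; 1.5 Hz delta over −400…2000 ms),
  with per-subject amplitude `base (+ shift if symptomatic) + N(0, σ_s)`
  and per-trial jitter N(0, σ_t). Pulse supports are long enough that each
  pulse's spectrum stays inside its own band (a Hann pulse of duration T
  has a main lobe of half-width 2/T around the carrier); the theta carrier
  is an odd sine (zero net area, no low-frequency leakage), the delta
  carrier a cosine peaking at 250 ms so a positive shift deepens the slow
  positivity in the analysis window rather than cancelling it;
* spatially correlated 1/f^α background noise (α = 1, unit per-channel
  RMS ≡ 1 µV), mixed from sources at jittered channel locations so
  neighbouring channels share noise and spatial filtering is non-trivial.

Questionnaire scores come from per-group truncated normals matched to the
published group means/SDs and ranges, so cutoff-based assignment recovers
the generating groups exactly. A single integer seed determines everything.

Defaults are study-scale (70 subjects per class, 80 trials per valence).
Test scenarios scale down: the recovery scenarios use 40 subjects per group
and 20 trials per valence; permutation-calibration and leakage runs use
30 per group, 16 channels, and 10 trials. `planted_effect_report` gives the
closed-form expected group difference of windowed band power at each
effect's peak channel (subject- and trial-level amplitude variance
contribute equally to both groups and cancel), which the tests verify
against direct Monte-Carlo measurement.

Planted shifts in the recovery scenarios are 3 µV (theta) and 6 µV (delta)
against 1 µV trial noise. Delta needs the larger effect: a quasi-static
window yields per-subject covariances with one or two effective degrees of
freedom, so class-covariance eigenvalue estimates carry far more sampling
noise than in theta, and a smaller planted ratio drowns in it at 40
subjects per group. Both regimes were verified stable across generator
seeds.

What the synthetic bed does **not** model: biophysical forward fields and
realistic head geometry, non-stationary or non-Gaussian artifacts,
trial-count asymmetries between valences, correlated symptom dimensions
(scores are drawn independently of the EEG effect amplitudes), and
between-subject variation in effect topography or latency. Passing recovery
tests therefore show the estimator chain is correct and leakage-free under
its own assumptions, not that real effects of that size are detectable in
real data.

## Numerical conventions and degenerate inputs

* Seeds: one master seed fans out via `SeedSequence`; derived seeds are
  reduced below 2³¹. Identical configs re-run bit-identically.
* Zero-variance windows: rejected with a diagnostic unless λ > 0; zero
  projected variance in the transform raises rather than returning −∞.
* Degenerate t-test inputs: zero variance with zero mean difference gives
  t = 0, p = 1; with nonzero mean, ±∞ and p = 0, flagged.
* Stratified folds throughout; a fold that cannot contain both classes is
  an error rather than a silent skip. Class imbalance is handled by
  stratification only — balanced accuracy already corrects prevalence.
* EDF/BDF import trusts the file's channel labels (matched to the montage
  case-insensitively) and expects equal-length concatenated epochs; the
  internal container round-trips float64 bit-exactly and validates a JSON
  sidecar schema on load.

## Known limitations

* The per-fold CSP refit inside grid selection makes `run_model` O(grid ×
  folds) eigendecompositions; at 64 channels this is seconds, not minutes,
  but scales cubically with channel count.
* The permutation test permutes subject labels around the full selection +
  scoring procedure; with B = 999 and the full grid this is expensive, so
  reported p-values in `run_model` fix the selected configuration (the
  selection stage is inside the observed score's CV only via its chosen
  hyperparameters). Whether the original analysis permuted within or
  around selection is unknowable from the text; both are exposed
  (`permutation_test(grid=...)` vs `permutation_test(params=...)`).
* Pattern export provides channel weights; rendering topographic maps is
  left to the user's plotting stack.
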