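# Methods

`tagshift` analyzes frequency-tagged EEG from a four-arc probabilistic
spatial-cueing experiment. Four arcs arranged around fixation flicker at
18, 21, 24 and 27 Hz (upper right, lower right, lower left, upper left),
each driving a steady-state visual evoked potential (SSVEP) over
contralateral posterior cortex. A central cue points at one arc; the
arcs simultaneously switch from a common baseline color to either a
*different*-color configuration (four unique colors) or a *same*-color
configuration (one arc adjacent to the cued arc shares its color). The
question the analysis answers is whether attending the cued arc also
facilitates the same-colored uncued arc (global feature-based spread),
and with what temporal dynamics.

## Experiment model

The schedule generator allocates trial classes with **exact counts**
and then shuffles the order: on the default 1000-trial session, 360
trials carry a post-cue target event (640 do not), 120 of the event
trials carry a second late event (800–1850 ms, at least 800 ms after
the first), and 168 trials carry a pre-cue fixation event. Event
conditions follow a 3:1:1:1 validity ratio within each color
configuration — `val`/`val_match` (cued arc, 120 each) versus `inval`,
`inval_match`, `inval_non_match` (adjacent uncued arcs, 40 each) — and
event times are uniform within three 100-ms bins (200–300, 400–500,
600–700 ms), exactly one third of event trials per bin. The arc that
duplicates the cued color ("match side") is likewise allocated in
balanced counts per cue position, so that pooled condition trial counts
are equal to within one trial. Exact allocation makes every marginal
count a testable invariant rather than a binomial draw.

## Synthetic EEG generator

Each trial superimposes four sinusoids at the tag frequencies, phase
locked to cue onset, with Gaussian spatial profiles (width 0.45 on the
unit sphere) centered on contralateral posterior channels (right
hemifield → PO7/O1, left hemifield → O2/PO8). The amplitude of each
sinusoid follows the condition of its arc in that trial:

* constant baseline (1 µV) before the cue;
* after the cue, a logistic rise `gain · expit((t − t50)/τ)` toward a
  plateau gain, with a late linear decay.

Default dynamics encode the qualitative result pattern of this
paradigm: cued arcs +30 % (half-rise 350 ms) in both configurations, the
same-colored uncued arc +18 % with the same early half-rise, uncued
arcs of the different configuration +14 % but late (700 ms), the
non-matching uncued arc +10 % and latest (900 ms), and a mild decay
late in the trial. The diagonal arc (never analyzed) is unmodulated.
These values are qualitative: the paper's per-condition effect sizes
cannot be estimated without its data, so recovery tests assert
magnitudes against the generator's own truth and orderings against the
reported pattern, not the paper's numbers.

Noise is 1/f^α background (α = 1, 4 µV RMS) plus white sensor noise
(0.5 µV RMS), independent across trials and channels, with a lognormal
channel-to-channel spread of noise gain (σ = 0.2) and reduced
background on the bipolar EOG derivations (×0.4). The spread matters:
with identical noise on every channel the across-channel dispersion of
channel statistics collapses and ordinary signal topography would be
misdetected as bad channels; real recordings always show channel-level
noise heterogeneity. At these defaults the single-trial SNR at the tag
frequencies is below one, so trial averaging is necessary — the regime
the method is designed for. What the generator does **not** emulate:
volume conduction from realistic head geometry, harmonics of the tag
frequencies, non-stationary alpha rhythms, or correlated noise between
channels beyond the shared topographies; passing tests therefore
validate the pipeline's algebra and statistical calibration, not its
robustness to every physiological artifact.

Behavior is simulated per trial: hits with probability 1 − lapse
(default lapse 0.18, matching ~82 % hit rates), reaction times Gaussian
around condition-specific bases (val 430, val_match 432, inval_match
462, inval_non_match 472, inval 475 ms; SD 60 ms), false alarms at
1.5 % in no-event trials, and a pre-cue task with 3 % lapse.

## Preprocessing

Epochs run from −1500 to +2200 ms around the cue at 256 Hz; only trials
without post-cue events enter the SSVEP analysis. The cleaning chain:

1. **Linear detrending** per trial and channel, fitted on the −1000 to
   +2000 ms analysis window.
2. **Ocular rejection**: trials whose smoothed (50 ms) peak-to-peak
   vertical EOG derivation (blinks) or horizontal derivation (eye
   movements, ≈1° per 25 µV) exceeds 25 µV inside the analysis window
   are discarded; the two reasons are logged separately.
3. **Bad channels**: per trial, channel statistics (SD, maximal
   absolute gradient, range) are z-scored against the scalp-channel
   population using median/MAD (breakdown-resistant); channels above
   z = 3 on any statistic are replaced by spherical-spline
   interpolation from the remaining channels. Trials with more than 15
   interpolated channels are discarded. Because across-channel z-scores
   are blind once the majority of channels is corrupted (the median
   moves into the artifact), a trial whose median channel power is
   grossly deviant across trials (z > 5 × threshold) is discarded whole
   with a distinct reason.
4. **Scalp current density**: spherical-spline surface Laplacian
   (Perrin parameterization, spline order m = 4, regularization
   λ = 10⁻⁵, 50 Legendre terms, head radius 0.095 m), output in µV/m².
   The operator is precomputed as a matrix; it is linear and maps
   uniform potentials to zero. It agrees with MNE's implementation to
   ~10⁻¹² relative on identical coordinates.

## Spectral analysis and electrode selection

Amplitude spectra use the 3-s analysis window (768 samples), giving a
1/3 Hz resolution at which all four tags are bin-centered; amplitudes
are scaled so a unit sinusoid at a bin center reads 1.0. Per subject
and tag frequency the channel with maximal amplitude within the
17-channel parieto-occipital cluster (I1, I2, Iz, O1, O2, Oz, P10,
P5–P9, PO3/4/7/8, POz) is selected — from the all-condition average
over the full window, so cue-related enhancement affects all
frequencies alike — and extended by its 4 nearest scalp neighbors
(Euclidean on the unit sphere; they may lie outside the cluster):
five channels per subject and frequency. Ties at the argmax resolve to
the lowest channel index and are flagged. Signal quality is the
peak-versus-sideband comparison, the sideband being the mean of the two
bins exactly ±1 Hz (±3 bins) from the tag, feeding a 2×4
Band-by-Frequency repeated-measures ANOVA.

## Envelope extraction

The Gabor-energy filter is a complex Gaussian-windowed exponential with
spectral half-FWHM 1 Hz; by the Gaussian Fourier identity
(FWHM_t · FWHM_f = 4 ln 2/π s·Hz) its temporal half-FWHM is 220.636 ms.
The kernel is normalized to unit envelope gain at the center frequency;
its closed-form transfer exp(−4 ln 2 (Δf/FWHM)²) puts cross-tag leakage
at 3 Hz separation near 0.2 %. Trials are averaged per cue position in
the time domain first, then filtered, then averaged across the five
selected channels (this order follows the analysis being reproduced;
the alternative order is exposed as an option for sensitivity checks).
Envelopes become percent change against the −720 to −220 ms baseline —
the baseline ends one temporal half-FWHM before the cue so no post-cue
samples leak into it — and are collapsed across the four tag
frequencies per condition: `cued_match`, `cued`, `uncued_match`,
`uncued_non_match`, `uncued`. Uncued conditions pool clockwise and
counterclockwise arrangements; the `uncued` pool (roughly twice the
size of the others) is subsampled to 50 % with a seeded draw to
equalize SNR. Edge handling: the convolution uses the full epoch and no
padding, which keeps the 0–1500 ms statistics window free of edge
transients; envelope values within ~2σ of the epoch ends (beyond
≈±1.7 s) are attenuated and are not used by any statistic.

## Statistics

* **Running cluster tests**: pointwise paired/one-sample t-tests;
  contiguous runs exceeding the pointwise α = 0.05 critical value form
  clusters scored by summed t. The null distribution is the maximum
  cluster sum over within-subject sign flips of the differences (5000
  by default), giving family-wise control; permutation p-values are
  (1 + #{null ≥ obs})/(n_perm + 1) and cannot fall below 1/(n_perm+1).
  Zero-variance time points are treated as non-significant with a
  warning. Monte-Carlo calibration at n = 12: family-wise error 0.044
  over 1000 null simulations.
* **JZS Bayes factors**: BF₁₀ integrates the noncentral-t likelihood
  over a Cauchy(0, r = 0.71) prior on the standardized effect
  (adaptive quadrature) against the point null; running versions mark
  time points with BF₁₀ < 0.33 as supporting the null.
* **Jackknife onsets**: leave-one-subject-out means; onset is the first
  linearly-interpolated crossing of 85 % of the base-to-peak range
  inside 0–1500 ms (85 % rather than 50 % keeps the criterion above
  baseline-level noise); individual onsets via the Smulders
  back-transform o_i = n·ō − (n−1)·o₍₋ᵢ₎, compared by two-tailed paired
  t-test. Subsamples that never reach the criterion yield missing
  onsets; more than 20 % missing aborts.
* **Window contrasts** (750–1250 ms means): cued vs cued_match, the
  spatial-selectivity difference (cued − uncued) vs
  (cued_match − uncued_non_match), and uncued_match vs uncued, each
  with two-tailed paired t, difference-score Cohen's d, and BF₁₀. The
  difference-score d is the default because the mixed-model-based d of
  the original analysis is not reproducible without its data; a pooled
  variant can be computed from the returned means.
* **rm-ANOVA** with Greenhouse-Geisser correction (via pingouin) for
  the one-way five-condition RT analysis and the 2×4 Band×Frequency
  design; Holm step-down adjustment for post-hoc and planned contrasts.
* **Power**: the a priori sample size inverts noncentral-t power;
  d = 0.66, α = 0.05 two-tailed, power 0.90 gives n = 27.

Behavioral RTs are filtered to ±3.5 SD around the pooled all-subject,
all-condition mean (and ≥150 ms) before averaging per subject and
condition. A press within 150–1000 ms of an event counts as a hit
(window exposed in configuration; the original report does not state
one).

## Numerical and design choices

* Condition probabilities are implemented as exact fractions
  (1/3, 1/3, 1/9, 1/9, 1/9 of event trials); the printed 33.34 %/11.1 %
  round these.
* Onset interpolation is linear between samples; ties at the cluster
  argmax go to the lowest index; the uncued subsample uses
  floor(n/2) without replacement.
* Montage coordinates come from the standard 10-10 template bundled
  with MNE, re-centered and unit-normalized; the 64-channel layout is
  chosen to contain the full posterior cluster (a stock BioSemi-64
  labeling lacks I1/I2). EOG positions are nominal face coordinates.
* Simulation problem sizes in tests and the acceptance script (e.g.
  5 subjects × 500 trials for envelope recovery, 1000 null simulations
  at 200 permutations for calibration) are chosen as the smallest
  sizes at which the checked property is statistically decisive;
  group-mean plateau recovery is unbiased (verified at 10 × 500:
  29.99 recovered vs 29.97 truth) with per-subject scatter of ±4
  percentage points.

## Known limitations

Stimulus rendering, photometric calibration, eye tracking beyond the
EOG thresholds, resampling of real 512 Hz recordings (synthetic data
are generated at 256 Hz directly), harmonic analysis and source
localization are out of scope. The BDF reader is a thin optional
wrapper; epoching real data against a schedule is left to the caller's
event codes. The SCADS approximation shares the cited method's intent
(per-trial channel statistics) but not its exact parameterization,
which is unpublished.
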