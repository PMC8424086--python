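# Methods

This note records the models, conventions and design decisions behind
`kcindex`, in the order the pipeline applies them, together with what the
synthetic validation does and does not establish.

## Recording model and synchronization

A subject is four tri-axial accelerometer streams (left/right wrist,
left/right ankle), nominally 150 Hz for 10 min, each with device-local
timestamps. Device clocks of one subject agree to < 1 ms. Synchronization
linearly interpolates all four streams onto one uniform grid at the target
rate over the *intersection* of the limb spans, left-aligned to the latest
start so no stream is ever extrapolated. Linear interpolation is adequate
because clock discrepancies (< 1 ms) are far below one sample period
(6.7 ms); its error on band-limited movement signal is orders of magnitude
below sensor noise, and it is order-preserving. Recordings shorter than the
configured minimum duration (default 600 s, with a 5% tolerance) are
rejected; the minimum is configurable because behavioral state can end a
session early and the analysis itself has no hard length requirement beyond
filter settling.

Acceleration is stored internally in m/s² (declared unit converted on read,
1 g = 9.80665 m/s²). All six features are invariant to the overall
acceleration scale, so the unit choice cannot affect any result; this is
asserted end to end in the tests rather than assumed.

## Gravity removal

Each axis is high-pass filtered at 0.05 Hz to remove the gravitational/
postural component. The filter family and order are a package choice: a
4th-order Butterworth applied forward-backward (zero phase). Zero phase
matters because the inter-limb statistic downstream is a *timing*-sensitive
cross-correlation of jerk; a causal filter would add a frequency-dependent
lag. Butterworth is maximally flat in the passband where general-movement
energy lives (~0.1–10 Hz). Edges are padded by odd reflection over three
filter time constants (3/0.05 Hz = 60 s) before the forward-backward pass;
odd reflection continues the signal without introducing a step at the
boundary, suppressing startup transients on 10-min records. A warning is
emitted when a recording is shorter than three time constants. Filtering is
applied after synchronization, since the IIR filter assumes uniform
sampling.

Dead sensors are caught before filtering: a limb whose raw signal is
constant on every axis raises a degenerate-signal error (after high-pass
filtering such a limb would look like numerically tiny noise and produce
meaningless features).

## Features

**Per-limb kurtosis of PC1.** The centered 3-axis signal is projected on
the eigenvector of the largest eigenvalue of its 3×3 sample covariance
(sign fixed by making the first nonzero loading positive — kurtosis is
sign-invariant, the convention only makes runs deterministic). Kurtosis is
the Pearson (non-excess) biased moment form m₄/m₂²: baseline 3 for a
Gaussian, lower bound 1 (attained by symmetric two-point signals),
unbounded above for heavy tails. Kurtosis is computed on the whole record,
not sub-windows. The choice of the biased Pearson convention matches the
default of the numerical environments this kind of signal processing is
typically done in, and keeps the Gaussian-reference reading (narrow vs wide
bell) simple.

**Pair jerk cross-correlation.** Jerk is the per-axis first difference
divided by the sampling interval; the Euclidean norm across axes makes it
invariant to sensor orientation, which is essential because left and right
bands are strapped on with mirrored, unknown orientations. No smoothing is
applied: the high-pass already removed drift, and noise that is independent
across limbs cannot *create* inter-limb correlation (it only shrinks it
toward zero, uniformly across groups). For each pair (upper = wrists,
lower = ankles) both jerk series are mean-centered and cross-correlated
with coefficient normalization (product of series norms, so lag 0 equals
the Pearson correlation); the statistic is the maximum over integer lags
within ±2 s. The window tolerates the small latencies seen in
cramped-synchronized movement while excluding spurious far-lag maxima; it
is configurable (`max_lag_s`).

Numerical notes: the peak of the coefficient-normalized cross-correlation
of a k-sample-shifted copy is 1 − O(k/n) because the norms cover the full
series; tests therefore use shifts ≪ n. Zero-variance inputs raise
degenerate-signal errors naming the limb or pair.

## The KC index

Features are combined with equal weights after dividing each by its cohort
range (max − min over all subjects), ×100. The default implements exactly
this range division **without subtracting the cohort minimum**; a full
min-max variant ((x − min)/range) is available via
`normalization="min_max"`. Within a fixed cohort the two differ per feature
by an additive constant, so rankings, ROC curves and AUC are identical;
cutoff *values* are not transferable between the two conventions. The
range-divide form is the package default; the choice is recorded in every
output's config hash.

The index is cohort-referenced: adding a subject can change every score
through the range denominators. Two scoring modes exist: refit (cohort
grows, normalization refitted) and frozen (a stored `CohortNormalization`
is applied to new subjects, leaving existing scores untouched) — the frozen
mode is what a deployed cutoff requires. A cohort in which some feature has
zero spread cannot be normalized and is rejected.

## Cutoff and uncertainty

Abnormal (PR ∪ CS) is the positive class and scores high. ROC operating
points are evaluated at all midpoints between consecutive distinct scores
(±∞ sentinels close the curve); a subject is called positive when its score
is strictly above the threshold. AUC is the Mann–Whitney concordance
probability with ties counted ½, identical to the trapezoidal area under
the empirical curve. The operating cutoff maximizes Youden's
J = sensitivity + specificity − 1, with ties broken toward higher
specificity, then the lower threshold; only finite midpoints are candidate
cutoffs. Confidence intervals for both the cutoff and the AUC are 95%
percentile bootstrap over 1,000 unstratified resamples drawn with
replacement at the original sample size; resamples missing a class are
redrawn (so the effective resample count stays at n_boot), and the cutoff
is recomputed on a fresh ROC per resample. Stratified resampling is
available as an option but is not the default. All resampling is driven by
seeded generators; fixed seed ⇒ byte-identical outputs.

## Synthetic cohort generator

The generator exists to validate the pipeline's construction — no clinical
recordings are distributable — and encodes the three clinical classes as
parameter regimes of one movement model: per limb, burst onsets are the
superposition of a shared Poisson stream (rate `coupling · burst_rate`)
copied to all limbs with per-limb Gaussian timing jitter, and an
independent stream (rate `(1 − coupling) · burst_rate`). Each burst is a
Hann-windowed sinusoid with Gamma-distributed amplitude, duration and
frequency (group-specific means and CVs) in a random 3-D direction; shared
bursts reuse one mark across limbs, so coupled limbs emit the same jerk
envelope regardless of direction. Gravity is a ~9.81 m/s² vector
random-walking slowly on the sphere (independent per sensor), and white
Gaussian sensor noise and per-device clock offsets (uniform within
±0.4 ms) complete the signal. Each subject draws from a counter-based
substream of the cohort seed, so subject data are reproducible regardless
of cohort composition.

Default group regimes (frozen):

| group | burst rate (Hz) | amp CV | dur mean (s) | dur CV | freq (Hz) | coupling | jitter (s) |
|------|------|------|------|------|------|------|------|
| N  | 0.25 | 0.60 | 1.2 | 0.60 | 1.5 | 0.1 | 0.10 |
| PR | 0.08 | 0.15 | 0.8 | 0.15 | 2.5 | 0.1 | 0.10 |
| CS | 0.08 | 0.15 | 0.8 | 0.15 | 2.5 | 0.9 | 0.05 |

Shared across groups: burst peak amplitude mean 2 m/s² (typical of
moderate infant limb movement; the features are scale-free so only its
ratio to the noise floor matters), sensor noise 0.01 m/s² RMS (a realistic
MEMS accelerometer noise floor — note that differencing to jerk multiplies
white noise by the sampling rate, so this value, not the movement
amplitude, controls how much the jerk correlation is diluted), gravity
wander amplitude 0.1 (dimensionless walk scale) with a 120 s timescale
(supine infants change posture rarely; faster or larger wander leaks
through the 0.05 Hz high-pass and floods the variance of sparse-movement
records).

Construction validity, verified by test: expected pair cross-correlation
increases strictly with `coupling`; expected PC1 kurtosis increases
strictly as the burst rate decreases (sparser movement, at every
amplitude-variability level) and along the joint sparser-and-more-
stereotyped axis of the (burst rate, amp CV) grid — the N→PR direction.
One subtlety is worth recording: at *fixed* burst rate, lowering the
amplitude CV alone slightly **lowers** kurtosis, because for any burst
mixture the kurtosis carries a factor E[A⁴]/E[A²]² ≥ 1 that is minimized
by constant amplitudes. Stereotypy raises kurtosis only through its
covariates (sparsity, shorter bursts), which dominate in the class
regimes; the construction target is therefore the joint axis, not the
amplitude-CV axis in isolation.

What the simulator does *not* emulate: joint kinematics and limb linkage,
trunk movement, behavioral-state structure (sleep/cry segments),
non-white sensor error (bias instability, temperature drift), or movement
classes beyond the three regimes. Passing the synthetic acceptance suite
therefore shows the pipeline measures what it claims on signals with the
assumed burst/coupling structure; it does not certify clinical
performance, which requires real cohorts.

## Problem sizes used in validation

The validation suite uses scaled-down recordings chosen for statistical
sufficiency: closed-form filter checks run on full-length 600 s signals
(frequency resolution at 0.005 Hz requires them); the invariance suite
uses a 6-subject cohort of 120 s recordings (invariances are exact
properties, not statistical ones); simulator grid checks use 150 s
recordings with 8–10 seeds per cell; the default-cohort structure test
runs all 68 subjects at 150 s, and `scripts/acceptance.py` at 300 s
(kurtosis estimates from sparse burst processes are the noisiest
ingredient; 300 s halves their sampling error relative to 150 s while the
group-level conclusions are unchanged across these sizes).

## Known limitations

* The KC index has no absolute scale: scores, and hence cutoffs, are
  meaningful only relative to a cohort normalization (or a frozen one
  shipped with the cutoff).
* Kurtosis of sparse burst processes converges slowly; short recordings
  give noisy per-subject features, and group separation degrades below
  ~2–3 min of usable signal.
* The jerk correlation statistic saturates toward its noise-diluted
  ceiling rather than 1 on real sensors; comparisons are valid within a
  hardware configuration, not across noise floors.
* Multi-class discrimination (N vs PR vs CS) is deliberately out of scope;
  the method targets the clinically actionable normal-vs-abnormal call.
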