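# Methods

This note documents the models, conventions and numerical choices behind
`capscore`, in the spirit of a package's statistical methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute themselves.

## Problem setting

CAP scoring assigns every second of a NREM-sleep EEG recording to
background (B) or to an activation phase of subtype A1 (high-voltage slow
waves, amplitude at least one third above background), A2 (mixture), or
A3 (low-voltage fast rhythms). Valid A-phases last 2–60 s. The classes
are heavily imbalanced — background typically covers ~70% of the night —
so evaluation centers on the weighted accuracy
WAC = (1/K) Σ_j n_jj / n_{+,j} (mean per-true-class recall), with plain
accuracy reported alongside for comparability.

## Time conventions

Seconds are 0-based with half-open epochs [t, t+1). All features are
emitted at exactly 1 Hz on the shared epoch grid; trailing windows end at
t+1 s. Seconds earlier than a trailing window's nominal length use a
growing window over the samples available so far ("warm-up"), so every
feature row has one value per second and no row needs alignment padding.

## Band filtering

Third-order Butterworth band-passes (BB 0.3–35, δ 0.3–4, θ 4–8, α 8–13,
σ 13–16, β 16–35 Hz), realized as second-order-section cascades — the
0.3 Hz edge at 512 Hz is numerically ill-conditioned in transfer-function
form. Filtering is **causal** (single pass): the amplitude features are
defined on past samples, and a zero-phase forward–backward pass would
leak future signal into them. The resulting group delay is accepted; it
is identical across bands of a comparison and small relative to the 2 s
minimum event duration.

## Features (55 rows)

* **C_{φ,τ}, C_{φ,τ₀}** — mean *rectified* amplitude (mean |x|) of the
  band signal over trailing 60 s / 2 s windows at 1 s steps (59 s / 1 s
  overlaps). "Mean amplitude" is not further specified in the CAP
  literature's descriptor lineage; mean rectified amplitude is the
  conventional estimator there.
* **MMSD_φ** = (C_{φ,τ₀} − C_{φ,τ})/C_{φ,τ}, with an ε = 1e-12 µV floor
  on the denominator. Scale-invariant by construction.
* **TEO_φ** — Teager energy ψ[n] = x[n]² − x[n−1]x[n+1] over the whole
  series (the operator is non-causal at the sample level), then the
  maximum per 1 s epoch; the two edge samples replicate their neighbors.
* **ZCR_φ** — strict sign changes within each epoch; a zero sample takes
  the previous nonzero sign (leading zeros the first nonzero sign), and
  pairs spanning an epoch boundary belong to neither epoch.
* **LZC_φ** — epoch binarized at its own median (values strictly greater
  → 1), then LZ76 exhaustive parsing; the feature is the raw phrase
  count, unnormalized. A constant epoch parses to 2 phrases.
* **Max_freq / Mean_freq / Spec_area** — magnitude spectrum of a trailing
  3 s Hamming-windowed segment per second. Max_freq is the argmax bin
  frequency (0 by convention for a zero window); Mean_freq is the
  spectral centroid — "frequency of mean energy" admits a median-frequency
  reading too, but the centroid is the standard moment and is what we
  use; Spec_area is the trapezoidal area under the magnitude spectrum.
* **EMD_1..12** — per-second means of the first 12 IMFs from a
  full-signal sifting decomposition (cubic-spline envelopes with two
  mirrored extrema per boundary, Cauchy criterion SD < 0.2, at most 200
  sifts). If fewer than 12 IMFs emerge the missing levels are zero rows;
  extra modes are discarded. Windowed EMD is avoided entirely because its
  edge artifacts dominate short segments.
* **ShEnt** — −Σ p log₂ p over a 16-bin histogram spanning the epoch's
  own min–max range; a constant epoch has entropy 0.
* **FD** — Higuchi fractal dimension with k_max = 8 (epochs hold 128–512
  samples), ordinary least-squares slope of log L(k) vs log(1/k);
  degenerate epochs report 1.0.
* **Var_φ** — unbiased sample variance (divisor N−1) per epoch. The
  variance family covers all six bands, matching the 55-feature
  inventory: 5 MMSD + 5 C_τ + 5 C_τ₀ + 5 TEO + 6 ZCR + 6 LZC + 3 STFT +
  12 EMD + 1 ShEnt + 1 FD + 6 Var.

## Conditioning

Per feature row and per subject, in fixed order: (1) causal moving
average over the current and previous 30 values ("order 30" read as a
31-tap uniform FIR), applied to every row whose name does not start with
MMSD/TEO/EMD — the exemption list is read literally, so the C amplitude
rows *are* smoothed; (2) outlier replacement — values beyond 4 SD of the
row mean become the row median, statistics taken from the original row in
a single pass (at 3 SD the A-phases themselves would be flagged); (3)
min–max normalization to [0, 1], constant rows mapping to zero. Keeping
statistics per subject makes the cross-validation trivially leakage-free.

## Reduction

mRMR uses the greedy MID (difference) criterion: at each step pick the
feature maximizing MI(feature; labels) minus the mean MI with the already
selected features. Features are discretized into 3 quantile bins before
MI estimation; the first pick is therefore the pure maximum-relevance
feature. PCA is the centered covariance eigendecomposition (components
orthonormal, explained variances non-increasing); inside cross-validation
both reducers are fitted on training subjects only.

## Classifiers

* **DA** — linear/quadratic discriminant analysis fitted by closed-form
  Gaussian discriminants rather than explicit squared-error minimization
  of the discriminant weights; the decision surfaces are equivalent and
  the fit is far better conditioned. QDA uses a 1e-6 regularization
  ridge.
* **k-NN** — Euclidean metric, majority vote over k ∈ {3,5,7,9,15,25};
  vote ties are broken by the nearest neighbor belonging to a tied class.
* **SVM** — soft-margin machines with the Gaussian kernel
  exp(−γ‖xᵢ−xⱼ‖²) (the negative exponent; an unbounded positive-exponent
  kernel is not meaningful), combined one-against-all: c binary machines,
  prediction by the largest decision value. Solver tolerance is fixed at
  1e-3 so fits are deterministic. The full grids are C = 2⁻⁵…2¹⁵ and
  γ = 2⁻¹⁵…2⁵ in octave-squared steps (11×11 = 121 pairs).

## Post-processing and evaluation

Predicted A-runs (on the A-vs-B collapse) of length 1 or > 60 s revert to
background; surviving runs keep their per-second subtypes. The filter is
idempotent. Evaluation is leave-one-subject-out: conditioning is
per-subject, ranking/PCA and the classifier are refitted per fold on the
training subjects, the held-out subject is predicted and duration-
filtered, and confusion matrices are accumulated (rows = predicted,
columns = true). Reported WAC/AC are means over folds; pooled-matrix
versions are also emitted. An empty true class is excluded from WAC with
a warning. Display rounding is to integer percent.

`svm_grid_search_loso` scores each (C, γ) pair by its mean outer-fold
WAC and returns the argmax (ties to smaller C, then smaller γ). Selecting
on the outer folds is an optimistic protocol — the returned best WAC is a
model-selection summary, not an unbiased generalization estimate; for an
unbiased estimate, fix the pair and rerun `leave_one_subject_out`.

## Synthetic cohorts

The generator emulates exactly the signal properties the features key
on, with exact ground truth:

* background: Fourier-domain 1/f power shaping of white noise,
  band-limited to 0.3–35 Hz, rescaled to the target SD (default 15 µV,
  jittered ±20% per subject for inter-subject variability);
* A1: the delta-band component is multiplied by `a1_gain` (default 2,
  floor 4/3 per the subtype's amplitude definition) under a 0.5 s cosine
  taper;
* A3: band-limited 8–35 Hz noise is added at `a3_gain` (default 2) times
  the background's fast-band RMS while the delta component is halved;
* A2: the A1 modification over a uniform 50–80% leading fraction of the
  event, the A3 modification over the remainder;
* events: 1.5/min, durations uniform on [4, 15] s (≈26% A-seconds, i.e.
  the ~70% background predominance of real scorings), non-overlapping
  with ≥ 2 s gaps; subtype mix (0.5, 0.25, 0.25) reflecting A1
  predominance; one master seed, subject i deriving seed master+i.

What the generator does **not** model: sleep-stage architecture, CAP
sequence periodicity, K-complex/spindle morphology, artifacts, electrode
drift. Passing the cohort evaluations therefore demonstrates that the
pipeline recovers planted amplitude/frequency structure under subject
heterogeneity and class imbalance — it does not certify clinical
performance on polysomnographic data.

## Problem sizes and defaults for the shipped evaluations

The end-to-end evaluations use an 8-subject cohort at 20 min/subject and
128 Hz (≈9,600 scored seconds), k-NN with k = 25 on the 30 top-ranked
mRMR features for the binary task, and the one-against-all SVM on 40
features for the multi-class task with a reduced 3×3 grid
(C ∈ {2⁻⁵, 2⁻¹, 2³}, γ ∈ {2⁻⁹, 2⁻⁵, 2⁻¹}) that subsamples the full grid
around its typically selected operating region. These sizes keep a full
from-scratch run in the minutes range on a single CPU while leaving the
planted effects comfortably detectable.

## Known limitations

* The EDF writer is minimal (16-bit, 1 s records, single channel) and
  exists for round-tripping synthetic cohorts; reading uses MNE and
  accepts channel-label dialects ("C4-A1", "C4A1", "C4_A1").
* Free-text Physionet-style annotation import is best-effort; the
  canonical interchange format is the strict 3-column TSV.
* Causal filtering introduces band-dependent phase delay relative to the
  annotation clock; at the 1 s label resolution this is sub-epoch for all
  bands but not zero.
* The per-second label discretization (majority overlap, ties to A,
  later onset wins among overlapping events) is a convention; scored
  atlases do not specify one.
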