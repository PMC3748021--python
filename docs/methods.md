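# Methods

This note documents the models, numerical choices, and open design
decisions behind `rsvpsearch`, and what the synthetic study does and does
not establish about real EEG data.

## Signal conditioning

Continuous EEG is band-passed with a fourth-order Butterworth filter,
1–10 Hz (delta/theta carry the P300), applied forward–backward
(`sosfiltfilt`) so the filter is zero-phase and ERP latencies are
preserved. The signal is then decimated by plain integer subsampling —
the 1–10 Hz band-pass is the anti-alias filter for any target rate of
32 Hz or above — and re-referenced to the common average (CAR). Event
onsets are rescaled by integer division during decimation. All three
operations are linear; CAR and decimation commute (asserted by test), so
their order is a convention, not a modeling choice: the implemented order
is band-pass → decimate → (optional EOG correction) → CAR.

EOG correction is ordinary least squares: each EEG channel is regressed
on the EOG channel(s) over a calibration segment rich in eye activity,
assuming the uncontaminated EEG is uncorrelated with the EOG; correction
subtracts the fitted leakage. It is an optional pipeline switch — with
the synthetic default of a spatially uniform leakage, CAR alone already
cancels the contamination, mirroring the empirical finding that the
correction does not change decoding performance appreciably.

Epochs span the half-open window [200, 700) ms after onset. At 32 Hz this
is exactly 16 samples; with the 8-channel centro-parietal montage (C3,
Cz, C4, CPz, Pz, PO3, POz, PO4) a trial flattens to 128 features. The
half-open convention is the only one consistent with that feature count.
The target-to-target interval (TTI) of a target trial is its distance in
stimuli to the preceding target, categorized {1, 2, 3, >3}; the first
target of a sequence, having no predecessor, is filed under ">3".

## Decoding

**Discriminant power (DP).** For two classes the canonical variate
reduces to the Fisher/LDA direction w ∝ S<sub>w</sub><sup>−1</sup>(m₁ −
m₀) (computed with a tiny ridge, 1e-8 of the mean scatter eigenvalue, for
rank-deficient scatter). Feature j is scored by the squared Pearson
correlation between its column and the trial projections Xw, normalized
so ΣDP = 100%. Constant features score 0 (their correlation is
undefined). DP is normalized per fold, not globally, before thresholding.

**Stability selection.** Trials are split into 3 contiguous-in-time
blocks (respecting presentation order; a stratified split is substituted
when a block would miss a class); features with DP > 1% in *every* fold
are kept. When nothing survives — typical for signal-free data — the
downstream convenience pipeline falls back to all features rather than
failing, so chance-level inputs produce chance-level outputs instead of
errors.

**Gaussian prototype classifier.** Each class is a mixture of
`n_prototypes` (default 4) Gaussian prototypes; posteriors come from
Bayes' rule over summed prototype likelihoods with empirical class
priors. The default covariance structure is diagonal per prototype,
fitted by expectation–maximization with k-means initialization (seeded;
tolerance 1e-6, ≤ 200 sweeps; variance floor 1e-6 × mean feature
variance). EM on a per-class mixture was chosen over gradient-based
prototype updates as a better-specified estimator of the same model
family. A `pooled` option shares one full covariance (pooled
within-prototype scatter) across classes; with one prototype per class it
reduces exactly to LDA, which the tests exploit as a closed-form oracle.

**Hardening.** Soft scores become hard labels by `score > 0.5` — the
threshold is strict, so ties fall to distractor, the conservative choice
in a rare-target stream.

**LDA ensemble comparator.** One LDA (lsqr solver, Ledoit–Wolf
shrinkage) per 100 ms window of the epoch; the epoch duration must be a
whole multiple of the window (200–700 ms → 5 classifiers), with window
boundaries rounded to samples so counts may differ by one at awkward
rates. The fusion rule — unspecified in the literature the design
follows — is the mean of per-window outputs z-standardized on the
training set.

## Label propagation

Nodes are images; a per-space graph connects every node to its K = 5
nearest labeled and K nearest unlabeled neighbors by Euclidean distance.
Arc weights are a Gaussian kernel exp(−d²/σ²) with σ the median of all
selected neighbor distances (median heuristic); the graph is symmetrized
by union, and per-space graphs merge by arithmetic-mean weights with
absent arcs counted as 0 ("equal contribution"). The original
Bayesian-network parameterization of arc probabilities is not recoverable
from the source material; the Gaussian kernel with median bandwidth is a
declared substitute, exposed as configuration.

Before propagation the hard labels are balanced by uniformly
undersampling the majority class, per iteration, on that iteration's
labels only. Propagation minimizes Σ w<sub>ij</sub>(f<sub>i</sub> −
f<sub>j</sub>)² with labeled values clamped — the harmonic (Gaussian
field) solution — via one direct sparse solve of the graph-Laplacian
system; no iterative relaxation. Unlabeled nodes whose component contains
no labeled node are undetermined; they receive the uninformative value
0.5 and a logged warning. By the maximum principle all outputs lie in
[0, 1]; the implementation clips float residue at the boundaries.

## The closed loop

Four iterations, 200 images per iteration (two 100-image RSVP sequences
treated as one block; the 4 Hz timing is irrelevant offline), initial
sequence with exactly 10% targets. After each iteration the top-200
images by the current propagation (ties broken by stable node-id order)
form the next sequence; presented images may reappear, since a clamped
hard-1 image outranks everything below 1, and are clamped anew each
iteration. The final ranking averages the per-iteration propagated
vectors (`accumulate`). Two comparison variants: `latest_only` ranks by
the last propagation alone; `average_eeg_first` averages each presented
image's soft EEG scores over its presentations, hardens and balances once
(re-balancing before the final propagation, for consistency with the per-
iteration path), propagates once, and keeps the averaged soft scores on
the presented images themselves. All randomness flows from a single
config seed through labeled child streams (`_seeds.py`), so full runs are
bit-reproducible.

## Evaluation

ROC AUC is the Mann–Whitney probability with the ½ tie convention.
Average precision follows the i/n rule with unretrieved targets scoring
0; the denominator is therefore all targets in the database.
TTI-stratified AUC scores each TTI category's targets against the full
shared distractor pool; empty categories report NaN, not 0. The
seed-paired run comparison uses the Wilcoxon signed-rank test with an
exact sign-enumeration distribution (dynamic programming over doubled
mid-ranks, valid under ties) for ≤ 25 nonzero differences and the normal
approximation beyond; an all-zero difference series is reported as
degenerate with p = 1.

## The synthetic study

The generator emulates the features the pipeline is sensitive to, not
scalp physics:

* **Background** — AR(1)-colored Gaussian noise (coefficient 0.9,
  stationary sd `noise_sd`), giving a low-frequency-weighted spectrum.
* **Target response** — one Gaussian-windowed positive deflection per
  target (temporal sd 70 ms), peak latency 400 ± 20 ms (jitter clipped to
  310–490 ms), spatial profile peaking at CPz/Pz (0.10–1.00 across the 8
  channels). Real P3 complexes are richer; one bump suffices to exercise
  decoding. Peak amplitude is `ERP_GAIN × discriminability × noise_sd`
  with ERP_GAIN = 1.5. The mapping from discriminability to amplitude is
  a free modeling choice; this value places the full pipeline's
  cross-validated AUC near 0.67 on an 800-trial training run (the scale
  of a real training session), i.e. in the moderate (< 0.75) operating
  regime the framework is designed for. Note that with only the 8
  analysis channels simulated, CAR removes the mean of the spatial
  profile, so only its across-channel contrast is decodable — the reason
  the profile is deliberately non-uniform.
* **EOG** — one channel of Hanning-shaped blink transients (0.2/s during
  recordings, 0.5/s in the 2-minute calibration segment, amplitude ≈ 30 ×
  noise sd) plus measurement noise, mixed linearly into every EEG channel
  (default coefficient 0.25).
* **Image features** — two spaces (16- and 12-dimensional, standing in
  for appearance- and edge-histogram-type indexes), one isotropic
  Gaussian cluster per class (class-mean spread 3.0, within-class sd
  `cluster_sd` = 1.0), class sizes as equal as possible.
* **Synthetic labeler** — binormal scores with separation δ = √2 ·
  Φ⁻¹(AUC), mapped through Φ(z − δ/2) so the classes sit symmetrically
  about the 0.5 hardening threshold; expected AUC equals the requested
  value exactly, with disjoint uniform ranges for AUC = 1. It is the
  default driver for loop-level tests, decoupling loop behavior from
  classifier tuning; full EEG simulation is used for conditioning and
  decoding tests.

What passing tests therefore show: the algorithmic claims — accumulation
beats single-shot propagation under a weak labeler, propagation solves
the stated quadratic exactly, parameters are recovered where identifiable
— hold under controlled conditions with known ground truth. What they do
not show: robustness to non-stationary noise, real P3 latency/amplitude
structure (including genuine TTI effects, which the simulator does not
model), volume conduction, or real image-feature statistics.

## Problem sizes and numerical details

Loop-level results average 20–30 seeded runs on a 1000-image, 10-class
database (100 targets); decoding results use 400–800-trial oddball runs
at 10% prevalence, 3-fold stratified cross-validation. The harmonic solve
uses `scipy.sparse.linalg.spsolve` on the unlabeled-block Laplacian;
degenerate kernels (all-zero neighbor distances) fall back to unit
weights. At a chance-level labeler the running-average AP drifts mildly
*downward* across iterations: re-sequencing by an uninformative
propagation replaces the 10%-prevalence initial sequence with arbitrary
clusters, so fewer true targets get clamped later. "No improvement
without information" is the property asserted; exact flatness is not
expected and not claimed.

## Known limitations

* The graph consumes precomputed feature matrices; no feature extraction
  from pixels.
* No spatial filtering (xDAWN/CSP), ICA artifact removal, online
  adaptation, or adaptive stopping — the iteration count is fixed at 4.
* `average_eeg_first` rankings mix clamped-scale propagated values with
  raw soft scores on presented images, as that comparator prescribes;
  its AP is sensitive to that convention.
* The minimal EDF writer emits 16-bit samples, one record per second,
  without embedded events (the CSV event table travels alongside).
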