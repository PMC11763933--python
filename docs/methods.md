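# Methods

## Pipeline model

The package treats a multichannel EEG recording as a collection of
(segment, band) panels and summarizes each panel by the texture of its
directed-connectivity matrix. The processing order is fixed: segment →
band-pass → z-score → pairwise Granger causality → eight LGS code
matrices → three scalar quantifiers → one-versus-all classification.
Normalization is applied per channel *within* each band-filtered
segment (an alternative — once per recording — would change nothing
downstream, since the Granger fits are scale-invariant after any
per-channel affine map; the per-panel choice keeps every panel's
invariant checkable locally).

### Preprocessing

Segments are consecutive, non-overlapping and anchored at sample 0;
recordings shorter than `segment_len × n_segments` are rejected rather
than padded, and any remainder is discarded. Defaults: 30,000 samples
(60 s at 500 Hz) × 5 segments, i.e. a 150,000-sample minimum.

Band-passing uses a second-order Butterworth design per band edge pair.
By default the filter is applied forward and backward (`sosfiltfilt`),
which removes phase distortion at the cost of doubling the effective
order and making the filter non-causal; `zero_phase=False` gives the
single-pass variant. The γ band's 100 Hz upper edge requires fs > 200
Hz; a band edge at or above Nyquist raises a configuration error
instead of silently clipping.

Z-scoring uses the population standard deviation (divisor n). A
constant channel raises a degenerate-signal error naming the channel.

### Granger connectivity

For an ordered pair (source x, target y), both nested autoregressions
are fit by OLS with an intercept on the same truncated sample range
(t = trim…n−1, trim = the maximum lag considered), so the variance
comparison is not confounded by differing sample counts. Residual
variance uses divisor n_obs. Lag order is either fixed or selected per
target by BIC on the restricted model (the restricted model depends
only on the target, so selection costs one sweep per channel, not per
pair). Internally all pair fits for one panel share a single Gram
matrix Z′Z over the lagged design, which makes the 342 ordered pairs of
a 19-channel panel essentially free after one O(n·(Cp)²) pass; tests
verify this path against a naive per-pair `lstsq` reference at 1e-8
relative tolerance.

**Binarization.** The as-printed rule — edge iff var(ẽ) < var(e), ties
to 0 — is the default. For nested OLS on identical samples the full
model's residual variance is smaller almost surely, so this rule
saturates: the matrix tends to all ones regardless of the data. The
package implements the rule faithfully, counts saturated matrices as
first-class warnings in the run manifest, and offers two documented
alternatives: a relative `min_improvement` guard, and a calibrated
nested-model F-test (`binarize_mode="ftest"`, threshold `alpha`).
`binarize=False` returns the continuous relative variance reduction
1 − var(ẽ)/var(e) instead.

Convention: rows cause columns ((i, j) = 1 means channel i
Granger-causes channel j); the diagonal is identically 0. The LGS
encoding is orientation-sensitive, so this convention is part of the
reproducibility contract.

### LGS texture encoding

Each operator is pure data: a block shape, a target cell, and an
ordered list of exactly eight directed edges between block offsets
(LELGS: two four-edge groups whose sub-codes are OR-combined). The
engine slides the block with stride 1 over all fully contained
positions (no padding), emits bit 1 per edge when from-cell − to-cell
≥ 0 (ties encode 1), and assembles bits first-edge-most-significant.
For an m × n matrix and an R × C block the code matrix is
(m−R+1) × (n−C+1); with 19 channels, between 15×15 and 17×17 per
operator. Codes depend only on pairwise order relations, so they are
invariant under any strictly increasing transform of the matrix —
a property test exercises this directly.

The eight shipped tables follow the published geometry of the operator
family (block shapes 3×5, 4×4, 4×3, 5×3 and 3×3; symmetric
counterclockwise/clockwise double loops for SLGS and VSLGS; OR-combined
vertical and horizontal chains for LELGS; zigzag walks, plain and
centre-started, for the four Z-operators). The exact arrow sequences
are this package's transcription and are asserted by an exhaustive
per-window, per-edge oracle; user-defined operators can be loaded from
JSON without engine changes. The `comparison` and `bit_order` options
flip the sign convention and bit significance for sensitivity analysis.

### Quantifiers

Per code matrix: Shannon entropy of the empirical 256-bin code
histogram (bits, range [0, 8]); the same histogram entropy under the
natural log (nats, range [0, ln 256]); and the largest singular value
of the code matrix. The two entropies are exactly proportional
(factor ln 2) — this redundancy is retained deliberately because the
three-quantifier feature layout is the pipeline's contract;
`logenergy_mode="sum_log_squares"` substitutes the conventional
signal-processing log-energy form Σ ln(c²) over nonzero codes for users
who want an independent second entropy. Histograms use raw relative
frequencies with no smoothing; zero-probability terms contribute 0.
SVD is computed on the code matrix (a histogram has no meaningful SVD),
entropies on the histogram, per each formula's domain.

Feature tables are tidy: one row per (subject, segment, band), columns
`<operator>_<quantifier>` in operator-alphabetical × (shannon,
logenergy, svd) order — 24 features — plus subject, segment, band and
label metadata. Per-quantifier 8-column tables are exact slices of the
combined table.

### Classification

Each class defines an independent binary one-versus-all task. Folds are
stratified on the *multiclass* label with a recorded seed, so all OVA
tasks share one partition; `grouping="subject"` switches to
StratifiedGroupKFold so no subject's segments straddle train and test
(segment-level folding leaks subject identity; the default remains
segment-level, and reports label the mode). Metrics are computed from
per-fold confusion counts: accuracy, sensitivity (recall), precision,
and F1 (harmonic mean of precision and sensitivity); empty-denominator
cells yield 0 with an explicit flag. Hyperparameters: KNN k=5; RBF SVM
with C=1 and scikit-learn's `gamma="scale"`; Gaussian Naïve Bayes;
AdaBoost with 50 depth-1 trees and the config seed. No class
rebalancing is applied. Fold-level records are stored so every mean ±
sd is recomputable.

## Synthetic cohorts

Each subject is a stable VAR(2): self-lags (0.5, −0.2) on every channel
(scalar AR(2) roots at modulus √0.2 ≈ 0.45), plus lag-1 cross-coupling
of strength 0.5 on the edges of the subject's class graph, innovations
N(0, 1), 500-sample burn-in. The five class graphs are fixed data —
acyclic digraphs over 19 nodes with 6–12 edges differing in both
density and placement — so stability holds for any jittered coupling
(the companion spectrum stays triangular), and the generator still
verifies the companion spectral radius before sampling. Per-subject
coupling strengths are jittered ±10% uniformly so classes are
distributions, not points. On top of the VAR, each class adds one
band-limited sinusoid (amplitude 1, random phase per channel) at a
class-specific frequency (δ/θ/α/SMR/β centres), exercising band
extraction. Defaults: 19 channels, 500 Hz, 150,000 samples, 20 subjects
per class; a flag reproduces the emulated study's class sizes
(95/42/28/25/40, total 230).

What the generator does **not** emulate: 1/f background spectra, volume
conduction and reference effects, artifacts (ocular, muscular), and
non-stationarity. Passing tests therefore demonstrate that the pipeline
recovers *planted linear directed structure* under band filtering and
texture encoding — not that the features separate clinical populations.

## Study configurations and problem sizes

Tests and the acceptance script scale the study down to keep full runs
cheap while leaving the generator's per-sample conditions (channel
count, rates, coupling strength, jitter, innovation SD) untouched:

- **Edge recovery**: bivariate VAR(2), coupling 0.5, n = 30,000, 100
  seeded replicates, lag-2 F-test at α = 0.01.
- **End-to-end cohort**: 5 classes × 20 subjects, 30,000 samples per
  subject split into five 6,000-sample segments, γ band, lag-8 F-test
  at α = 1e-4, KNN OVA with 10-fold CV, measured against each class's
  majority baseline; a 20-replicate label-permutation control checks
  that shuffled labels carry no class signal.

Two choices in the end-to-end configuration deserve justification.
First, the γ band: zero-phase band-pass filtering leaves strong
autocorrelation that a low-order AR cannot whiten, and in narrow bands
(α, SMR) this miscalibrates the nested F-test so badly that the edge
false-positive rate approaches 1 and the matrices saturate. The γ band
(30–100 Hz) is the widest band and retains most of the VAR's broadband
structure; measured on planted graphs, lag-8 fits there achieve a 100%
hit rate at ~1% false-edge rate. Second, the F-test mode rather than
the default variance rule: the saturated default produces constant
matrices with no class information by construction, so any study of
class separability must use a calibrated detector. Both effects are
reported as warnings by the pipeline itself.

A note on the permutation control: a KNN under permuted labels does
*not* revert exactly to the majority-class proportion — with 20%
positive labels, a majority vote of five neighbors predicts positive
with probability ≈ P(Bin(5, 0.2) ≥ 3) ≈ 0.06, putting expected accuracy
near 0.77 rather than 0.80. The control therefore checks (a) that
permuted accuracy does not *exceed* baseline (no residual signal), and
(b) that it sits at baseline within the fold-level spread the CV report
itself carries.

## Numerical choices and degenerate inputs

- Granger Gram solves use `numpy.linalg.solve` on the small subsystem;
  a singular subsystem (constant or collinear series) raises a
  degenerate-signal error naming the pair. Residual sums of squares are
  clipped at 0 against cancellation.
- Variance-rule ties (var(ẽ) = var(e)) are non-edges.
- LGS ties (difference exactly 0) encode bit 1; a constant matrix
  yields code 255 everywhere.
- Entropy terms with p = 0 contribute 0 by convention.
- Zero-denominator metrics are 0 with a recorded flag.
- EDF output is a minimal 16-bit single-record writer for synthetic
  data round-trips; reading goes through mne, with a header pre-check
  rejecting mixed per-channel sampling rates.

## Known limitations

- The bivariate Granger formulation cannot distinguish direct from
  mediated influence (no conditional/multivariate variant).
- Zero-phase filtering is non-causal and therefore blurs directed
  inference within narrow bands; the single-pass option trades phase
  distortion for causality.
- The LGS arrow sequences are authoritative only as shipped; variants
  of the published diagrams may permute bits (which leaves entropies of
  saturated regions unchanged but can shift histograms).
- No artifact rejection, re-referencing or resampling is performed.
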