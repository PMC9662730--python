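# Methods

This note records the model, the defaults and the judgment calls behind
`spectrotex`, in the order the pipeline runs.

## Signal model and standardization

A recording is a channels × samples real matrix with a sampling rate,
ordered channel names, a class label and a subject id. Amplitude units
are deliberately treated as arbitrary: the z-normalization step removes
scale, so microvolts vs. millivolts (or EDF scaling quirks) cannot affect
the features.

Heterogeneous montages are reduced to the 16-electrode 10–20 subset
(Fp1 … O2) that clinical resting-state sets have in common, in a fixed
order, and resampled to 256 Hz. Channel matching is case-insensitive and
strips common reference suffixes (`-A1`, `-REF`, …) because acquisition
software labels electrodes inconsistently; a missing electrode is an
error rather than an interpolation target — fabricating a channel would
silently alter the texture statistics. Resampling is polyphase
(band-limited, anti-aliased); the output length is
`round(n · target_fs / fs)`.

## Preprocessing

Order: common average reference → low-pass → z-normalize → segment.

* **CAR** subtracts the across-channel mean at each sample; it removes
  common-mode noise and is undefined (rejected) for single-channel input.
* **Low-pass**: Butterworth, cutoff 40 Hz, order 4, applied zero-phase
  (forward–backward). The filter family and order are conventional EEG
  choices; zero-phase application preserves event timing in the
  spectrogram at the cost of squaring the magnitude response (the tests
  measure attenuation against |H(f)|² for exactly this reason). A causal
  single-pass mode exists (`FilterSpec(zero_phase=False)`).
* **z-normalization** is per channel per recording. A constant channel
  maps to zeros instead of NaN so a flat electrode cannot poison the
  pipeline. Per-segment normalization can be had by segmenting first and
  normalizing the segments.
* **Segmentation**: non-overlapping 3 s windows (768 samples at 256 Hz);
  the trailing remainder is discarded; every window inherits the
  recording's label and subject id. By default each window is split
  per channel, one spectrogram image per channel-window: with 16
  channels a 60 s recording yields 20 × 16 = 320 images. A stacked
  multi-channel segment mode exists (`per_channel=False`) for
  experimentation, but the per-channel reading is the default and the
  one all defaults are tuned around. Window length and an overlap
  fraction are configurable.

## Spectrogram images

The STFT uses a periodic Hamming window, window = fs/2 samples (128 at
256 Hz) and 50 % overlap (hop 64), giving 11 frames on a 3 s segment —
a balanced time/frequency trade-off for 768-sample windows. Frames are
taken only where a full window fits (no edge padding), so the frame
count is `floor((n − win)/hop) + 1`, and the magnitude is one-sided
(win/2 + 1 bins).

Rendering goes straight from the magnitude matrix to an 8-bit grayscale
image — no plotting library, no colormap — because the texture operators
consume scalar intensities and a draw-then-screenshot path would make
the pipeline depend on rendering internals. Steps: crop to 0–40 Hz (the
filter passband; full-Nyquist optional), log10(1 + m) compression
(default on), per-image min–max scaling to [0, 255], bilinear resize to
128 × 128, flip so frequency 0 is the bottom row, round to integers.
A constant or all-zero magnitude maps to an all-zero image. Per-image
scaling makes the image invariant to uniform amplitude scaling of the
segment; between-image contrast is carried by the *shape* of the
spectrum, not absolute power — consistent with z-normalized input.
Grayscale PNG export/import is provided for inspection.

## Texture descriptors

All three operators compare each interior pixel with its 8-neighborhood
(radius 1). The neighbor scan order is frozen — row-major from the
top-left, first neighbor → most significant bit — because any fixed
order yields equivalent histograms but reproducibility requires picking
one. The 1-pixel border is excluded from the code maps (no corner
interpolation), and a coded pixel belongs to a pyramid block according
to its own image coordinate.

* **Census transform**: bit 1 where center ≥ neighbor; alphabet 256.
* **CLBP**: differences d_p = g_p − g_c split into sign
  (s_p = [d_p ≥ 0]) and magnitude (m_p = |d_p|). CLBP_S packs the sign
  bits; CLBP_M packs [m_p ≥ c] with c = the mean of all magnitudes over
  the image (the CLBP literature's convention; an image-gray-mean mode
  is kept behind `m_threshold="gray_mean"` since the two thresholds are
  easy to conflate); CLBP_C = [g_c ≥ image gray mean]. S and M codes are
  riu2-mapped by default (uniform codes → bit count, others → 9;
  alphabet 10), treating the 8 bits as a circular ring.
* **LTP**: ternary q(d_p) = +1 iff d_p ≥ +μ, −1 iff d_p ≤ −μ, else 0,
  with μ = 5 gray levels; upper code packs (q = +1), lower code packs
  (q = −1). The dead zone makes the code robust to small intensity
  fluctuations that would flip LBP bits.

The spatial pyramid partitions the image into 2^L × 2^L blocks at levels
0–2 (21 blocks); when a side is not divisible the last row/column block
absorbs the remainder. Per block, cCENTRIST accumulates the joint
(S, M, C) histogram (10 × 10 × 2 = 200 bins riu2; the raw 256 × 256 × 2
mode exists for ablation) and tCENTRIST concatenates the 256-bin upper
and lower histograms (512). Histograms are L1-normalized per block
(default on) because border exclusion gives blocks unequal coded-pixel
counts. Descriptor lengths: 4200 (cCENTRIST) and 10752 (tCENTRIST).
A plain census-transform descriptor is included as a baseline only.

Every code operator is verified exactly against naive per-pixel
reference loops in the test suite; the vectorized implementations are
never their own oracle.

## Reduction and classifiers

PCA is fitted on training rows only, per CV fold — fitting it globally
would leak test statistics into the projection (a `pca_m` integer or
variance fraction is accepted; default: smallest M explaining 95 % of
variance, capped at 500). For wide matrices (n ≪ d) the fit goes through
the Gram matrix X_c X_cᵀ: its top eigenpairs give the same components as
the SVD at a fraction of the cost, and its trace gives the exact total
variance for the 95 % cutoff. Small problems use a plain economy SVD;
both paths are cross-checked in tests.

* **SVM**: libsvm linear kernel K(x, y) = xᵀy, C = 1, one-vs-one
  multiclass; per-class scores are the one-vs-rest aggregated decision
  values and the prediction is their argmax.
* **kNN**: Euclidean distance, k ∈ 1…10 (default 9); scores are vote
  fractions; vote ties break by smallest mean distance to the tied
  class's neighbors, then class index — deterministic.
* **Random forest**: 100 trees, entropy impurity, √d candidate features
  per split, seeded; scores are tree vote fractions.
* **LDA**: authored directly from the discriminant
  y_c = xᵀΣ⁻¹μ_c − ½μ_cᵀΣ⁻¹μ_c + log(n_c/n) with pooled within-class
  covariance and a 1e-6 ridge on the diagonal for invertibility; scores
  are the y_c values themselves. Cross-checked against scikit-learn's
  LDA.

## Evaluation

Five-fold CV. `segment` mode (default) stratifies individual images by
class; fold sizes differ by at most one because per-class remainders are
dealt through a round-robin cursor shared across classes (naive
stratification stacks remainders on the leading folds). `subject` mode
assigns whole subjects to folds (largest first, to the least-loaded
fold): it removes subject-identity leakage and is the mode to trust for
subject-level claims; segment-level CV on per-subject data is known to
be optimistic. Reports carry their mode tag.

Confusion convention: rows = actual, columns = predicted. Per class:
TP = cm[c][c], FN = row − TP, FP = column − TP, TN = rest;
Sen = 100·TP/(TP+FN), Spec = 100·TN/(TN+FP), Prec = 100·TP/(TP+FP),
F1 = 2TP/(2TP+FP+FN), Acc = 100·trace/total. Zero denominators return 0
with a warning rather than NaN. ROC curves are one-vs-rest over the
per-class scores, pooled over test folds; the macro curve averages
per-class TPR on a common FPR grid. Fold-averaged metrics are macro over
classes, then mean ± SD over folds.

All randomness (synthesis, folds, forest) flows from a single top-level
seed; two runs with the same config and seed serialize byte-identical
metrics JSON.

## Synthetic study

The generator emulates exactly one property of clinical EEG — classes
separable by spectral band power with subject-level structure — and
deliberately nothing else: no spike morphology, no burst suppression, no
non-stationarity, no artifacts, no inter-channel covariance structure.
Passing the end-to-end tests therefore demonstrates that the pipeline's
machinery (conditioning, imaging, texture coding, fold discipline,
classification) is correct and leak-free, *not* that the method reaches
any particular accuracy on real patients.

Defaults (the study conditions for tests and the acceptance script):
5 classes mimicking an ASD/EP/PD/SZ/HC cohort with one band center each
at 6 / 11 / 16 / 24 / 32 Hz (≥ 5 Hz apart, inside the 40 Hz passband),
4 subjects per class, 60 s per subject, 16 channels at 256 Hz, pink
noise (α = 1) at 10 dB SNR, per-subject frequency jitter ≤ 0.5 Hz,
per-channel amplitude jitter (σ = 0.2) and uniformly random per-channel
phases. The random phases are load-bearing: a common-phase sinusoid is
common-mode and would be removed by CAR, leaving noise-only features.
Setting all band powers to zero yields a noise-only cohort whose classes
are statistically indistinguishable (used as a negative control).

This default study produces 6400 images. At that size the per-fold PCA
(Gram route) dominates the cost; the full acceptance script — both
extractors, four classifiers, five folds each, plus a label-permutation
control — completes in roughly 7 minutes on one CPU. Under these
conditions all four classifiers sit near 100 % accuracy and the
permuted-label control at the 20 % chance level; those numbers are
computed, not asserted, by `scripts/acceptance.py` and the acceptance
tests.

## Known limitations

* Only P = 8, R = 1 neighborhoods are implemented for the code
  operators; larger radii would need interpolated sampling.
* The common printed form of the ternary comparison ("+1 if a ≥ μ, −1 if
  a < μ, 0 otherwise") is internally inconsistent; this package uses the
  standard resolution (−1 iff a ≤ −μ).
* `segment`-mode CV allows one subject's images in both train and test;
  use `subject` mode for subject-level generalization claims.
* The EDF writer covers the minimal subset needed to round-trip our
  recordings (16-bit, 1 s records, integer rates); it is not a general
  EDF+ exporter.
* The spatial pyramid is the standard non-overlapping 1+4+16 grid; the
  31-block shifted variant of the original census-histogram descriptor
  is not implemented.
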