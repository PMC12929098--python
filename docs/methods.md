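# Methods

This note documents the models, the synthetic data, the numerical
choices, and the limits of what the bundled experiments demonstrate.

## Classification model

The classifier is a shared encoder with two output heads. The bundled
encoder (`TinyConvBackbone`) is a stack of 3×3 stride-2 convolution +
ReLU blocks followed by global average pooling; the default widths
(16, 32, 32, 32) give a 32-dimensional feature vector from a 32×32×12
stack. Any object with `feature_dim`, `forward` and `backward` satisfies
the backbone contract, so large pretrained encoders can be plugged in;
for a pretrained 3-channel first layer adapted to 12 channels the
recommended recipe is replicate-and-rescale of the pretrained kernels.

Head 1 concatenates the backbone features with the tabular
photobleaching vector (toggled by `ModelConfig.use_tabular`; off
reproduces an image-only RGB mode) and is trained with BCE + KL against
soft labels; Head 2 sees features only and is trained with CE against
one-hot labels. Both heads are one-hidden-layer MLPs (256 units by
default) whose final layer is zero-initialized, so an untrained head
emits the uniform distribution. Head 1 uses a single softmax for its
output probabilities: BCE is applied per output element and KL across
the vector, and keeping every head output on the simplex guarantees the
averaged prediction is itself a distribution. A per-logit sigmoid
variant (renormalized) is available behind `head1_sigmoid` for
completeness.

The single-head ablation (`mode="single"`) runs Head 2 alone and applies
every enabled loss term to its output, so the multi-vs-single comparison
isolates the architectural split rather than the loss set.

### Losses and numerics

CE = −Σ y_i log p_i; BCE = mean_i −[q_i log p_i + (1−q_i) log(1−p_i)];
KL(Q‖P̂) = Σ Q_i log(Q_i/P̂_i); total = α·CE + β·BCE + γ·KL with
α = β = γ = 1 by default. Probabilities are clamped to [1e−7, 1−1e−7]
before any logarithm. The BCE reduction over the C per-output terms is
the arithmetic mean, which keeps the term on the same scale as CE under
unit weights. Soft-label vectors are constructed so their entries sum to
1.0 exactly in floating point (last entry by complement).

The whole network is numpy with hand-derived gradients: CE through the
softmax uses the closed form p − y; BCE and KL gradients are taken with
respect to the probabilities and pulled back through the softmax
Jacobian vector product p ⊙ (g − (g·p)). The test suite checks every
parameter group against central finite differences in both head modes.

## Training protocol

Stratified random splits of 80/10/10% (validation and test sizes
floored, remainder to train; per-class quotas by largest remainder so
global fold sizes are exact), several splits × several repeats, Nadam
(lr 2e−4, weight decay 1e−4 applied as an L2 gradient term, β₁ = 0.9,
β₂ = 0.999), batch size 4, reduce-on-plateau scheduling (factor 0.5,
patience 5, improvement threshold 0 — any strict decrease resets the
counter, so a constant loss stream triggers the first halving at epoch
6), and evaluation of the checkpoint with minimum validation loss.
Images are per-image min-max normalized to [0, 1] (per-channel variant
behind a flag) and bilinearly resized; training augmentation applies
gamma (U[0.8, 1.25]), mean-anchored contrast (U[0.8, 1.2]) and additive
Gaussian noise to images — each independently enabled per sample with
probability 0.5 — and Gaussian noise only to the tabular vector, with
padding-flagged entries left untouched. Repeats differ in both weight
initialization and augmentation stream, all derived from one run seed.

## Photobleaching features

Each lesion's feature vector is the mean lesion-mask pixel intensity of
each fluorescence frame (nominally 10 frames). Skin-background masks are
derived as the complement of the lesion ∪ marker union and background
means can be computed on request, but only lesion intensities enter the
feature vector — surrounding skin does not bleach in a diagnostically
useful way. Sequences shorter than the nominal length are padded by
repeating the last observed value with validity flags exposed
downstream; curves are not normalized by their initial intensity unless
`normalize_i0` is set. One mask (the first frame's segmentation) is
applied to all frames by default; per-frame masks are supported.

## Frame selection by k-NN purity

Candidate frame subsets (by default all prefixes plus all contiguous
windows) are compared by embedding the column-restricted curve matrix
and scoring neighborhood label purity. Design choices: the query point
is never its own neighbor (self-inclusion would inflate every score);
ties at the k-th distance break by ascending sample index, making the
score deterministic; subset ties break toward the smaller, then
earlier-starting subset, so uninformative extra frames are never kept on
a tie. The embedding is an injected provider; the default is a
deterministic sign-fixed PCA projection (reproducible, dependency-free
in the scoring path), and a supervised UMAP provider with the same
contract is available. The "hamming" metric on continuous coordinates is
near-degenerate, so by default coordinates are binarized at the
per-dimension median first; raw-float comparison is available behind
`binarize_hamming=False`. Note that a supervised embedding sees the
labels that purity then measures, so purity on such an embedding is an
optimistic selection criterion, not a generalization estimate.

## Synthetic data

`simgen` emulates the acquisition: per record a compact elliptical
lesion blob with soft class-conditioned spectral offsets across
channels, a small reference-marker square disjoint from the lesion, and
a fluorescence sequence whose lesion-region mean follows
I₀·exp(−λ_c·t) with class-specific decay constant λ_c, plus i.i.d.
Gaussian pixel noise (so the lesion-mean noise scales as
noise_sd/√area). Defaults: 50 records/class, 32×32 pixels, 12 channels,
10 frames, λ = (0.5, 0.25, 0.05) per class, spectral offsets
(0.3, 0, −0.3) alternated in sign across channels, I₀ = 1, noise 0.05.
The decay constants and offsets are free parameters chosen to give
well-separated classes at this scale; `decay_jitter` adds per-record
variability of λ (inter-patient photobleaching variability) and
`signal_frames=k` confines class-specific decay to frames t < k with a
shared plateau afterwards — the regime used to test that purity-guided
selection recovers the early informative window.

What the generator does **not** model: lesion morphology and texture,
camera spectral response, cross-polarization optics, illumination
inhomogeneity, or segmentation error (masks are exact by construction;
`threshold_segment` is a stand-in for a learned segmenter). Passing
tests therefore demonstrate the correctness and the qualitative behavior
of the method, not clinical performance.

## Experiment scales

The bundled experiments are sized for a single CPU: the end-to-end
recovery run uses 150 records at 32×32×12 with a 10-epoch budget; the
frame-selection study uses 180 lesions per replicate, ten replicates;
the noisy benchmark (noise 0.3, offsets ±0.03, decay jitter 0.12) uses 3
splits × 2 repeats per configuration. The full-scale protocol defaults
(448×448 inputs, 50 epochs, 5 splits × 3 repeats) remain the `TrainConfig`
defaults and apply unchanged to larger data.

## Known limitations

* The pooled t-test and Cohen's d are undefined for zero pooled
  variance; the report generator then records NaN for the statistics
  while keeping the group summaries.
* Runs within one split share data folds, so the t-test's independence
  assumption is approximate — the same trade-off the repeated-split
  protocol itself makes.
* The numpy network is single-threaded and sized for small inputs; it is
  not a general-purpose training framework.
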