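# melafuse

Multi-head, multi-loss classification of skin lesions from fused
multispectral image stacks and autofluorescence photobleaching curves.

## The problem

Multispectral skin-lesion imaging records the same lesion under several
narrow-band illuminations (autofluorescence excitation at 405 nm plus
green/red/near-IR reflectance), yielding a C-channel stack instead of an
RGB photo. Under sustained 405 nm excitation the endogenous fluorophores
(NADH, collagen, elastin) photobleach: the autofluorescence signal decays
over a 10-frame, 1 s-interval sequence, and the shape of that decay curve
carries diagnostic information. `melafuse` implements a classifier that
fuses both modalities to separate three lesion risk categories —
**Melanoma**, **Malignant** (non-melanoma) and **Other** — together with
the feature pipeline, the embedding-based frame selection, the training
protocol and the evaluation/significance suite, all exercisable end to
end on synthetic data.

## The model

A shared convolutional encoder maps the image stack to a feature vector
`f`. Two output heads consume it:

* **Head 1 (soft targets)** — an MLP over `[f ; x_tab]`, where `x_tab` is
  the photobleaching feature vector (mean lesion intensity per frame).
  It is trained against *soft labels* `Q` that encode inter-class
  similarity (Melanoma → (0.7, 0.2, 0.1), Malignant → (0.2, 0.7, 0.1),
  Other → (0.1, 0.1, 0.8)) using a per-output binary cross-entropy plus
  the Kullback–Leibler divergence KL(Q ‖ P̂).
* **Head 2 (hard targets)** — an MLP over `f` trained with categorical
  cross-entropy against the one-hot label.

The training objective is the weighted sum

    L = α·L_CE + β·L_BCE + γ·L_KL,      α = β = γ = 1,

and the final prediction is the plain average of the head probability
vectors, ŷ = (1/N) Σ ŷ⁽ⁱ⁾, which stays on the simplex.

Which photobleaching frames enter `x_tab` is decided before training by a
k-NN **purity** score on embeddings of the candidate curve sub-vectors:

    Purity(k) = (1/N) Σ_i (1/k) Σ_{j ∈ N_k(i)} 1{y_j = y_i},

with the query point excluded from its own neighborhood. Model
comparisons (multi-head vs. single-head ablation on identical splits) are
scored by accuracy and class-weighted trapezoidal AUC-PR and tested with
the pooled independent-samples t-test and Cohen's d.

The network core (strided-conv encoder, MLP heads, Nadam optimizer,
backpropagation) is implemented in numpy with explicit gradients and is
verified against finite differences in the test suite.

## Worked example

Write a pipeline config and run everything — simulation, curve
extraction, purity-guided frame selection, multi-head and single-head
training, evaluation and the significance comparison:

```yaml
# example.yaml
seed: 3
out_dir: example_run
simgen:
  n_per_class: 30
  image_size: 32
  n_channels: 12
  noise_sd: 0.25
  spectral_offsets: [0.05, 0.0, -0.05]
  decay_jitter: 0.1
train:
  max_epochs: 8
  n_splits: 2
  repeats: 2
```

```bash
melafuse run-all --config example.yaml
```

prints (abridged):

```json
[
  {
    "metric": "accuracy",
    "multi-head_mean": 0.6388888888888888,
    "multi-head_sd": 0.10638078975070422,
    "single-head_mean": 0.3888888888888889,
    "single-head_sd": 0.11111111111111113,
    "t_statistic": 3.2504180333157673,
    "p_value": 0.017457188595772333,
    "cohens_d": 2.2983926330486204
  }
]
```

and `example_run/frame_selection.json` contains

```json
{"k": 5, "metric": "euclidean", "purity": 0.651, "subset": [0, 1, 2, 3]}
```

Reading: on this deliberately noisy 90-lesion benchmark the purity search
kept only the first four photobleaching frames; the two-head model
averaged 0.64 test accuracy over 4 runs against 0.39 for the
single-head ablation trained on identical splits and seeds, a difference
the pooled t-test flags at p ≈ 0.017 with a large effect size (d ≈ 2.3).
Individual stages are also available as subcommands (`simulate`,
`extract-features`, `select-frames`, `train`, `evaluate`, `compare`).

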