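# Methods

## Model

The generator is a conditional variational encoder–decoder.  An image
encoder and a category encoder produce a joint feature; K independent
heads map it to diagonal-Gaussian latent parameters; reparameterized
samples are decoded into K questions by one shared LSTM.  The modeling
assumptions are the usual VAE ones — diagonal Gaussian posteriors, a
standard-normal prior (the KL term), and mean-squared feature
reconstruction — plus the package's central one: that pairwise
statistical dependence between latent spaces, measured by the maximal
information coefficient (MIC), is the right quantity to minimize for
question-set diversity.

Key architectural decisions where the design was open:

- **Latent → decoder conditioning.**  A learned linear map (followed by
  tanh) from the sample to the initial hidden and cell states of all
  LSTM layers; decoding starts from BOS.  This keeps a single shared
  decoder so that diversity can only come from the latents.
- **Reconstruction MLP shared across spaces** (`share_reconstruction`
  flag to un-share).
- **Inference is deterministic**: latents at their means (η = 0) and
  greedy decoding; sampled latents/tokens are available behind flags
  with explicit generators.
- **Training samples.**  Each image contributes one sample per distinct
  category among its questions: (image, category word, that category's
  questions).  Within a sample the questions are cycled to K sequences,
  question j pairing with latent space j.  The alternative — one sample
  per image under its modal category — lets the dominant category
  ("Others", ~45% of questions) claim about two thirds of conditioning
  labels and starves rare categories of signal.

## The MIC loss

`mic_exact` computes MIC exactly.  For each admissible grid shape
(a, b) — both sides at least 2, a·b below n^0.6 or an explicit λ, sides
capped by `max_grid_side` — it enumerates every contiguous partition of
the axis allowed fewer bins and finds the optimal partition of the
other axis by dynamic programming: with the other axis's bin labels
fixed, empirical mutual information is additive over the segments of
this axis, so an O(m²·parts) DP over segment boundaries is exact.
Cuts are only placed between distinct values (tied samples form atomic
blocks); a constant variable returns 0; fewer than 4 paired samples is
an error.  Normalization is by log₂ min(a, b) and the shape maximum is
returned.  The test suite checks this estimator against an independent
brute force that enumerates the partitions of *both* axes, to 1e-12.

The grid search is not differentiable, and how gradients were
propagated through the original loss is unknown.  Training therefore
defaults to a differentiable surrogate: per latent coordinate, the
batch Pearson correlation ρ between two spaces gives the Gaussian
mutual information −½·log(1−ρ²), squashed to [0, 1] as 1−√(1−ρ²).
For the linear-Gaussian dependence that reparameterized latents exhibit
this is exact and monotone with MIC; the exact DP estimator is used for
all evaluation (`pairwise_mic_matrix`, benchmark reporting).  The k = l
diagonal of the pairwise sum is a gradient-free constant (MIC of a
variable with itself is 1) and is excluded; pairs are counted once.
The batch dimension provides MIC's paired samples: dependence is
estimated per latent coordinate across the batch and averaged over
coordinates, respecting the diagonal-Gaussian structure.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α, β, γ, δ | 0.001, 1, 0.001, 1 | loss weights (reconstruction, MIC, KL, generation) |
| K (`n_spaces`) | 3 | number of latent spaces (2–4 are the studied range) |
| `d_z` | 64 | latent dimensionality (not dictated by the method; configurable) |
| `d_I`, `d_C` | 128, 64 | image/category feature sizes (tiny-CNN default) |
| MLP | 3 layers, hidden 512 | all feature/latent/reconstruction MLPs |
| LSTM | 3 layers, hidden 256 | shared question decoder |
| lr schedule | 1e-3, ×0.1 every 5 epochs, floor 1e-7 | Adam (optimizer not dictated; Adam is the VAE-training default) |
| batch, epochs | 32, 40 | full-scale protocol |
| image size | 224 | inputs resized (bilinear); random horizontal flip in training |
| MIC bound | n^0.6 (λ override) | grid cell-count bound; `max_grid_side` 5 |

"Best results" over epochs is interpreted as the checkpoint with the
best validation total loss — the only model-wide scalar available every
epoch.

## Synthetic data

The generator emulates a desk-scale radiology VQA corpus: grayscale
pseudo-radiographs whose scene description (modality-coded background,
plane corner marker, 2–4 organ ellipses at loosely anatomical canonical
positions, optional bright abnormality) fills question templates in six
categories, with per-question categories drawn i.i.d. from weights that
default to the emulated corpus tallies (312, 290, 290, 484, 742, 1772).
Each image gets 3–5 questions.  Everything is deterministic given the
spec seed.

What it deliberately does **not** emulate: medical plausibility beyond
attribute consistency, free-form question phrasing (the grammar is
closed — ~12 templates — so a trained model can reach near-perfect
BLEU and 0% Inventiveness on it), ambiguous or multi-label categories,
and realistic image statistics.  Passing the training properties here
shows the optimization behaves as designed, not that the model reaches
any particular quality on real radiology data.

Ground-truth selection (`select_ground_truth`) picks up to k
same-category questions greedily minimizing mean pairwise embedding
similarity: seeded with the least-similar pair, then adding the
candidate with the lowest summed similarity to the chosen set; ties
break by input order.  Exhaustive subset search is exponential; on ≤6
candidates the greedy result is verified to stay within 10% of the
exhaustive optimum.

## Evaluation

BLEU (corpus-level, clipped precision, brevity penalty), ROUGE-L
(LCS-F with β = 1.2, max over references, corpus mean) and CIDEr
(tf-idf n-gram cosine consensus, n = 1..4, ×10; a CIDEr-D flag adds
count clipping and the Gaussian length penalty) follow their published
definitions.  METEOR is the exact-unigram-match variant — no stemming
or synonym resources — with Fmean = 10PR/(R+9P) and the 0.5·(chunks/m)³
fragmentation penalty; scores are therefore conservative relative to
the full matcher.  Inventiveness counts exact matches of normalized
token sequences (the strictest reading of "completely different").
Similarity is the mean pairwise inner product of unit-norm sentence
embeddings within an image's question set, averaged over images with at
least two questions.  The default embedder is an offline
character-3-gram hashed bag vector (md5-based, 256 dims, L2-normalized)
— deterministic and dependency-free; an external semantic encoder can
be registered behind the same contract and will change Similarity
values but none of its invariants.  The printed reference values of the
Similarity metric for specific sentence pairs (0.77 / 0.6) are
properties of the external universal-sentence-encoder features and are
not reproduced by the offline embedder.

Latent separation is the mean silhouette coefficient (Euclidean, space
index as label) of the K spaces' samples — a quantitative stand-in for
eyeballing a tSNE embedding.

## The desk-scale benchmark

`divqg.benchmark` fixes the configuration used by the training-property
tests and the acceptance script: 200 synthetic 32×32 images (train 150
/ val 30 / test 20), K = 2, d_z = 16, a (4, 8, 16, 16)-channel CNN,
64-wide MLPs, a 2-layer/96-hidden decoder, 10 epochs.  The optimizer is
scaled to the problem size — base lr 0.01, batch 16 — because the
full-scale protocol (1e-3, batch 32) yields only ~50 updates here,
visibly undertrained.  Flip augmentation stays on as in the full-scale
protocol; note that mirroring the anatomy but not the question text
turns the left/right slot of roughly a tenth of the samples into label
noise.

Exact pairwise MIC and the separation score are measured on the
validation images' reparameterized samples; category control asks, for
every category, what fraction of questions generated on test images
parse back to that category under the template grammar.

## Known limitations

- At desk scale the MIC term (β = 1, surrogate in [0, 1]) is comparable
  in magnitude to the converged generation loss over the ~50-word
  template vocabulary, so it exerts proportionally far more pressure
  than in a full-scale regime where the generation loss over a real
  medical vocabulary dominates; a small generation-loss cost of the
  diversity loss is visible in the benchmark.
- With deterministic inference, the K decoded questions of one category
  frequently coincide on the closed template grammar; the diversity
  effect is measured in latent space (pairwise MIC, separation) rather
  than in surface text at this scale.
- Exact MIC is exponential in the exhausted axis's bin count; it is
  intended for the small bounds used here (n up to a few hundred,
  sides ≤ 5), not as a general-purpose MIC library.
- The numpy autodiff core is single-device and eager; it is sized for
  the desk-scale models in this package, not for ResNet-scale training.
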