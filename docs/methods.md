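# Methods

## Problem

Given a drug × side-effect matrix of known frequency classes (five
ordered labels: very rare = 1, rare = 2, infrequent = 3, frequent = 4,
very frequent = 5; 0 marks unknown pairs), predict the class of unseen
pairs.  The package treats this as multi-class classification over
multi-source similarity features rather than as regression, which
removes the class-boundary ambiguity that regression formulations must
resolve post hoc.

## Similarity sources

Eleven drug similarities and four side-effect similarities are built
from raw inputs:

| name | input | method |
|---|---|---|
| `stitch_*` (5 channels) | chemical–chemical association scores, integers 1–1000 | score / 1000, absent pair → 0, diagonal → 1 |
| `structure` | binary fingerprint vectors | Tanimoto (Jaccard) |
| `target` | binary drug–target incidence | cosine |
| `word` | real substructure embeddings | cosine, clipped to [0, 1] |
| `pathway_enzyme` | drug–pathway × pathway–enzyme product | cosine of product rows |
| `dipa` / `dipf` (drug and side-effect) | frequency-class matrix rows / columns | cosine of binarized (`dipa`) or raw-class (`dipf`) profiles |
| `semantic` | side-effect term DAGs | Wang decayed-contribution similarity |
| side-effect `word` | term embeddings | cosine |

Every matrix is validated to be symmetric within 1e-9, unit-diagonal and
in [0, 1].

Numerical choices: a zero profile has cosine similarity 0 to everything
(the diagonal stays 1) — a profile with no information shares nothing,
and this avoids NaNs.  Negative cosines from signed embeddings are
clipped to 0 to preserve the range invariant.  The semantic similarity
uses the Wang contribution scheme with decay 0.5 (configurable): a
term's own S-value is 1, an ancestor's is the maximum of decay ·
S(child), and similarity is the shared-contribution fraction.  The decay
of 0.5 is the standard choice in ontology-based semantic similarity; the
scheme is invariant to node relabeling.

Leakage control: `dipa`/`dipf` are functions of the supervision matrix,
so in pairwise cross-validation they are recomputed per fold from
training entries only (`refit_dsa_similarities`); a `refit_dsa: false`
config flag restores the naive whole-matrix behaviour for comparison.
In cold-start and independent protocols these matrices are removed
entirely (9 drug + 2 side-effect matrices remain), since new drugs have
no known frequencies.

## Feature combinations and network

For drug *i* and side effect *j*, the raw features are the *i*-th rows
of the P drug matrices and the *j*-th rows of the Q side-effect matrices
(P = 11, Q = 4; 9 and 2 masked).  Three combinations feed three
extractor branches:

* **concatenation** (length P·n + Q·m, n drugs, m side effects) → an
  autoencoder whose encoder is linear → self-attention → linear, with a
  two-linear-layer decoder used only for an auxiliary reconstruction
  loss;
* **addition** (length n + m; elementwise sums within each entity's
  vectors) → a second, smaller autoencoder of the same shape;
* **interaction maps** — each raw vector is projected to width h by a
  per-source learnable linear map; the P·Q outer products of projected
  drug and side-effect representations form rank-1 h×h maps (44 full,
  18 masked), processed by three (conv → batch-norm → ReLU) blocks and
  flattened.

Self-attention follows `softmax(QKᵀ/√d_k)V` with a residual
`ReLU(LN(A + X)) + X`.  Attention operates *within* a sample: the hidden
vector is reshaped into t tokens of width hidden/t (default t = 8), so
inference is independent of batch composition.  Single-head attention is
the default; the same block fuses the concatenated branch latents (the
fused vector is zero-padded to a multiple of t for tokenization and
un-padded afterwards).

A variational head maps the fused vector to a Gaussian mean μ and
log-variance, and the latent is sampled by the reparameterization trick
F_l = μ + ε·σ (ε ~ N(0, I) during training, ε = 0 at evaluation, so
predictions are deterministic; sampling at evaluation is available by
flag).  A two-hidden-layer MLP with five sigmoid outputs scores the
classes; the predicted class is the argmax, with ties resolved toward
the lower (rarer) class.

## Loss

L = BCE + α1·MSE(concat branch) + α2·MSE(addition branch) + α3·KL(μ, σ)
+ γ·Σθ².  BCE is elementwise binary cross-entropy of the five sigmoid
scores against the one-hot label — with sigmoid outputs this is the only
shape-consistent reading, and the per-class scores directly feed macro
AUPR.  The KL term is the standard non-negative Gaussian divergence
−½ Σ (1 + log σ² − μ² − σ²); a `paper_literal_kl` flag reproduces the
sign-flipped variant for comparison, but the non-negative form is the
default because the term is meant to regularize toward the prior.  The
reconstruction targets are the branch *inputs* (the standard autoencoder
contract).  L2 is applied through the explicit γ term, not optimizer
weight decay.

Defaults: learning rate 1e-4, dropout 0.4, batch 128, latent d = 64,
γ = 1e-5 (the grid-search optima for the benchmark-scale setting;
`pipeline.GRID_RANGES` carries the published search ranges), and
α1 = α2 = 0.1, α3 = 0.01 as small-weight defaults.  Training uses Adam
with early stopping (patience 10) on the BCE loss of a seeded 10%
slice of the training pairs — carved from training only, never from the
test fold.

## Evaluation protocols and metrics

* **pairwise**: known pairs shuffled into k = 10 near-equal folds;
* **cold start**: drugs partitioned into k folds; a fold's test pairs
  are all known pairs of its drugs; bank masked to 9 + 2;
* **independent**: explicit drug id lists for train and test, verified
  disjoint; bank masked.

Eight metrics: accuracy, weighted and macro F1, Cohen's κ, multiclass
(R_k) MCC, macro precision and recall with zero-division mapped to 0,
and macro one-vs-rest AUPR by trapezoidal integration of the
precision-recall curve (classes absent from a test fold are skipped
with a warning, so the average stays well-defined on small folds).

Regression baselines producing continuous scores are converted to
classes by fitting one Gaussian kernel density per class on training
scores (Scott bandwidth) and assigning each new score the class of
maximal density — unweighted by default, prior-weighted by flag.  A
degenerate class (fewer than two distinct scores) falls back to a
Gaussian at the class mean with bandwidth 0.05.

## Synthetic study

The generator emulates every raw source with planted structure: drugs
and side effects receive latent clusters; a cluster-pair table assigns
base classes covering all five labels with mild geometric imbalance;
`density` of the pairs is revealed, each resampled uniformly with
probability `noise_rate`.  Same-cluster entities share fingerprint
cores, target and pathway blocks, embedding centroids and DAG
ancestors, and receive high association scores.  The default study
conditions are 40 drugs × 50 side effects, density 0.3, noise 0.1 —
600 known pairs.  A nearest-centroid check on concatenated similarity
rows confirms the signal is linearly recoverable before any deep model
is invoked.

What the fixture does **not** emulate: the scale of real
pharmacovigilance data (hundreds of drugs, ~10⁵ known pairs), realistic
class marginals, heavy-tailed similarity distributions, or correlated
noise between sources.  Passing on the fixture demonstrates that the
machinery — builders, leakage control, training, metrics — is correct
and that the model recovers plantable structure; it does not certify
benchmark-level accuracy on real data.

## Desk-scale profile

`RunConfig.desk_scale()` sizes the model for the synthetic study:
projection width h = 8, CNN channels (8, 16, 16), autoencoder hidden
widths 128/64, latents 32, d = 32, learning rate 1e-3, batch 64, up to
60 epochs with patience 8.  With tens of entities the full-scale widths
(h = 16, channels 32/64/64, hidden 256) are over-parameterized and
slower without being more informative; the package defaults keep the
full-scale values.

## Known limitations

* The tensor engine is CPU-only, float64, dense; it is sized for the
  desk-scale studies, not for the 757×994 benchmark geometry.
* The exact semantic-similarity variant used by the upstream similarity
  pipeline is not published; the Wang scheme with decay 0.5 is this
  package's documented choice.
* Whether DIPA/DIPF should be refit per fold in pairwise CV is not
  specified upstream; refitting is the default here because the
  alternative leaks test-fold labels into the features.
* Ordinal structure of the classes is not exploited; the loss treats
  classes as unordered, matching the published formulation.
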