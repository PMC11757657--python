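# Methods

This document describes the model and procedures implemented by
`pannet-ips`: what each stage computes, the assumptions it makes, the
tunable parameters and their defaults, and the design of the synthetic
cohort generator used for development and testing.

## 1. Problem setting

Pancreatic neuroendocrine tumors (PanNETs) are graded in part by how the
tumor infiltrates the surrounding non-neoplastic pancreatic parenchyma
(NNPP). A pathologist assigns each slide an infiltration score from 1
(pushing, well-demarcated border) to 5 (diffusely infiltrative). A case is
represented by three slides; the sum of the three slide scores maps the
case to an **Infiltration Pattern Score (IPS)** class:

| total of 3 slide scores | class |
|---|---|
| 3–6 | IPS1 |
| 7–9 | IPS2 |
| 10–15 | IPS3 |

The package predicts the case-level IPS class from whole-slide images via
a two-stage pipeline: a tissue-type classifier produces a patch-level
prediction map, and a graph neural network (GNN) classifies cell-graphs
built on patches sampled at the tumor–parenchyma interface. Case
predictions are obtained by voting over all patch predictions of the
case's slides.

## 2. Tissue prediction map (`tissue_map`)

Each slide is tiled into non-overlapping square patches (default 256 px).
Patches whose non-white fraction falls below `tissue_threshold` (default
0.1; "white" is luminance > 0.9) are labeled background without
classification. Remaining patches are optionally stain-normalized
(Reinhard normalization in CIELAB: shift/scale each channel to reference
means and standard deviations) and summarized by an 8-dimensional
color/texture feature vector (per-channel means and standard deviations,
luminance entropy, gradient energy). A multinomial logistic regression
with inverse-class-frequency weights maps features to one of three
foreground tissue types: PanNET tumor, NNPP, and stroma.

The classifier is deliberately simple: the package's contribution is the
interface-sampling and graph-classification stages, and any patch
classifier that fills the `TissueClassifier` contract (per-patch
probabilities over the four tissue codes) can be substituted, including a
CNN trained elsewhere. The output is a `PredictionMap`: an integer label
grid plus per-patch class probabilities, serializable losslessly to
TSV + JSON.

Tissue label codes are fixed integers: background 0, PanNET 1, NNPP 2,
stroma 3.

## 3. Interface patch selection (`patch_selection`)

From the label grid the pipeline:

1. finds the **largest tumor region of interest (TRoI)**: the largest
   connected component of PanNET patches (4-connectivity by default;
   8-connectivity available). Ties are broken deterministically by the
   smallest row-major coordinate of any member;
2. marks **border patches**: TRoI patches with at least one 4-neighbor
   labeled NNPP or stroma. Background does not qualify — a tumor edge
   facing glass says nothing about infiltration;
3. assigns every other TRoI patch a **hop distance**: its breadth-first
   graph distance (within the TRoI) from the border set, and keeps
   patches with hop distance ≤ `max_hops` (default 6).

The hop distance is the supervision-weighting signal in stage two:
patches at distance 0 straddle the invasive front and carry the
infiltration phenotype; deep patches look like bulk tumor regardless of
the case's pattern.

## 4. Cell-graphs (`cell_graph`)

For each selected patch, nuclei (from a segmentation tool such as
HoVer-Net, whose JSON export dialect is read directly, or from the
synthetic generator) become graph nodes with five morphology features:
area, eccentricity, solidity, mean intensity, and perimeter. When only
contours are given, features are computed from the polygon (shoelace
area, eigen-moment eccentricity, convex-hull solidity, polygon
perimeter).

Edges are the union-symmetrized k-nearest-neighbor relation (k = 5) over
centroid distance, restricted to pairs within `max_edge_dist` (50 px).
Each edge is weighted by the cosine similarity of the two nuclei's
within-patch z-scored feature vectors, mapped from [−1, 1] to (0, 1] via
(cos + 1)/2, so that weight ≈ 1 means histomorphologically alike cells.
Edges with weight 0 or below `similarity_threshold` are dropped.

Before training or inference, node features are standardized with
mean/variance statistics fit on training graphs only; zero-variance
dimensions map to 0.

## 5. Graph classifier and infiltration-weighted loss (`gnn`)

No deep-learning framework is assumed; the GNN is the package's own
NumPy implementation with manual backpropagation and Adam. Each
message-passing layer is GIN-style:

    H' = ReLU(ReLU((H + A·H) W1 + b1) W2 + b2)

with A the binary symmetric adjacency (sparse CSR, graphs batched
block-diagonally). After `n_layers` (default 3, hidden width 32), a
graph embedding is read out (mean by default; sum and max available),
passed through dropout (0.1) during training, and classified by a linear
softmax head over the three IPS classes. Training runs Adam
(learning rate 0.01) for `epochs` (default 40) over shuffled mini-batches
(size 32) and is bitwise deterministic for a fixed seed on one CPU.

Supervision is weak: every patch inherits its **case's** IPS label. The
**infiltration loss** focuses learning on the invasive front by weighting
each patch's cross-entropy by its hop distance d:

    w_i = exp(−λ d_i) / Σ_j exp(−λ d_j)        (softmax over −λd, per batch)
    L   = Σ_i w_i · CE_i

λ = `decay_rate` (default 0.5). λ = 0 recovers the plain mean
cross-entropy, which serves as the ablation baseline.

At inference, a case's bag is the set of graphs from all interface
patches of its three slides. The case class is the **plurality vote**
over patch argmax predictions; ties break first by summed class
probability, then by class order. A Graph-GradCAM-style node attention
map (rectified, max-normalized product of last-layer activations with the
channel-averaged gradient of the class logit) is provided for
inspection.

## 6. Evaluation (`evaluation`)

`classification_report` computes per-class precision/recall/F1 and the
support-weighted F1 (reported in percent). Cross-validation is
**case-level and stratified**: all slides of a case share a fold; folds
are formed by a seeded shuffle and round-robin assignment within each
class, so fold class counts differ by at most one. Feature
standardization is fit on training folds only. The headline number is the
weighted F1 of pooled case predictions, reported as mean ± std over
per-fold runs.

## 7. Synthetic cohort generator (`fixtures`)

Real slides cannot ship with the package, so development and testing use
a generative model that reproduces the *signal structure* the pipeline
exploits, at toy scale.

**Cohort.** `n_cases` (default 35) cases are assigned IPS classes by
target proportions (default 20.0 / 51.4 / 28.6%, largest-remainder
rounding). Each case draws three slide scores from its class's total
band. Within a band, triples are weighted by
`exp(−κ·(max−min))` with κ = `score_concordance` (default 2.0): a
pathological case tends to show a consistent pattern across its slides,
and uniform triples would make adjacent classes nearly indistinguishable
at the slide level (brute-force enumeration of all score→class voting
rules caps weighted F1 near 0.66 under uniform triples — below any
useful operating point — versus ≈ 0.86 at κ = 2 and ≈ 0.97 at κ = 4).

**Tissue maps.** Each slide is a label grid (default 16×16): a central
tumor blob whose radius is modulated by random low-order harmonics with
amplitude `roughness × slide_score` (rougher borders for higher scores),
surrounded by NNPP with a stroma fraction (0.20) carved out by a
smoothed-noise quantile, background outside the tissue ellipse. The
largest tumor component is kept; stragglers are relabeled NNPP.

**Nuclei.** Each selected patch receives on average 30 nuclei drawn from
Gaussian morphology components (tumor-like, parenchyma-like,
stroma-like). The parenchyma-like admixture decays with hop distance d
and grows with slide score s:

    fraction(d, s) = (m0_base + m0_slope·(s − 1)) · exp(−mixing_decay · d)

defaults m0_base = 0.15, m0_slope = 0.15, mixing_decay = 0.5. This is
exactly the interface-decay structure the infiltration loss is designed
to exploit: the class-discriminative signal lives at small d.

`easy_cohort_config` is a preset for demonstrations and end-to-end
checks: balanced classes, 12×12 grids, a stronger score dependence
(m0_base = 0.05, m0_slope = 0.20), and κ = 4.0, giving a cohort on which
the full pipeline should score well when healthy.

**What the generator does not emulate:** real stain variation and
artifacts, multifocal tumors, realistic nuclear texture or spatial
clustering, inter-observer score noise, and any correlation between
tissue architecture and morphology beyond the single interface-mixing
mechanism. Results on synthetic cohorts validate the machinery, not
clinical performance.

## 8. Numerical and reproducibility choices

- All randomness flows from `numpy.random.SeedSequence`; cohort
  generation spawns child sequences per case/slide, so results are
  identical for a fixed seed regardless of generation order.
- The softmax in the loss and head subtracts the row max before
  exponentiation; the loss weights normalize over the batch.
- Cosine similarity treats two zero feature vectors as identical
  (similarity 1); a zero against a nonzero vector yields weight 0 and the
  edge is dropped.
- Solidity uses the convex hull's 2-D volume (its area); degenerate
  (collinear) contours fall back to solidity 1.
- Adam uses standard bias correction (β₁ = 0.9, β₂ = 0.999, ε = 1e−8).
- Default problem sizes (16×16 grids, ~30 nuclei/patch, ≤ 100-case
  cohorts) are chosen so every documented workflow runs in seconds to a
  few minutes on a single CPU core.

## 9. Known limitations

- The feature-table tissue classifier is a stand-in; on real slides a
  CNN trained on annotated tiles should replace it via the
  `TissueClassifier` contract.
- Weak supervision assigns the case label to every patch; slides of a
  discordant case (e.g. scores 2, 2, 5) contribute mislabeled patches,
  mitigated but not removed by the distance weighting and case-level
  voting.
- Plurality voting ignores patch-count imbalance between slides; a slide
  with a large interface dominates the bag.
- The GNN is unregularized beyond dropout and early-ish stopping via a
  fixed epoch budget; no validation-based model selection is performed
  inside a fold.
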