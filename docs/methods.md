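# Methods

This note documents the statistical model, the algorithmic choices, and
the limits of what the package's tests demonstrate.

## Problem setting

The pipeline targets binary tumor/normal classification of liver
hepatocellular carcinoma from two omics layers — microarray gene
expression and DNA methylation — measured on *different* sample cohorts
over a shared gene universe, followed by ranking of the genes that drive
the classification. The two practical obstacles it addresses are
high-dimension/low-sample-size cohorts and the fact that the two layers do
not share samples, only genes.

## Preprocessing

Per layer: probes mapping to the same gene are averaged (missing entries
ignored in the mean); remaining missing values are imputed with the mean
of the gene over the sample's own label group; a gene missing across an
entire label group cannot be recovered and is dropped with a logged count.
Each gene is then min-max scaled to [0, 1] across **all** samples of the
layer, train and test pooled. That ordering (normalize, then split)
follows the source workflow faithfully but leaks test-set ranges into
training; with per-gene min-max the effect is a monotone per-gene rescale
and does not change rank-based conclusions, but users comparing against
strictly leak-free protocols should re-normalize on the training split.
Constant genes map to 0 rather than erroring — degenerate but harmless
downstream (they become edgeless in the graph and carry no gradient).

## Differential screening

Fold change is the ratio of group means computed on the raw linear
positive scale (ratios of min-max values are meaningless because minima
are 0); a `log2_input` flag computes FC as 2^(meanT − meanN) for
log-scale matrices. Significance is a two-sided Welch two-sample t-test
(the safer default when group variances differ). Thresholds are strict
inequalities: FC > 2 (expression), FC > 1.2 (methylation), p < 0.05, raw
p-values with **no multiple-testing correction** — a deliberately liberal
screen whose output is only a candidate panel, not an inference. Only
upregulated genes are kept; the panel is the sorted intersection of the
two layers' selections, and an empty intersection is a hard error
suggesting threshold relaxation.

## Cartesian-product integration

Tumor pairs are all (tumor expression sample × tumor methylation sample)
combinations; likewise normals. Each pair is represented as one node per
panel gene carrying a 2-vector (expression, methylation) — gene-level
nodes match the co-expression graph's vertices; the alternative of 2G
separate nodes per pair was rejected as it has no gene-level graph to
attach to. Pair order is deterministic (tumor block first, expression-
major).

The default 7:3 split is stratified by class at the **pair** level with
train size floor(0.7·n) per class, which is faithful to the source
workflow but lets a source sample contribute pairs to both partitions. A
`grouping="source"` option keeps all pairs of an expression sample in one
partition. The consequence of pair-level splitting is measurable: in our
label-shuffle experiments a model trained on pair-split shuffled-source
labels still reaches AUROC ≈ 0.95 purely by memorizing source-sample
identity. Held-out performance under the default split therefore
overstates generalization to new patients; the honest null (below) and
the `source` grouping are provided for that reason.

## Co-expression graph

For genes i, j with Pearson correlation r_ij, the signed power adjacency
is C_ij = ((1 + r_ij)/2)^α. Each training pair contributes its expression
channel and its methylation channel as two separate observations of every
gene, so the correlation treats the channels symmetrically; the graph is
always computed from training pairs only and the observation matrix is
fingerprinted into the graph object. Constant genes get r = 0 (edgeless)
with a warning.

α is the smallest candidate in 1..20 whose scale-free topology fit
reaches signed R² ≥ 0.8 (connectivities k_i = Σ_j C_ij binned into 10
bins; log10 frequency regressed on log10 mean connectivity; the index is
−sign(slope)·R² so only decaying degree distributions score). If no
candidate reaches the target the best-fitting one is returned with a
warning; fully degenerate connectivity falls back to the conventional
α = 6. The reference experiments fix α = 6 so that within-module edges
survive binarization (0.9⁶ ≈ 0.53 > 0.5) while uncorrelated pairs do not
(0.5⁶ ≈ 0.016).

The edge matrix is A_ij = 1 iff C_ij > adj_thresh (strict), diagonal
forced to 1: self-loops are required so every node attends to itself.
`adj_thresh` defaults to 0.5 and can be grid-searched on validation AUROC
of a budget-capped model (`tune_adj_thresh`), ties breaking toward the
sparser graph.

## MLA-GNN

Each attention layer computes, per edge with A_ij = 1,
e_ij = LeakyReLU(a_src·Wh_i + a_dst·Wh_j) (slope 0.2), softmax-normalizes
e over each node's neighborhood (additive −1e9 mask on non-edges), and
updates h_i′ = ELU(Σ_j att_ij W h_j + b); multi-head outputs are
concatenated. Defaults: 1 head, hidden width 8, projection width 8 — all
configurable. Level features: G1 is the untouched input; G2 and G3 follow
layers 1 and 2; G2′, G3′ are equal-width linear projections; F1/F2/F3 are
node-major flattenings and F is their concatenation, feeding a linear
2-class head with dropout 0.4 on F during training.

Training minimizes cross-entropy with inverse-frequency class weights by
default (the Cartesian product is imbalanced, e.g. 3,432 : 7,590), using
Adam at lr = 0.005, batch size 64, up to 100 epochs with early stopping on
validation loss (patience 10) when a validation set is supplied. All
randomness — initialization, shuffling, dropout — derives from a single
seed, and a non-finite loss aborts with diagnostics.

The network, including the attention softmax, runs on a minimal
reverse-mode autodiff engine written for this package; every operator's
vector-Jacobian product is checked against central finite differences in
the test suite, and a full-model gradient check against numerical
differentiation passes at ~1e-10.

## Full-gradient saliency

For each scored sample the gradient of its predicted-class logit is taken
with respect to G1 (level F1), G2′ (F2) and G3′ (F3) — gradients at the
level features themselves, not only at the leaves. The per-node
attribution at a level is feature × gradient summed over that node's
coordinates, plus the producing layer's bias × gradient term accumulated
per node (the full-gradient decomposition's bias path; G1 has no bias
site). Setting `include_bias=False` falls back to plain gradient × input.
The fused-F attribution is the sum of the three levels (F is their
concatenation, so its gradient decomposes exactly). Per-gene scores are
the mean absolute attribution over the scored samples — a deliberate
choice, since a single representative sample would make rankings depend
on which sample was picked. Deeper bias sites (inside the attention
layers) are not attributed; their contribution is shared across nodes
through the attention weights and has no unambiguous per-node assignment.

## Synthetic cohorts and what the tests show

The generator draws each gene as baseline + effect + noise on a linear
positive scale: baseline 2·noise_sd, Gaussian noise, values clipped at
0.05 so ratio fold changes are defined. Planted genes get a tumor-mean
shift of effect_size·noise_sd in **both** layers (effect 3 ⇒ FC ≈ 2.5,
above the FC > 2 screen). Module structure uses one latent factor per
block, x = √ρ·z + √(1−ρ)·ε, giving exact within-module correlation ρ in
expectation. Duplicated probes repeat a gene's row with fresh noise and a
probe-suffixed id plus a probe→gene map; missing values are injected
uniformly at random.

Defaults are 200 genes, 30/30 samples per group and layer, 10 planted
genes at effect 3, four modules of 20 genes at ρ = 0.8, noise SD 1. The
reference experiments (`mlagnn.experiments`) use 100 genes with 20/20
samples per layer for recovery and 50 genes with 15/15 for the null —
sizes chosen so the whole suite runs comfortably on a single CPU while
keeping the statistical conclusions stable across seeds.

What the generator does **not** emulate: beta-distributed methylation
values, batch effects, probe-level biases, heavy-tailed expression noise,
and missing-not-at-random patterns. Passing tests therefore demonstrate
the pipeline's correctness and its behavior under the stated statistical
model, not performance on real clinical cohorts; the near-perfect AUROC and
10/10 saliency recovery reflect a well-separated synthetic regime
(effect 3 SD with ~560 training pairs), not expected clinical accuracy.

The label-shuffled null permutes **pair** labels after integration.
Shuffling source labels instead is not a valid null here (see the
integration section); the pair-level permutation yields mean test AUROC
≈ 0.50 over ten seeds, confirming the training loop does not manufacture
signal.

## Numerical choices and degenerate inputs

- Min-max of a constant gene → 0; normalization is idempotent to 1e-12.
- Zero normal group mean → FC = +inf with a warning; zero variance in both
  groups with equal means → t = 0, p = 1.
- Attention mask uses an additive −1e9 before the softmax; masked weights
  underflow to exactly 0 and rows sum to 1 within 1e-6 (observed ≤ 2e-16).
- Matrix TSVs are written with `%.17g` and read with round-trip float
  parsing, so write→read is bit-exact and run manifests hash stably.
- Split tie policy: train size floor(fraction·n) per class.
- tune_adj_thresh ties break toward the larger threshold (sparser graph).

## Known limitations

- Pair-level splitting leaks source samples across partitions (documented
  above); use `grouping="source"` for patient-level claims.
- The scale-free criterion is unreliable on small panels; on unstructured
  data it can still cross R² = 0.8 at high powers, which is why the
  reference experiments pin α.
- The autodiff engine is single-threaded numpy; cohorts beyond a few
  thousand pairs × a few hundred genes will train slowly.
- Probabilities from the linear-SVM baseline use Platt scaling via
  scikit-learn's deprecated `probability=True`; the harness will need
  updating when scikit-learn removes it.
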