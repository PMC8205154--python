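# Methods

`gcsenet` predicts miRNA–disease (or miRNA–phenotype) associations from a
three-layer heterogeneous network of diseases, genes and miRNAs. This note
describes the model as implemented, the choices made where the design was
genuinely open, what the synthetic data generator does and does not emulate,
and the numerical details that matter for reproducing a run.

## Pipeline

1. **Similarity layers.** Disease–disease similarity comes from a term
   hierarchy (MeSH-style DAG): each disease D induces decayed contributions
   over its ancestor closure, D_D(D)=1 and
   D_D(t) = max over children ṫ of Δ·D_D(ṫ) (Δ = 0.5 per step), and two
   diseases are scored by the contributions of shared ancestors normalised by
   their total semantic values. miRNA–miRNA similarity is the best-match
   average between the miRNAs' associated disease sets. For phenotype mode a
   Resnik similarity is provided: −ln(N_pm/N) of the fewest-annotated common
   ancestor, with gene annotations propagated up the DAG (the ancestor set is
   reflexive; natural log — the base only rescales).
2. **Network assembly.** Similarity matrices are sparsified to k-nearest
   neighbours (k = 15, ties broken by identifier) with the similarity kept as
   edge weight; disease–gene, miRNA–gene and gene–gene edges come in as
   weighted lists. Diseases without any gene edge are dropped — the gene
   layer is the only path by which the encoder can say anything about them.
   Association labels are held apart from the graph: no label ever becomes an
   edge, which makes the held-out evaluation guard structural rather than
   procedural.
3. **Encoder.** An edge-typed (relational) GCN with three layers and one
   weight matrix per connection type {dd, gg, mm, dg, gd, mg, gm} plus a
   per-node-type self weight. Messages are normalised by
   c_ij = 1/√(n_i·n_j) with per-relation neighbour counts, counted
   self-inclusively for within-type relations and with the self term scaled
   by 1/(deg+1), so on a homogeneous graph the layer reduces exactly to
   ReLU(D^−1/2(A+I)D^−1/2 H W). Inputs are one-hot per node within its type;
   the first layer therefore acts as an embedding lookup. Bilinear decoders
   σ(z_aᵀ W_rel z_b) score disease–gene and miRNA–gene links; the encoder is
   trained on those two link-prediction tasks (per-batch 1:1 resampled
   negative non-edges, binary cross-entropy, Adam lr 1e-2, L2 2e-3, dropout
   0.25 on layer inputs) and then frozen.  The encoder's own training
   settings (epochs, edge batch, dropout) carry no standard reference —
   the method's quoted optimiser settings belong to the classification
   stage — and were selected on held-out link prediction during
   development;
   heavier input dropout hurt link generalisation because dropping one-hot
   inputs deletes node identities outright. Training is two-stage by design:
   the decoders define standalone link probabilities which are exactly what
   the feature stage consumes, so nothing downstream back-propagates into
   the encoder.
4. **Features.** For a candidate pair (d, m), three channels over the fixed
   (lexicographic) gene axis: x_d[j] = (1+D_dg_j)·p(d,g_j),
   x_m[j] = (1+D_mg_j)·p(m,g_j), and x_dm = α·x_d + (1−α)·x_m with α = 0.57
   (0.5 in phenotype mode). D is the reciprocal typed degree of the gene
   (0 for isolated genes): a gene attached to a single disease is maximally
   up-weighted (×2) because that one association is maximally specific.
   Channels are z-scored per channel and gene position using training-split
   statistics only; zero-variance positions pass through centred but
   unscaled.
5. **Classifier.** 1-D convolution along the gene axis (16 filters, width 4),
   squeeze-and-excitation gating on the filter channels (global average
   squeeze, bottleneck ratio r = 4, sigmoid gates), max pooling (width 2),
   one hidden fully connected layer (64), softmax over two classes.
   Cross-entropy, Adam lr 1e-2, L2 2e-3, dropout 0.5, batch 64, 150 epochs
   (phenotype mode: batch 128, 20 epochs). Inverse-frequency class weights
   switch on automatically when one class outnumbers the other by more than
   1.5:1.

All linear algebra is dense numpy; gradients come from a small in-repo
reverse-mode autodiff core (`gcsenet.autodiff`) whose every operation is
checked against central finite differences in the test suite. At the scales
this package targets (hundreds of nodes, thousands of labeled pairs) full
dense passes on one CPU core are faster than any sparse or accelerator
machinery would be.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| Δ (`delta`) | 0.5 | per-step semantic contribution decay in the term DAG |
| α (`alpha`) | 0.57 / 0.5 | disease-channel weight in the combined channel (disease / phenotype task) |
| k (`knn_k`) | 15 | neighbours kept when sparsifying similarity matrices |
| c (`embed_dim`) | 64 | node embedding dimension (constant across layers) |
| layers (`gcn_layers`) | 3 | graph convolution depth |
| r (`se_ratio`) | 4 | SE bottleneck compression |
| lr / L2 / dropout | 1e-2 / 2e-3 / 0.5 | optimiser settings (both stages; classifier dropout 0.5, encoder input dropout 0.25) |
| batch / epochs | 64 / 150 (128 / 20) | classifier training (disease / phenotype) |
| `neg_ratio` | 1.0 | negatives sampled per positive |
| `folds`, `grouping` | 10, by-disease | CV shape; by-disease keeps all of a disease's pairs in one fold |

The CNN's shape parameters (filters 16, kernel 4, pool 2, hidden 64) have no
standard reference values; they are this package's own defaults, exposed in
`RunConfig`. Encoder epochs default to 100 minibatched passes over the
positive edges (batch 128 edges per relation per step).

Two numerical choices deserve a note. First, Glorot initialisation assumes
dense inputs; with one-hot inputs pushed through degree-normalised sparse
adjacencies, activations attenuate several-fold per layer and the bilinear
scores start pinned at σ(0), where fitting stalls (or, with a larger
learning rate, collapses into dead ReLUs). Layer weights are therefore
initialised at 3× the Glorot scale (`init_params(gain=...)`). Second, the
encoder epoch is a *minibatched* pass over positive edges rather than one
full-batch step — with only ~100 full-batch steps Adam cannot reach a useful
link-prediction fit.

## Ambiguities resolved

- "All relationships with a particular disease should be put into separate
  folds" is read as *grouped-by-disease* (one fold holds all of a disease's
  pairs), consistent with the leakage-prevention intent; `grouping="by-pair"`
  remains available. Homologous-gene grouping is not modelled (no homology
  data exists for synthetic genes).
- The SE block sits between convolution and pooling, once.
- The squeeze is standard global average pooling with the spatial extent
  specialised to 1-D (channels × genes).
- Ties in the ancestor-decay max and the Resnik argmin are resolved by value
  only; terms with zero propagated annotations are excluded from the Resnik
  minimum (−log undefined).
- A miRNA with an empty disease set has no defined functional similarity;
  the package raises instead of returning 0.
- Precision/recall/F1 use threshold 0.5 on the class-1 probability;
  undefined ratios are reported as NaN with a warning.
- Because labels are never graph edges, the encoder's fit is independent of
  any train/test split of the labels; `run_cv` therefore fits the encoder
  once per run and shares it across folds (`encoder_per_fold=True` restores
  literal per-fold refitting, at ten times the encoder cost and identical
  leakage properties).

## Synthetic data: what it emulates and what it does not

The generator plants a *gene-mediated* association signal. Every node gets a
latent u ~ N(0, I₈). Bipartite edges are Bernoulli with probability
σ(u_a·u_b + b), the intercept b bisection-calibrated per edge type to target
densities (disease–gene and miRNA–gene 2.5%, gene–gene 2%); dd/mm
similarities are cosines of the latents mapped to [0,1]; labels mark the top
q = 3% of σ(u_m·u_d) — matching the positive rate of curated miRNA–disease
databases. Because disease–gene and miRNA–gene edges share the gene latents,
miRNA–disease association is learnable through the gene layer, which is
precisely the structural assumption the architecture encodes; σ(u_m·u_d) is
an oracle score no learned model should systematically beat. The disease
term DAG is a random rooted tree over the disease identifiers plus forward
edges that create multi-parent terms, and its gene annotations are the
disease–gene edges, so ontology code paths run on the same entities.

What passing tests on this generator shows: the implementation can recover a
planted low-rank, gene-mediated signal well above both chance and a
learning-free gene-overlap baseline, with every component wired correctly.
What it does not show: performance on real curated databases, whose degree
distributions are heavy-tailed and whose labels are biased by study effort —
none of which the generator reproduces.

Evaluation protocols scale with the task: the headline result is full
10-fold grouped CV at full training strength (~900 labeled pairs at 1:1).
The ablation, ratio and null-control sweeps use one stratified 80/20 split
per seed with shortened training (40 classifier / 50 encoder epochs, epochs
shrunk further as the labeled set grows in the ratio sweep) — these are
comparisons *between* runs, where a shared, cheaper protocol is the point.
The ratio sweep holds one 1:1 test split fixed and varies only the
*training* ratio, so its numbers isolate the effect of class imbalance from
test-set composition. At 3% prevalence a 15000-cell label grid cannot
supply 50 or 100 negatives per positive for *all* positives; the sweep
realises those ratios exactly by subsampling training positives (seeded) to
the largest count the grid supports. The label-shuffle control replaces the
label matrix with a uniform random one of equal prevalence; since the
encoder never consumes labels it is fitted once and reused across the five
shuffles.

## Known limitations

- The combined channel x_dm is an exact convex combination of x_d and x_m,
  so after normalisation it adds no information a convolution could not
  synthesise; on synthetic data its ablation is expected to be
  performance-neutral (any benefit on real data plausibly reflects
  optimisation dynamics rather than information content).
- Two-stage training is the default and only fully supported mode; joint
  encoder+classifier training is an extension point, not implemented.
- Dense adjacencies bound practical graph sizes to a few thousand nodes.
- Identifiers are opaque case-sensitive strings; no miRNA naming-dialect
  normalisation or cross-database ID mapping is attempted.
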