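# Methods

## The model

scmomtf analyzes *paired* single-cell multi-omics data: two count matrices
`X⁽¹⁾ ∈ R^{n×v₁}` (RNA) and `X⁽²⁾ ∈ R^{n×v₂}` (ATAC peaks or ADT proteins)
measured in the same `n` cells. One multitask network serves three tasks at
once — dimension reduction, cell-type classification and data simulation —
so the shared representation is shaped by all three objectives:

* **Modality encoders** `E⁽ᵐ⁾` map each cell's per-modality profile to a
  150-dimensional modality embedding `h⁽ᵐ⁾ᵢ = E⁽ᵐ⁾(x⁽ᵐ⁾ᵢ)`.
* **Cell encoder** `E_cell` maps the concatenation `[h⁽¹⁾ᵢ, h⁽²⁾ᵢ]` (length
  300) to the 64-dimensional joint cell embedding `zᵢ` — the dimension-
  reduction output.
* **Decoders** `D⁽ᵐ⁾` reconstruct `x̂⁽ᵐ⁾ᵢ = D⁽ᵐ⁾(zᵢ)`; encoder + decoders
  together form the *generator* used for simulation.
* **Discriminators** `Dis⁽ᵐ⁾` score the probability that a profile is real
  rather than reconstructed; they train adversarially against the generator
  with least-squares (LSGAN) losses.
* **Classifier** is a single affine layer + softmax on `zᵢ`, giving class
  probabilities `yᵢ` over the `C` cell types.

Training minimizes

    L_total = L_res + γ·L_cls + L_gen + L_dis

with

* `L_res = (1/nM) Σᵢ Σₘ ‖x̂⁽ᵐ⁾ᵢ − x⁽ᵐ⁾ᵢ‖²` (mean squared reconstruction),
* `L_cls` the cross entropy against label-smoothed targets
  `y_ls = (1−α)·y_onehot + α/C`,
* `L_gen = (1/nM) Σ (Dis⁽ᵐ⁾(x̂⁽ᵐ⁾ᵢ) − 1)²` and
  `L_dis = (1/nM) Σ Dis⁽ᵐ⁾(x̂⁽ᵐ⁾ᵢ)² + (1/nM) Σ (Dis⁽ᵐ⁾(x⁽ᵐ⁾ᵢ) − 1)²`,
  the least-squares adversarial pair.

Updates alternate per minibatch: discriminators first (generator frozen),
then encoders/decoders/classifier (discriminators frozen). `γ·L_cls` enters
the optimized total; the training log records the raw `L_cls` alongside.

### Architecture details

All sub-networks are shallow Linear → LayerNorm → tanh stacks: one hidden
layer (width 256) for encoders and decoders, two for discriminators, and a
bare affine layer for the classifier. Shallowness is deliberate — it keeps
per-feature attribution meaningful and training fast. Layer normalization is
per-sample, so inference is a deterministic row-wise function: embedding a
subset of cells gives exactly the rows of the full-dataset call. The network
is implemented directly in numpy with hand-written reverse-mode gradients
and an Adam optimizer; on these model sizes a minute of single-core CPU
trains the full default benchmark, and every run is bit-reproducible from
its seed.

### Training defaults and why

| parameter | default | rationale |
|---|---|---|
| epochs / batch | 100 / 256 | loss plateaus well before 100 on the benchmark datasets |
| lr (generator, classifier) | 1e-3 | standard Adam default for shallow nets |
| lr (discriminators) | 1e-4 | slower discriminator stabilizes the LSGAN pair |
| α (label smoothing) | 0.1 | common default; caps classifier overconfidence |
| γ (classification weight) | 1.0 | tasks weighted equally |
| input_noise_sd | 0.3 | denoising augmentation (below) |
| class_balance | "oversample" | rare-type handling (below) |
| weight_decay | 0 | available, not needed at benchmark scale |

Two training-time mechanisms deserve explanation because they are the
package's own design choices, not part of the loss definitions:

* **Denoising input noise** (`input_noise_sd`, default 0.3 on the log
  scale): encoder inputs are perturbed with seeded Gaussian noise each time
  a cell is visited; reconstruction targets stay clean. Without it the
  encoders memorize training cells (held-out accuracy ~0.88 on the default
  benchmark versus ~1.0 with it); 0.3 is small relative to the log-scale
  marker signal (~log 4 ≈ 1.4) but large enough to regularize.
* **Class-balanced oversampling** (`class_balance="oversample"`): minibatch
  indices are drawn with probability inversely proportional to class
  frequency, so a 1% cell type is visited as often as an abundant one — and,
  combined with the input noise, each visit is a fresh augmentation rather
  than a repetition. A loss-weighting variant (`"weight"`) and plain
  shuffling (`"none"`) are available.

## Preprocessing

RNA and ATAC counts are depth-normalized to the median per-cell total and
log1p-transformed; ADT counts get a per-cell centered-log-ratio transform
(`log1p(x) −` its per-cell mean), the standard treatment for protein panels.
Highly variable features are selected by mean-binned normalized dispersion
(the seurat-style recipe) — defaults keep the top 4000 genes and 4000 peaks
and *all* ADT features. ATAC peaks use the same dispersion recipe as genes;
whether accessibility should be variance-selected before or after TF-IDF-style
transforms is genuinely ambiguous, and the dispersion route keeps both
modalities symmetric. Cells with zero counts in a depth-normalized modality
are dropped with a warning.

## The synthetic generator

`generate_paired_dataset` plants known structure so every downstream claim
is checkable: `K` cell types drawn i.i.d. from `type_proportions`
(re-drawn until every declared type has ≥ 2 cells, so rare types of 0.1–1%
remain usable in stratified folds); RNA counts from a gamma-Poisson
(negative binomial, shape 2.0) with log-normal per-gene baselines and
per-cell library sizes; ATAC as binarized Bernoulli accessibility (open
probability 0.05 baseline, 0.40 at marker peaks); ADT as negative binomial
over a small protein panel. Each type's markers occupy a disjoint block of
10% of the genes at four-fold elevation — the marker density convention of
splatter-style simulators, reflecting that real cell types differ in a
sizeable fraction of the transcriptome, not a handful of genes; a sparser
planting (e.g. 1% of genes) makes rare types information-poor in a way real
rare populations are not, and no learner — the network, balanced logistic
regression, or L1-sparse regression — can then recover a 1% type from the
handful of training cells available. Marker peak *j* is placed inside the
genomic interval of marker gene *j*, so peak-to-gene attribution has
recoverable truth. Batch effects are additive per-(batch, feature) Gaussian
shifts on the normalized scale (`add_batch_effect`), the first-order model
of a log-scale batch offset.

What the generator does *not* emulate: chromatin co-accessibility structure,
gene–gene correlation beyond type membership, trajectories/doublets/ambient
RNA, multiplicative or nonlinear batch distortions. Passing benchmarks here
demonstrates that the machinery recovers planted structure under NB/Bernoulli
noise at realistic marker densities — not performance on any real tissue.

## Tasks

* **Dimension reduction** — `embed_cells`; quality is scored by k-means
  (k = number of types, 30 restarts) on `z` against the true labels with
  ARI/NMI/AMI.
* **Classification** — `predict_cell_types` (argmax of the classifier);
  evaluated by stratified five-fold cross-validation. Classes with fewer
  cells than folds stay in every training fold with a warning.
* **Simulation** — `simulate_cells` resamples source cells of the target
  type, encodes, perturbs `z` with seeded Gaussian noise (scale =
  `noise_scale` × the per-dimension latent SD of that type, default 0.1) and
  decodes both modalities. `noise_scale=0` returns plain reconstructions.
  Output is on the normalized scale; `inverse_transform_counts` optionally
  maps back to count-like values (expm1, clip, round). Fidelity is the
  Pearson correlation of per-gene mean expression between real and simulated
  cells over the union of each side's top-100 highly variable genes.
* **Batch correction** — `correct_batches` trains on a labeled reference
  batch only and pushes each query batch through the frozen model. Each batch is
  first feature-standardized on its own statistics (per-dataset scaling, as
  in reference-mapping pipelines), which cancels additive per-feature batch
  offsets up to estimation error; the shared frozen embedding then aligns
  cell types across batches.

## Evaluation metrics

ARI, NMI and AMI are implemented from the contingency table. ARI uses the
pair-count form under the permutation model (the printed pair-count formula
with the squared denominator restored — the description "near one when
aligned, near zero under random assignment" pins the standard definition).
NMI normalizes mutual information by `max{H(P), H(T)}`; AMI subtracts the
exact hypergeometric expected mutual information with the same max
normalization. Natural logarithms throughout (the ratios are base-invariant).
Degenerate conventions: two identical single-cluster partitions score 1, a
single-cluster against anything else scores 0. The test suite checks all
three against brute-force oracles (explicit pair loops, probability-dict
entropies, integer-combinatorics expectations) exhaustively over every pair
of partitions of up to six items, and against scikit-learn on random cases.

## Interpretability

Feature attribution uses a seeded permutation-sampling Shapley estimator:
for each explained cell, random feature orders are walked from a background
cell toward the cell's own values, crediting each feature its marginal
change in the model output. The estimator satisfies local accuracy by
construction (per-cell attributions telescope to `f(x) − mean f(background)`)
and is exact in expectation. Explained outputs: the predicted probability of
the cell's own type (`classification`) or the 64 embedding coordinates
(`dimension_reduction`, aggregated per feature as the sum of absolute
contributions — the aggregation is a declared choice). Both modalities are
attributed jointly over the concatenated feature vector and split back into
per-modality tables; scores are mean |Shapley value| per cell type, min-max
normalized to [0,1] per table for reporting. Defaults: background 100 cells,
evaluation budget `2·features + 2048` per cell, 25 explained cells per type.
Exact Shapley is exponential in features; the sampling budget trades
variance for time and is the reason the attribution benchmark uses a
moderate feature count (150 genes + 100 peaks).

ATAC peaks (`"chrom:start-end"`, 0-based half-open) map to a gene when the
peak overlaps the gene interval extended 2000 bp upstream of the
transcription start, strand-aware; annotation is read from BED6 or GTF.

## Benchmark problem sizes

The shipped benchmarks run on one CPU core in a few minutes total: the main
recovery and rare-type runs use 1000 cells × (2000 genes + 2000 peaks) with
100 training epochs; batch correction trains on one ~500-cell batch; the
attribution benchmark uses 600 cells × (150 genes + 100 peaks) with 60
epochs. These sizes are the package's chosen study conditions for desk-scale
reproducibility, scaled down from the tens of thousands of cells in typical
public datasets.

## Known limitations

* M = 2 modalities exactly; no mosaic/unpaired integration.
* The classifier is supervised — no label-free operation.
* Simulation output lives on the normalized scale by default; the inverse
  transform is approximate (log-scale decoding error becomes multiplicative).
* The per-batch standardization in `correct_batches` targets additive batch
  effects; strongly nonlinear batch distortions would need the reference
  model to see them during training.
* Attribution cost grows linearly with feature count per explained cell;
  attributing all 4000+4000 default features is possible but slow.
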