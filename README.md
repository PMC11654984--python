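# scmomtf

Multitask analysis of **paired single-cell multi-omics data** — RNA + ATAC
(SNARE-seq, SHARE-seq, 10x Multiome) or RNA + ADT (CITE-seq) measured in the
same cells. One adversarially trained network serves three tasks at once:

* **dimension reduction** — a 64-dimensional joint cell embedding `z`,
* **cell-type classification** — a label-smoothed softmax head on `z`,
* **data simulation** — the encoder–decoder pair as a generator,

plus **batch correction** by reference-batch training and **Shapley-value
feature attribution** for surfacing candidate marker genes (with ATAC
peak-to-gene mapping). A built-in synthetic paired-omics generator plants
known cell types, markers, rare populations and batch effects, so the whole
pipeline is testable without downloading any dataset.

## The model in brief

For paired matrices `X⁽¹⁾ ∈ R^{n×v₁}`, `X⁽²⁾ ∈ R^{n×v₂}`:

    h⁽ᵐ⁾ᵢ = E⁽ᵐ⁾(x⁽ᵐ⁾ᵢ)                 modality encoders (dim 150)
    zᵢ    = E_cell([h⁽¹⁾ᵢ, h⁽²⁾ᵢ])       cell embedding (dim 64)
    x̂⁽ᵐ⁾ᵢ = D⁽ᵐ⁾(zᵢ)                    decoders / generator
    yᵢ    = softmax(W zᵢ + b)            classifier

trained with `L_total = L_res + γ·L_cls + L_gen + L_dis`: mean-squared
reconstruction, cross entropy against label-smoothed targets
`(1−α)·y + α/C`, and a least-squares GAN pair in which per-modality
discriminators push reconstructions toward the data distribution. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import scmomtf as sm

# synthetic paired RNA+ATAC data: 500 cells, 4 types with planted markers
cfg = sm.SimulationConfig(n_cells=500, n_types=4, n_rna=300, n_atac=200,
                          n_markers_per_type=30, marker_fold_change=4.0, seed=0)
ds, gt = sm.generate_paired_dataset(cfg)
ds = sm.normalize_counts(ds)

train_idx, test_idx = sm.split_folds(ds, k=5, seed=0)[0]
state, log = sm.train(ds.subset_cells(train_idx),
                      tcfg=sm.TrainConfig(epochs=50, batch_size=128, seed=0))

test = ds.subset_cells(test_idx)
pred, probs = sm.predict_cell_types(state, test)
print("held-out accuracy:",
      sm.classification_accuracy(np.asarray(pred), np.asarray(test.cell_labels)))

emb = sm.embed_cells(state, ds)
part = sm.cluster_embedding(emb.z, k=4, n_init=30, seed=0)
truth = sm.Partition(np.unique(ds.cell_labels, return_inverse=True)[1])
print("ARI:", sm.adjusted_rand_index(part, truth))
```

prints

```
held-out accuracy: 1.0
ARI: 1.0
```

— every held-out cell is assigned its planted type, and k-means on the
64-dim embedding reproduces the planted partition exactly (ARI = 1 means
perfect agreement up to label renaming). Continuing with simulation and
attribution:

```python
sim = sm.simulate_cells(state, ds, sm.SimulationRequest("type0", n_cells=200, seed=0))
real = ds.modality_1.subset_cells(np.where(np.asarray(ds.cell_labels) == "type0")[0])
print(sm.simulation_fidelity(real, sim.modality_1, n_top=100)["pearson_mean_expression"])
# 0.981  <- top-100-HVG mean-expression Pearson between real and simulated type0 cells

t_rna, t_atac = sm.attribute_features(state, ds, task="classification",
                                      background_size=40, max_cells_per_type=10, seed=0)
print(sm.rank_markers(t_rna, "type0", top_k=5))
# gene00016    1.000
# gene00012    0.890
# gene00001    0.817
# gene00023    0.792
# gene00019    0.776
```

The top-attributed genes are planted `type0` markers (`gene00000`–`gene00029`
by construction), with scores min-max normalized to [0, 1].

## Command line

```sh
scmomtf simulate-data --out data/               # synthetic dataset + ground truth
scmomtf train --m1 data/modality1.csv --m2 data/modality2.csv \
              --labels data/labels.csv --out model.npz
scmomtf embed    --checkpoint model.npz --m1 ... --m2 ... --out z.csv
scmomtf classify --checkpoint model.npz --m1 ... --m2 ... --out labels_pred.csv
scmomtf simulate --checkpoint model.npz --celltype type0 --n-cells 200 ...
scmomtf correct  --reference-m1 ... --query-m1 ... --out corrected/
scmomtf evaluate --embedding z.csv --labels data/labels.csv
scmomtf explain  --checkpoint model.npz --task classification --celltype type0 ...
```

Data formats: MatrixMarket + features/barcodes sidecars, delimited text
(cells × features) and `.h5ad`; labels as `cell_id,cell_type[,batch]` CSV.

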