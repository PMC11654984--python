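"""User-facing tasks on a trained model: dimension reduction, cell-type
prediction, cell simulation and reference-based batch correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import LabelCodec, OmicsMatrix, PairedDataset, ValidationError
from .network import CellEmbedding, ModelConfig, ModelState, classify, decode, encode
from .training import TrainConfig, train


@dataclass
class SimulationRequest:
    """What to simulate: a named cell type (or "ALL") and how many cells.

    ``noise_scale`` perturbs the latent embedding with seeded Gaussian noise
    scaled by the per-dimension latent standard deviation of the target type;
    0 reproduces plain reconstructions of resampled source cells.
    """

    target_cell_type: str = "ALL"
    n_cells: int = 200
    noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be at least 1")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be nonnegative")


def _check_features(state: ModelState, ds: PairedDataset) -> None:
    if state.feature_ids is None:
        return
    for stored, mat in zip(state.feature_ids, ds.modalities):
        if list(stored) != list(mat.feature_ids):
            missing = sorted(set(stored) - set(mat.feature_ids))[:5]
            extra = sorted(set(mat.feature_ids) - set(stored))[:5]
            raise ValidationError(
                f"feature space mismatch for {mat.modality_tag}: "
                f"missing e.g. {missing}, unexpected e.g. {extra}"
            )


def embed_cells(state: ModelState, ds: PairedDataset) -> CellEmbedding:
    """Deterministic joint embedding of every cell in the dataset."""
    _check_features(state, ds)
    return encode(state, ds.modality_1.values, ds.modality_2.values)


def predict_cell_types(
    state: ModelState, ds: PairedDataset
) -> tuple[list[str], np.ndarray]:
    """argmax class per cell plus the full probability matrix."""
    emb = embed_cells(state, ds)
    probs = classify(state, emb.z)
    codes = probs.argmax(axis=1)
    if state.classes is None:
        raise ValidationError("model carries no class vocabulary; train first")
    codec = LabelCodec(state.classes)
    return codec.decode(codes), probs


def simulate_cells(
    state: ModelState, ds: PairedDataset, req: SimulationRequest
) -> PairedDataset:
    """Simulate cells of a target type through the trained generator.

    Source cells of the target type are resampled with replacement, encoded,
    perturbed in latent space and decoded back to both modalities.
    ``target_cell_type="ALL"`` draws sources proportionally from every type.
    """
    _check_features(state, ds)
    if ds.cell_labels is None:
        raise ValidationError("simulation needs labeled source data")
    labels = np.asarray(ds.cell_labels)
    known = sorted(set(labels))
    if req.target_cell_type == "ALL":
        pool = np.arange(ds.n_cells)
    else:
        if req.target_cell_type not in known:
            raise ValidationError(
                f"unknown cell type {req.target_cell_type!r}; known types: {known}"
            )
        pool = np.where(labels == req.target_cell_type)[0]
    rng = np.random.default_rng(req.seed)
    src = rng.choice(pool, size=req.n_cells, replace=True)

    _check_features(state, ds)
    x1 = np.asarray(ds.modality_1.values, float)
    x2 = np.asarray(ds.modality_2.values, float)
    z = encode(state, x1[src], x2[src]).z
    if req.noise_scale > 0:
        sigma = encode(state, x1[pool], x2[pool]).z.std(axis=0, keepdims=True)
        z = z + req.noise_scale * sigma * rng.standard_normal(z.shape)
    xh1, xh2 = decode(state, z)
    m1 = OmicsMatrix(xh1, list(ds.modality_1.feature_ids), ds.modality_1.modality_tag)
    m2 = OmicsMatrix(xh2, list(ds.modality_2.feature_ids), ds.modality_2.modality_tag)
    return PairedDataset(
        m1,
        m2,
        [f"sim{i:05d}" for i in range(req.n_cells)],
        cell_labels=[labels[i] for i in src],
        normalized=True,
    )


def inverse_transform_counts(mat: OmicsMatrix) -> OmicsMatrix:
    """Optional mapping of simulated log-scale values back to count-like values."""
    vals = np.rint(np.clip(np.expm1(mat.values), 0.0, None))
    return OmicsMatrix(vals, list(mat.feature_ids), mat.modality_tag)


@dataclass
class BatchCorrectionResult:
    state: ModelState
    embeddings: list[CellEmbedding]
    labels: list[list[str]]
    probabilities: list[np.ndarray]


def _standardize_per_batch(ds: PairedDataset) -> PairedDataset:
    """z-score every feature within the dataset (per-batch scaling).

    Computed on each batch's own statistics, this removes additive
    per-(batch, feature) offsets up to estimation error, the first-order
    model of a batch effect on the log scale.  Near-constant features fall
    back to unit scale.
    """
    mats = []
    for mat in ds.modalities:
        vals = np.asarray(mat.values, float)
        mu = vals.mean(axis=0, keepdims=True)
        sd = vals.std(axis=0, keepdims=True)
        sd[sd < 1e-8] = 1.0
        mats.append(OmicsMatrix((vals - mu) / sd, list(mat.feature_ids), mat.modality_tag))
    return PairedDataset(
        mats[0], mats[1], list(ds.cell_ids), ds.cell_labels, ds.batch_labels,
        normalized=True,
    )


def correct_batches(
    reference: PairedDataset,
    queries: list[PairedDataset],
    mcfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
    standardize: bool = True,
) -> BatchCorrectionResult:
    """Train on the labeled reference batch; embed and classify each query.

    The frozen reference-trained model maps every batch into one embedding
    space, which is the batch-correction strategy: cells of the same type end
    up nearby regardless of batch, and query labels come from the classifier.
    By default every batch is feature-standardized on its own statistics
    first (the per-dataset scaling step common in reference-mapping
    pipelines), which cancels additive per-feature batch offsets.
    """
    if reference.cell_labels is None:
        raise ValidationError("reference batch must be labeled")
    for q in queries:
        for r_mat, q_mat in zip(reference.modalities, q.modalities):
            if list(r_mat.feature_ids) != list(q_mat.feature_ids):
                raise ValidationError("query feature space differs from reference")
    if standardize:
        reference = _standardize_per_batch(reference)
        queries = [_standardize_per_batch(q) for q in queries]
    state, _ = train(reference, mcfg, tcfg)
    embeddings, labels, probabilities = [], [], []
    for q in queries:
        emb = embed_cells(state, q)
        pred, probs = predict_cell_types(state, q)
        embeddings.append(emb)
        labels.append(pred)
        probabilities.append(probs)
    return BatchCorrectionResult(state, embeddings, labels, probabilities)
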