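"""Synthetic paired multi-omics generator with known ground truth.

Emulates matched RNA + ATAC (or RNA + ADT) measurements with shared
cell-type structure: per-type marker features, optional rare populations
and additive batch effects.  RNA and ADT counts follow a negative-binomial
(gamma-Poisson) model with per-cell library-size variation; ATAC is
binarized accessibility (Bernoulli) with elevated open probability at
marker peaks.  Each marker peak is placed inside the genomic interval of
its paired marker gene so peak-to-gene attribution has recoverable truth.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy.random.Generator``, so repeated calls are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import OmicsMatrix, PairedDataset, ValidationError

#: span of each synthetic gene body and spacing between gene starts (bp)
_GENE_LEN = 2_000
_GENE_SPACING = 10_000


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic paired dataset.

    Defaults describe a desk-scale experiment: 1000 cells, five equally
    abundant types, 2000 genes + 2000 peaks (or 50 proteins for RNA+ADT).
    Each type carries markers in 10% of the genes (the convention of
    splatter-style simulators, where distinct cell types differ in a
    sizeable fraction of the transcriptome) with four-fold elevation.
    """

    n_cells: int = 1000
    n_types: int = 5
    type_proportions: np.ndarray | None = None  # uniform when None
    n_rna: int = 2000
    n_atac: int = 2000
    n_adt: int = 50
    n_markers_per_type: int = 200
    marker_fold_change: float = 4.0
    rna_dispersion: float = 2.0  # NB shape theta; var = mu + mu^2/theta
    atac_open_prob_base: float = 0.05
    atac_open_prob_marker: float = 0.40
    adt_mean: float = 20.0
    adt_dispersion: float = 10.0
    modality_pair: tuple[str, str] = ("RNA", "ATAC")
    batch_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type_proportions is None:
            self.type_proportions = np.full(self.n_types, 1.0 / self.n_types)
        self.type_proportions = np.asarray(self.type_proportions, dtype=float)
        if len(self.type_proportions) != self.n_types:
            raise ValidationError("type_proportions length must equal n_types")
        if abs(self.type_proportions.sum() - 1.0) > 1e-9:
            raise ValidationError("type_proportions must sum to 1")
        for name in ("n_cells", "n_types", "n_rna", "n_atac", "n_adt", "n_markers_per_type"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for p in (self.atac_open_prob_base, self.atac_open_prob_marker):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("open probabilities must lie in [0, 1]")
        if self.marker_fold_change <= 0:
            raise ValidationError("marker_fold_change must be > 0")
        if self.batch_shift_sd < 0:
            raise ValidationError("batch_shift_sd must be nonnegative")
        if self.modality_pair not in (("RNA", "ATAC"), ("RNA", "ADT")):
            raise ValidationError("modality_pair must be (RNA, ATAC) or (RNA, ADT)")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    cell_type_of_cell: list[str]
    marker_features_of_type: dict[str, dict[str, list[str]]]  # type -> modality -> ids
    batch_of_cell: list[str] | None = None
    gene_annotation: pd.DataFrame | None = field(default=None, repr=False)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mean`` and NB shape ``theta``."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam).astype(np.float64)


def _draw_types(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """i.i.d. type assignment; re-drawn until every declared type has >= 2 cells."""
    for _ in range(1000):
        t = rng.choice(cfg.n_types, size=cfg.n_cells, p=cfg.type_proportions)
        if np.min(np.bincount(t, minlength=cfg.n_types)) >= 2:
            return t
    raise ValidationError(
        "could not draw >= 2 cells for every type; increase n_cells or proportions"
    )


def generate_paired_dataset(cfg: SimulationConfig) -> tuple[PairedDataset, GroundTruth]:
    """Generate one paired dataset plus its ground truth.

    RNA baseline means are log-normal across genes; each type's marker genes
    are elevated ``marker_fold_change``-fold.  Marker peak *j* of a type is
    geometrically paired with marker gene *j* of the same type (the peak
    interval lies inside the gene interval).
    """
    if cfg.n_markers_per_type * cfg.n_types > min(
        cfg.n_rna, cfg.n_atac if cfg.modality_pair[1] == "ATAC" else cfg.n_adt
    ):
        raise ValidationError("n_markers_per_type x n_types exceeds a modality's feature count")
    rng = np.random.default_rng(cfg.seed)
    types = _draw_types(rng, cfg)
    type_names = [f"type{k}" for k in range(cfg.n_types)]

    # gene annotation: sequential intervals on two synthetic chromosomes
    gene_ids = [f"gene{i:05d}" for i in range(cfg.n_rna)]
    chroms = np.where(np.arange(cfg.n_rna) % 2 == 0, "chr1", "chr2")
    starts = (np.arange(cfg.n_rna) // 2) * _GENE_SPACING
    gene_annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chroms,
            "start": starts,
            "end": starts + _GENE_LEN,
            "strand": np.where(np.arange(cfg.n_rna) % 3 == 0, "-", "+"),
        }
    )

    # disjoint marker blocks, one per type, shared index across modalities
    mk = cfg.n_markers_per_type
    marker_gene_idx = {k: np.arange(k * mk, (k + 1) * mk) for k in range(cfg.n_types)}

    base_mean = rng.lognormal(mean=0.0, sigma=0.6, size=cfg.n_rna)
    lib = rng.lognormal(mean=0.0, sigma=0.3, size=cfg.n_cells)
    type_means = np.tile(base_mean, (cfg.n_types, 1))
    for k in range(cfg.n_types):
        type_means[k, marker_gene_idx[k]] *= cfg.marker_fold_change
    rna = _nb_counts(rng, type_means[types] * lib[:, None], cfg.rna_dispersion)
    m1 = OmicsMatrix(rna, gene_ids, "RNA")

    markers: dict[str, dict[str, list[str]]] = {}
    if cfg.modality_pair[1] == "ATAC":
        # peak j paired with gene j for j < n_rna; extras placed intergenic
        peak_ids = []
        for j in range(cfg.n_atac):
            if j < cfg.n_rna:
                g = gene_annotation.iloc[j]
                s = int(g.start) + 500
                peak_ids.append(f"{g.chrom}:{s}-{s + 500}")
            else:
                s = (j - cfg.n_rna) * _GENE_SPACING + _GENE_LEN + 3_000
                peak_ids.append(f"chr3:{s}-{s + 500}")
        probs = np.full((cfg.n_types, cfg.n_atac), cfg.atac_open_prob_base)
        for k in range(cfg.n_types):
            probs[k, marker_gene_idx[k]] = cfg.atac_open_prob_marker
        atac = (rng.random((cfg.n_cells, cfg.n_atac)) < probs[types]).astype(np.float64)
        m2 = OmicsMatrix(atac, peak_ids, "ATAC")
        second_ids = peak_ids
    else:
        second_ids = [f"protein{i:03d}" for i in range(cfg.n_adt)]
        adt_base = np.full(cfg.n_adt, cfg.adt_mean) * rng.lognormal(0.0, 0.3, cfg.n_adt)
        adt_means = np.tile(adt_base, (cfg.n_types, 1))
        for k in range(cfg.n_types):
            adt_means[k, marker_gene_idx[k] % cfg.n_adt] *= cfg.marker_fold_change
        adt = _nb_counts(rng, adt_means[types], cfg.adt_dispersion)
        m2 = OmicsMatrix(adt, second_ids, "ADT")

    for k, name in enumerate(type_names):
        idx = marker_gene_idx[k]
        markers[name] = {
            "RNA": [gene_ids[i] for i in idx],
            cfg.modality_pair[1]: [
                second_ids[i % len(second_ids)] for i in idx
            ],
        }

    cell_ids = [f"cell{i:05d}" for i in range(cfg.n_cells)]
    labels = [type_names[t] for t in types]
    ds = PairedDataset(m1, m2, cell_ids, cell_labels=labels)
    gt = GroundTruth(labels, markers, batch_of_cell=None, gene_annotation=gene_annotation)
    return ds, gt


def add_batch_effect(
    ds: PairedDataset,
    gt: GroundTruth,
    n_batches: int = 2,
    shift_sd: float = 0.8,
    seed: int = 0,
) -> tuple[PairedDataset, GroundTruth]:
    """Assign cells to batches and add a per-(batch, feature) shift.

    The shift is drawn once per batch and feature, ``N(0, shift_sd)``, and
    added on the normalized (log) scale — apply after ``normalize_counts``.
    ``shift_sd = 0`` leaves the data untouched (batch labels still assigned).
    """
    if n_batches < 2:
        raise ValidationError("n_batches must be at least 2")
    if shift_sd < 0:
        raise ValidationError("shift_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    batch_idx = rng.integers(0, n_batches, size=ds.n_cells)
    batch_names = [f"batch{b}" for b in batch_idx]

    new_mats = []
    for mat in ds.modalities:
        vals = np.asarray(mat.values, dtype=np.float64)
        shifts = rng.normal(0.0, shift_sd, size=(n_batches, mat.n_features)) if shift_sd > 0 else None
        out = vals if shifts is None else vals + shifts[batch_idx]
        new_mats.append(OmicsMatrix(out, list(mat.feature_ids), mat.modality_tag))
    shifted = PairedDataset(
        new_mats[0],
        new_mats[1],
        list(ds.cell_ids),
        ds.cell_labels,
        batch_names,
        normalized=ds.normalized or shift_sd > 0,
    )
    gt_out = GroundTruth(
        list(gt.cell_type_of_cell),
        gt.marker_features_of_type,
        batch_of_cell=batch_names,
        gene_annotation=gt.gene_annotation,
    )
    return shifted, gt_out


def write_ground_truth(gt: GroundTruth, cell_ids: list[str], out_dir: str | Path) -> None:
    """Write ground truth as labels CSV + JSON marker manifest (+ gene BED)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"cell_id": cell_ids, "cell_type": gt.cell_type_of_cell})
    if gt.batch_of_cell is not None:
        df["batch"] = gt.batch_of_cell
    df.to_csv(out / "ground_truth_labels.csv", index=False)
    (out / "markers.json").write_text(json.dumps(gt.marker_features_of_type, indent=1))
    if gt.gene_annotation is not None:
        bed = gt.gene_annotation[["chrom", "start", "end", "gene_id", "strand"]].copy()
        bed.insert(4, "score", 0)
        bed.to_csv(out / "genes.bed", sep="\t", header=False, index=False)
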