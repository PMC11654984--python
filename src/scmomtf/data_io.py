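"""Loading, validation, normalization and feature selection for paired single-cell multi-omics data.

The canonical in-memory container is :class:`PairedDataset`: two row-aligned
cell-by-feature matrices (RNA plus either ATAC or ADT) with optional cell-type
and batch labels.  Supported on-disk formats are MatrixMarket with
features/barcodes sidecars (CellRanger layout), delimited text (cells x
features) and the h5ad annotated-matrix container.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

MODALITY_TAGS = ("RNA", "ATAC", "ADT")


class ValidationError(ValueError):
    """Raised when an input violates a dataset invariant."""


@dataclass
class OmicsMatrix:
    """A cell-by-feature matrix for one modality.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_features)`` array of counts or normalized values.
    feature_ids
        Unique feature identifiers: gene symbols, peaks as
        ``"chrom:start-end"`` (0-based half-open), or protein names.
    modality_tag
        One of ``"RNA"``, ``"ATAC"``, ``"ADT"``.
    """

    values: np.ndarray
    feature_ids: list[str]
    modality_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if sp.issparse(self.values):  # pragma: no cover - guarded by asarray
            self.values = self.values.toarray()
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D cell-by-feature matrix")
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("feature_ids must be unique")
        if self.modality_tag not in MODALITY_TAGS:
            raise ValidationError(
                f"modality_tag must be one of {MODALITY_TAGS}, got {self.modality_tag!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "OmicsMatrix":
        return OmicsMatrix(self.values[idx], list(self.feature_ids), self.modality_tag)

    def subset_features(self, idx: np.ndarray) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values[:, idx],
            [self.feature_ids[i] for i in np.asarray(idx)],
            self.modality_tag,
        )


@dataclass
class PairedDataset:
    """Matched two-modality single-cell dataset (M = 2).

    Both matrices are row-aligned: row *i* of each modality is the same cell.
    """

    modality_1: OmicsMatrix
    modality_2: OmicsMatrix
    cell_ids: list[str]
    cell_labels: list[str] | None = None
    batch_labels: list[str] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        n1 = self.modality_1.values.shape[0]
        n2 = self.modality_2.values.shape[0]
        if n1 != n2:
            raise ValidationError(f"modalities disagree on cell count: {n1} vs {n2}")
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.cell_ids) != n1:
            raise ValidationError("cell_ids length does not match matrices")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if self.cell_labels is not None and len(self.cell_labels) != n1:
            raise ValidationError("cell_labels must have one entry per cell")
        if self.batch_labels is not None and len(self.batch_labels) != n1:
            raise ValidationError("batch_labels must have one entry per cell")
        if not self.normalized:
            if (self.modality_1.values < 0).any() or (self.modality_2.values < 0).any():
                raise ValidationError("raw counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def modalities(self) -> tuple[OmicsMatrix, OmicsMatrix]:
        return (self.modality_1, self.modality_2)

    def subset_cells(self, idx) -> "PairedDataset":
        idx = np.asarray(idx)
        return PairedDataset(
            self.modality_1.subset_cells(idx),
            self.modality_2.subset_cells(idx),
            [self.cell_ids[i] for i in idx],
            None if self.cell_labels is None else [self.cell_labels[i] for i in idx],
            None if self.batch_labels is None else [self.batch_labels[i] for i in idx],
            normalized=self.normalized,
        )


@dataclass
class LabelCodec:
    """Bijective mapping between cell-type names and integer codes in [0, C)."""

    classes: list[str]
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.classes = [str(c) for c in self.classes]
        if len(set(self.classes)) != len(self.classes):
            raise ValidationError("classes must be distinct")
        self._index = {c: i for i, c in enumerate(self.classes)}

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "LabelCodec":
        return cls(sorted(set(str(v) for v in labels)))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def encode(self, labels: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[str(v)] for v in labels], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - defensive
            raise ValidationError(f"unknown class {e.args[0]!r}; known: {self.classes}")

    def decode(self, codes: Sequence[int]) -> list[str]:
        return [self.classes[int(c)] for c in codes]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path, fmt: str | None) -> tuple[np.ndarray, list[str], list[str]]:
    """Return (values cells x features, cell_ids, feature_ids)."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if path.is_dir() or suffix == ".mtx":
            fmt = "mtx"
        elif suffix == ".h5ad":
            fmt = "h5ad"
        elif suffix in (".csv", ".tsv", ".txt"):
            fmt = "csv" if suffix == ".csv" else "tsv"
        else:
            raise ValidationError(f"cannot infer format of {path}")
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")
    if fmt == "mtx":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        base = mtx_path.parent
        try:
            m = scipy.io.mmread(mtx_path)
        except OSError as e:
            raise IOError(f"unreadable MatrixMarket file {mtx_path}: {e}") from e
        features = pd.read_csv(base / "features.tsv", sep="\t", header=None)
        barcodes = pd.read_csv(base / "barcodes.tsv", sep="\t", header=None)
        # CellRanger convention: rows are features, columns are cells
        values = np.asarray(sp.csr_matrix(m).T.todense())
        return values, barcodes[0].astype(str).tolist(), features[0].astype(str).tolist()
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        return df.to_numpy(dtype=float), df.index.astype(str).tolist(), df.columns.astype(str).tolist()
    if fmt == "h5ad":
        adata = ad.read_h5ad(path)
        X = adata.X
        values = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
        return values, adata.obs_names.astype(str).tolist(), adata.var_names.astype(str).tolist()
    raise ValidationError(f"unsupported format tag {fmt!r}")


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a two/three-column label table (cell_id, cell_type[, batch])."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("labels file needs at least cell_id and cell_type columns")
    df = df.rename(columns={df.columns[0]: "cell_id", df.columns[1]: "cell_type"})
    if df.shape[1] >= 3:
        df = df.rename(columns={df.columns[2]: "batch"})
    df["cell_id"] = df["cell_id"].astype(str)
    return df.set_index("cell_id")


def read_paired_dataset(
    path_m1: str | Path,
    path_m2: str | Path,
    labels_path: str | Path | None = None,
    fmt: str | None = None,
    modality_tags: tuple[str, str] = ("RNA", "ATAC"),
) -> PairedDataset:
    """Load two modality matrices and align them on the shared cell axis.

    Cells present in only one modality are dropped with a logged warning;
    modality-1 row order is preserved for the retained cells.
    """
    v1, cells1, feat1 = _read_matrix(path_m1, fmt)
    v2, cells2, feat2 = _read_matrix(path_m2, fmt)
    if len(set(cells1)) != len(cells1) or len(set(cells2)) != len(cells2):
        raise ValidationError("duplicate cell ids within a modality")
    keep = set(cells1) & set(cells2)
    if not keep:
        raise ValidationError("no overlapping cell ids between the two modalities")
    dropped = (len(cells1) - len(keep)) + (len(cells2) - len(keep))
    if dropped:
        logger.warning("dropping %d cells present in only one modality", dropped)
    order = [c for c in cells1 if c in keep]
    idx1 = [cells1.index(c) for c in order] if order != cells1 else None
    pos2 = {c: i for i, c in enumerate(cells2)}
    idx2 = [pos2[c] for c in order]
    m1 = OmicsMatrix(v1 if idx1 is None else v1[np.asarray(idx1)], feat1, modality_tags[0])
    m2 = OmicsMatrix(v2[np.asarray(idx2)], feat2, modality_tags[1])

    cell_labels = batch_labels = None
    if labels_path is not None:
        tab = read_labels(labels_path)
        missing = [c for c in order if c not in tab.index]
        if missing:
            raise ValidationError(
                f"labels file missing {len(missing)} barcodes (e.g. {missing[:3]})"
            )
        cell_labels = tab.loc[order, "cell_type"].astype(str).tolist()
        if "batch" in tab.columns:
            batch_labels = tab.loc[order, "batch"].astype(str).tolist()
    return PairedDataset(m1, m2, order, cell_labels, batch_labels)


def write_paired_dataset(ds: PairedDataset, out_dir: str | Path, fmt: str = "csv") -> None:
    """Write both modalities (plus labels, if any) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, mat in (("modality1", ds.modality_1), ("modality2", ds.modality_2)):
        if fmt in ("csv", "tsv"):
            sep = "," if fmt == "csv" else "\t"
            pd.DataFrame(mat.values, index=ds.cell_ids, columns=mat.feature_ids).to_csv(
                out / f"{name}.{fmt}", sep=sep
            )
        elif fmt == "mtx":
            d = out / name
            d.mkdir(exist_ok=True)
            scipy.io.mmwrite(d / "matrix.mtx", sp.csr_matrix(mat.values.T))
            pd.Series(mat.feature_ids).to_csv(d / "features.tsv", sep="\t", header=False, index=False)
            pd.Series(ds.cell_ids).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)
        elif fmt == "h5ad":
            adata = ad.AnnData(
                X=np.asarray(mat.values),
                obs=pd.DataFrame(index=ds.cell_ids),
                var=pd.DataFrame(index=mat.feature_ids),
            )
            adata.write_h5ad(out / f"{name}.h5ad")
        else:
            raise ValidationError(f"unsupported format {fmt!r}")
    if ds.cell_labels is not None:
        df = pd.DataFrame({"cell_id": ds.cell_ids, "cell_type": ds.cell_labels})
        if ds.batch_labels is not None:
            df["batch"] = ds.batch_labels
        df.to_csv(out / "labels.csv", index=False)


# ---------------------------------------------------------------------------
# normalization / feature selection / folds
# ---------------------------------------------------------------------------

def _clr(values: np.ndarray) -> np.ndarray:
    # centered log-ratio per cell on log1p counts; finite for zero entries
    y = np.log1p(values)
    return y - y.mean(axis=1, keepdims=True)


def normalize_counts(ds: PairedDataset) -> PairedDataset:
    """Depth-normalize + log1p RNA/ATAC; centered-log-ratio transform ADT.

    RNA and ATAC counts are scaled to the median per-cell total of their
    modality and log1p-transformed.  Cells with zero total in either
    depth-normalized modality are removed with a warning.  Idempotent: a
    dataset already flagged ``normalized`` is returned unchanged.
    """
    if ds.normalized:
        return ds
    keep = np.ones(ds.n_cells, dtype=bool)
    for mat in ds.modalities:
        if mat.modality_tag in ("RNA", "ATAC"):
            keep &= mat.values.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(f"removing {int((~keep).sum())} all-zero cells before normalization")
        ds = ds.subset_cells(np.where(keep)[0])

    new = []
    for mat in ds.modalities:
        vals = np.asarray(mat.values, dtype=np.float64)
        if mat.modality_tag == "ADT":
            out = _clr(vals)
        else:
            totals = vals.sum(axis=1, keepdims=True)
            target = float(np.median(totals))
            out = np.log1p(vals / totals * target)
        new.append(OmicsMatrix(out, list(mat.feature_ids), mat.modality_tag))
    return PairedDataset(
        new[0], new[1], list(ds.cell_ids), ds.cell_labels, ds.batch_labels, normalized=True
    )


def _hvg_indices(values: np.ndarray, feature_ids: list[str], n_top: int) -> np.ndarray:
    """Dispersion-based (seurat flavor) highly-variable feature indices, original order."""
    import scanpy as sc

    adata = ad.AnnData(
        X=np.asarray(values, dtype=np.float64),
        var=pd.DataFrame(index=feature_ids),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(
            adata, flavor="seurat",
            min_mean=-np.inf, max_mean=np.inf, min_disp=-np.inf,
        )
    disp = np.nan_to_num(adata.var["dispersions_norm"].to_numpy(), nan=-np.inf)
    # exactly n_top features; ties broken by original feature order
    order = np.lexsort((np.arange(disp.size), -disp))
    return np.sort(order[:n_top])


def select_highly_variable(
    ds: PairedDataset, n_rna: int = 4000, n_atac: int = 4000
) -> PairedDataset:
    """Keep the top-N highly variable features of RNA and ATAC; ADT is kept whole.

    Ranking is by normalized dispersion binned by mean (the seurat-style
    recipe) on the normalized, log-transformed data.  Requesting more features
    than exist keeps all of them with a warning.
    """
    if not ds.normalized:
        raise ValidationError("select_highly_variable expects normalized data")
    targets = {"RNA": n_rna, "ATAC": n_atac}
    new = []
    for mat in ds.modalities:
        n_top = targets.get(mat.modality_tag)
        if n_top is None:  # ADT: preserve all features
            new.append(mat)
            continue
        if n_top >= mat.n_features:
            if n_top > mat.n_features:
                warnings.warn(
                    f"requested {n_top} HVFs but {mat.modality_tag} has only "
                    f"{mat.n_features}; keeping all"
                )
            new.append(mat)
            continue
        idx = _hvg_indices(mat.values, mat.feature_ids, n_top)
        new.append(mat.subset_features(idx))
    return PairedDataset(
        new[0], new[1], list(ds.cell_ids), ds.cell_labels, ds.batch_labels, normalized=True
    )


def split_folds(
    ds: PairedDataset, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold split of cell indices.

    Classes with fewer than ``k`` cells are held out of the rotation and
    placed entirely in every training fold (with a warning), so rare types
    never leave an empty stratum.
    """
    if k < 2:
        raise ValidationError("k must be at least 2")
    if ds.cell_labels is None:
        raise ValidationError("split_folds requires cell labels")
    labels = np.asarray(ds.cell_labels)
    counts = pd.Series(labels).value_counts()
    rare_classes = set(counts[counts < k].index)
    if rare_classes:
        warnings.warn(
            f"classes with fewer than {k} cells kept in training folds only: "
            f"{sorted(rare_classes)}"
        )
    idx_all = np.arange(ds.n_cells)
    rare_mask = np.isin(labels, sorted(rare_classes))
    main_idx = idx_all[~rare_mask]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(main_idx, labels[main_idx]):
        train = np.sort(np.concatenate([main_idx[tr], idx_all[rare_mask]]))
        test = np.sort(main_idx[te])
        folds.append((train, test))
    return folds
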