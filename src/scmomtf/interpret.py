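"""Shapley-value feature attribution and ATAC peak-to-gene mapping.

Attribution uses a seeded permutation-sampling Shapley estimator: for each
explained cell a random feature order is walked from a background cell's
values toward the cell's own values, and each feature is credited its
marginal change in the model output.  Averaged over permutations and
backgrounds this converges to the Shapley value and satisfies local accuracy
(the per-cell attributions sum to ``f(x) - mean f(background)``) by
construction.

Two model outputs can be explained:

* ``classification`` — the predicted probability of the cell's own type;
* ``dimension_reduction`` — the cell-embedding coordinates, aggregated per
  feature as the sum of absolute contributions across embedding dimensions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import LabelCodec, PairedDataset, ValidationError
from .network import ModelState, classify, encode

TASK_TAGS = ("classification", "dimension_reduction")


@dataclass
class AttributionTable:
    """Per-feature, per-cell-type importance (mean |Shapley value|)."""

    scores: pd.DataFrame  # features x cell types
    modality_tag: str
    task_tag: str

    def __post_init__(self) -> None:
        if self.task_tag not in TASK_TAGS:
            raise ValidationError(f"task_tag must be one of {TASK_TAGS}")

    @property
    def normalized_scores(self) -> pd.DataFrame:
        """Min-max scaled to [0, 1] over the whole table."""
        lo = self.scores.to_numpy().min()
        hi = self.scores.to_numpy().max()
        if hi == lo:
            return self.scores * 0.0
        return (self.scores - lo) / (hi - lo)


@dataclass
class GeneInterval:
    """0-based half-open genomic interval of a gene."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")


def sampling_shapley(
    f,
    X: np.ndarray,
    background: np.ndarray,
    n_samples: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Permutation-sampling Shapley values of ``f`` for each row of ``X``.

    ``f`` maps an ``(m, n_features)`` array to an ``(m, d)`` output.  Returns
    an ``(n_rows, n_features, d)`` array.  ``n_samples`` is the model-
    evaluation budget per explained row (default ``2 * n_features + 2048``);
    at least ``n_features + 2`` evaluations (one full permutation walk) are
    needed and the budget is raised to that with a warning if it is smaller.
    """
    X = np.atleast_2d(X)
    background = np.atleast_2d(background)
    n_rows, n_feat = X.shape
    if n_samples is None:
        n_samples = 2 * n_feat + 2048
    if n_samples < n_feat + 2:
        warnings.warn(
            f"n_samples={n_samples} below one permutation walk; raising to {n_feat + 2}"
        )
        n_samples = n_feat + 2
    n_perms = max(1, n_samples // (n_feat + 1))
    rng = np.random.default_rng(seed)

    d = np.atleast_2d(f(X[:1])).shape[1]
    phi = np.zeros((n_rows, n_feat, d))
    for r in range(n_rows):
        x = X[r]
        acc = np.zeros((n_feat, d))
        for _ in range(n_perms):
            b = background[rng.integers(len(background))]
            order = rng.permutation(n_feat)
            # rows 0..n_feat: background with the first j features (in walk
            # order) replaced by x's values
            walk = np.tile(b, (n_feat + 1, 1))
            for j, feat in enumerate(order):
                walk[j + 1 :, feat] = x[feat]
            out = np.atleast_2d(f(walk))
            acc[order] += out[1:] - out[:-1]
        phi[r] = acc / n_perms
    return phi


def _concat_inputs(ds: PairedDataset) -> np.ndarray:
    return np.concatenate(
        [np.asarray(ds.modality_1.values, float), np.asarray(ds.modality_2.values, float)],
        axis=1,
    )


def attribute_features(
    state: ModelState,
    ds: PairedDataset,
    task: str = "classification",
    background_size: int = 100,
    n_samples: int | None = None,
    max_cells_per_type: int = 25,
    seed: int = 0,
) -> tuple[AttributionTable, AttributionTable]:
    """Mean |Shapley value| per feature and cell type, one table per modality.

    Both modalities are attributed jointly over the concatenated feature
    vector, then split back into per-modality tables.  For the
    ``classification`` task the explained output is the probability of each
    cell's own type; for ``dimension_reduction`` it is the cell embedding,
    with per-feature contributions summed in absolute value across the
    embedding coordinates.
    """
    if task not in TASK_TAGS:
        raise ValidationError(f"task must be one of {TASK_TAGS}")
    if ds.cell_labels is None:
        raise ValidationError("attribution aggregates per cell type; labels required")
    v1 = ds.modality_1.n_features
    X_all = _concat_inputs(ds)
    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(ds.n_cells, size=min(background_size, ds.n_cells), replace=False)
    background = X_all[bg_idx]

    codec = LabelCodec(state.classes) if state.classes else LabelCodec.from_labels(ds.cell_labels)

    def model_fn_for(class_code: int | None):
        def f(X):
            x1, x2 = X[:, :v1], X[:, v1:]
            emb = encode(state, x1, x2)
            if task == "dimension_reduction":
                return emb.z
            return classify(state, emb.z)[:, [class_code]]

        return f

    labels = np.asarray(ds.cell_labels)
    per_type: dict[str, np.ndarray] = {}
    for t_i, t_name in enumerate(sorted(set(labels))):
        cells = np.where(labels == t_name)[0]
        if len(cells) > max_cells_per_type:
            cells = rng.choice(cells, size=max_cells_per_type, replace=False)
        code = codec.encode([t_name])[0] if task == "classification" else None
        phi = sampling_shapley(
            model_fn_for(code),
            X_all[cells],
            background,
            n_samples=n_samples,
            seed=seed + 1 + t_i,
        )
        # mean over cells of the per-feature magnitude (summed over output dims)
        per_type[t_name] = np.abs(phi).sum(axis=2).mean(axis=0)

    scores = pd.DataFrame(per_type)
    t1 = AttributionTable(
        scores.iloc[:v1].set_axis(ds.modality_1.feature_ids),
        ds.modality_1.modality_tag,
        task,
    )
    t2 = AttributionTable(
        scores.iloc[v1:].set_axis(ds.modality_2.feature_ids),
        ds.modality_2.modality_tag,
        task,
    )
    return t1, t2


def rank_markers(table: AttributionTable, cell_type: str, top_k: int = 10) -> pd.Series:
    """Top features for one cell type by normalized score, ties broken by ID."""
    if cell_type not in table.scores.columns:
        raise ValidationError(
            f"unknown cell type {cell_type!r}; table has {list(table.scores.columns)}"
        )
    norm = table.normalized_scores[cell_type]
    order = sorted(norm.index, key=lambda f: (-norm[f], f))
    return norm.loc[order[: min(top_k, len(order))]]


def attribution_long_table(tables: list[AttributionTable]) -> pd.DataFrame:
    """Long-format (feature, cell_type, modality, task, score, normalized_score)."""
    rows = []
    for t in tables:
        norm = t.normalized_scores
        for ct in t.scores.columns:
            for feat in t.scores.index:
                rows.append(
                    {
                        "feature": feat,
                        "cell_type": ct,
                        "modality": t.modality_tag,
                        "task": t.task_tag,
                        "score": t.scores.loc[feat, ct],
                        "normalized_score": norm.loc[feat, ct],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# peak -> gene mapping
# ---------------------------------------------------------------------------

_PEAK_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_peak_id(peak_id: str) -> tuple[str, int, int]:
    m = _PEAK_RE.match(peak_id)
    if m is None:
        raise ValidationError(f"malformed peak id {peak_id!r}; expected 'chrom:start-end'")
    start, end = int(m["start"]), int(m["end"])
    if start >= end:
        raise ValidationError(f"peak {peak_id!r} has start >= end")
    return m["chrom"], start, end


def read_gene_annotation(path) -> list[GeneInterval]:
    """Gene intervals from BED6 (chrom start end name score strand) or GTF."""
    path = str(path)
    genes = []
    if path.endswith((".gtf", ".gff")):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attr"],
        )
        df = df[df["feature"] == "gene"]
        for _, r in df.iterrows():
            m = re.search(r'gene_id[ =]+"?([^";]+)"?', r["attr"])
            gene_id = m.group(1) if m else f"{r.chrom}:{r.start}-{r.end}"
            # GTF coordinates are 1-based inclusive
            genes.append(GeneInterval(gene_id, str(r.chrom), int(r.start) - 1, int(r.end), r.strand))
    else:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        for _, r in df.iterrows():
            genes.append(GeneInterval(str(r["name"]), str(r.chrom), int(r.start), int(r.end), str(r.strand)))
    return genes


def map_peaks_to_genes(
    peaks: list[str], genes: list[GeneInterval], window: int = 2000
) -> dict[str, list[str]]:
    """Map each peak to genes whose promoter-extended interval it overlaps.

    The gene interval is extended ``window`` bp upstream of the transcription
    start (strand-aware); overlap is on 0-based half-open intervals.  Peaks
    overlapping nothing map to an empty list.
    """
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    result: dict[str, list[str]] = {}
    for pid in peaks:
        chrom, ps, pe = parse_peak_id(pid)
        hits = []
        for g in by_chrom.get(chrom, []):
            gs = g.start - window if g.strand == "+" else g.start
            ge = g.end + window if g.strand == "-" else g.end
            if ps < ge and pe > max(gs, 0):
                hits.append(g.gene_id)
        result[pid] = sorted(hits)
    return result
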