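"""Clustering/classification metrics and simulation-fidelity scoring.

ARI is the permutation-model adjusted Rand index in its pair-counting form;
NMI normalizes mutual information by max{H(P), H(T)}; AMI subtracts the
exact hypergeometric expected mutual information.  All three operate on a
contingency table and use natural logarithms (the ratios are base-invariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import pearsonr
from sklearn.cluster import KMeans

from .data_io import OmicsMatrix, ValidationError


@dataclass
class Partition:
    """Integer cluster assignment over n items, labels in [0, n_groups)."""

    assignments: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.assignments)
        if arr.ndim != 1 or arr.size < 1:
            raise ValidationError("assignments must be a nonempty 1-D vector")
        # relabel to consecutive integers so any hashable labels are accepted
        _, self.assignments = np.unique(arr, return_inverse=True)

    @property
    def n(self) -> int:
        return self.assignments.size

    @property
    def n_groups(self) -> int:
        return int(self.assignments.max()) + 1


@dataclass
class PairCounts:
    """Pair agreement counts between two partitions of the same n items.

    N1: same cluster in both; N2: different in both; N3: same in P only;
    N4: same in T only.  They sum to n(n-1)/2.
    """

    N1: int
    N2: int
    N3: int
    N4: int


def _contingency(P: Partition, T: Partition) -> np.ndarray:
    if P.n != T.n:
        raise ValidationError("partitions must cover the same items")
    table = np.zeros((P.n_groups, T.n_groups), dtype=np.int64)
    np.add.at(table, (P.assignments, T.assignments), 1)
    return table


def pair_counts(P: Partition, T: Partition) -> PairCounts:
    table = _contingency(P, T)
    n = P.n
    comb2 = lambda x: x * (x - 1) // 2
    N1 = int(comb2(table).sum())
    same_p = int(comb2(table.sum(axis=1)).sum())
    same_t = int(comb2(table.sum(axis=0)).sum())
    N3 = same_p - N1
    N4 = same_t - N1
    N2 = comb2(n) - N1 - N3 - N4
    return PairCounts(N1, N2, N3, N4)


def adjusted_rand_index(P: Partition, T: Partition) -> float:
    """Adjusted Rand index under the permutation (hypergeometric) null.

    1 for identical partitions, ~0 for random assignment; can be negative.
    """
    if P.n < 2:
        return 1.0 if P.n_groups == T.n_groups else 0.0
    c = pair_counts(P, T)
    total = c.N1 + c.N2 + c.N3 + c.N4
    # expected index term from the marginal pair counts
    exp = ((c.N1 + c.N3) * (c.N1 + c.N4) + (c.N4 + c.N2) * (c.N3 + c.N2)) / total
    num = total * (c.N1 + c.N2) - ((c.N1 + c.N3) * (c.N1 + c.N4) + (c.N4 + c.N2) * (c.N3 + c.N2))
    den = total * total - ((c.N1 + c.N3) * (c.N1 + c.N4) + (c.N4 + c.N2) * (c.N3 + c.N2))
    if den == 0:  # both partitions put every pair together or every pair apart
        return 1.0
    return float(num / den)


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    nz = table > 0
    nij = table[nz].astype(float)
    ai = table.sum(axis=1, keepdims=True)
    bj = table.sum(axis=0, keepdims=True)
    outer = (ai @ bj)[nz].astype(float)
    return float((nij / n * np.log(n * nij / outer)).sum())


def normalized_mutual_information(P: Partition, T: Partition) -> float:
    """I(P, T) / max{H(P), H(T)}; conventions for degenerate partitions below.

    If both partitions are single-cluster (identical), returns 1; if only one
    is single-cluster the score is 0.
    """
    table = _contingency(P, T)
    n = P.n
    hp = _entropy(table.sum(axis=1), n)
    ht = _entropy(table.sum(axis=0), n)
    hmax = max(hp, ht)
    if hmax == 0.0:
        return 1.0
    if min(hp, ht) == 0.0:
        return 0.0
    return float(_mutual_information(table) / hmax)


def expected_mutual_information(table: np.ndarray) -> float:
    """Exact E{I} under the hypergeometric model of random labelings."""
    n = int(table.sum())
    a = table.sum(axis=1).astype(int)
    b = table.sum(axis=0).astype(int)
    lg = gammaln  # log Gamma(x); log(x!) = lg(x + 1)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                # log hypergeometric pmf at nij
                log_p = (
                    lg(ai + 1) - lg(nij + 1) - lg(ai - nij + 1)
                    + lg(n - ai + 1) - lg(bj - nij + 1) - lg(n - ai - bj + nij + 1)
                    - (lg(n + 1) - lg(bj + 1) - lg(n - bj + 1))
                )
                emi += np.exp(log_p) * (nij / n) * np.log(n * nij / (ai * bj))
    return float(emi)


def adjusted_mutual_information(P: Partition, T: Partition) -> float:
    """(I - E{I}) / (max{H(P), H(T)} - E{I}); 1 iff partitions identical."""
    table = _contingency(P, T)
    n = P.n
    hp = _entropy(table.sum(axis=1), n)
    ht = _entropy(table.sum(axis=0), n)
    hmax = max(hp, ht)
    if hmax == 0.0:
        return 1.0
    if min(hp, ht) == 0.0:
        return 0.0
    mi = _mutual_information(table)
    emi = expected_mutual_information(table)
    den = hmax - emi
    if abs(den) < 1e-15:
        return 1.0 if abs(mi - emi) < 1e-15 else 0.0
    return float((mi - emi) / den)


def cluster_embedding(
    z: np.ndarray, k: int, n_init: int = 30, seed: int = 0
) -> Partition:
    """k-means on the embedding, keeping the best of ``n_init`` seeded restarts."""
    z = np.asarray(z, dtype=float)
    if k > z.shape[0]:
        raise ValidationError(f"k={k} exceeds number of cells {z.shape[0]}")
    if k < 2:
        raise ValidationError("k must be at least 2")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return Partition(km.fit_predict(z))


def classification_accuracy(
    pred, true, per_class: bool = False
) -> float | tuple[float, pd.Series]:
    """Fraction correct; optionally per-true-class recall as a Series."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValidationError("predictions and labels must be nonempty and equal length")
    overall = float((pred == true).mean())
    if not per_class:
        return overall
    recalls = {}
    for cls in np.unique(true):
        mask = true == cls
        recalls[cls] = float((pred[mask] == cls).mean())
    return overall, pd.Series(recalls, name="recall")


def simulation_fidelity(
    real: OmicsMatrix, sim: OmicsMatrix, n_top: int = 100
) -> dict:
    """Mean-expression Pearson correlation over the union of top-HVG sets.

    Highly variable features are picked (dispersion ranking) in the real and
    simulated matrices separately; the summary is the Pearson correlation of
    per-feature mean expression between real and simulated over the union.
    ``per_feature`` holds each feature's quantile-profile correlation for a
    box-plot style view.
    """
    shared = [f for f in real.feature_ids if f in set(sim.feature_ids)]
    if len(shared) < 3:
        raise ValidationError("need at least 3 shared features")
    from .data_io import _hvg_indices

    def top_ids(mat: OmicsMatrix) -> list[str]:
        pos = [mat.feature_ids.index(f) for f in shared]
        vals = mat.values[:, pos]
        k = min(n_top, len(shared))
        if k >= len(shared):
            return list(shared)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idx = _hvg_indices(vals, shared, k)
        return [shared[i] for i in idx]

    union = sorted(set(top_ids(real)) | set(top_ids(sim)))
    r_pos = [real.feature_ids.index(f) for f in union]
    s_pos = [sim.feature_ids.index(f) for f in union]
    mean_r = real.values[:, r_pos].mean(axis=0)
    mean_s = sim.values[:, s_pos].mean(axis=0)
    summary = float(pearsonr(mean_r, mean_s)[0])

    per_feature = {}
    q = np.linspace(0.05, 0.95, 19)
    for f, rp, sp in zip(union, r_pos, s_pos):
        qr = np.quantile(real.values[:, rp], q)
        qs = np.quantile(sim.values[:, sp], q)
        if np.std(qr) == 0 or np.std(qs) == 0:
            per_feature[f] = np.nan
        else:
            per_feature[f] = float(pearsonr(qr, qs)[0])
    return {
        "pearson_mean_expression": summary,
        "features": union,
        "per_feature": pd.Series(per_feature, name="pearson"),
    }
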