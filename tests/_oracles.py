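"""Independent brute-force oracles used to verify the metric implementations.

Deliberately written along different algebraic routes than the package:
explicit O(n^2) pair loops, probability-dictionary entropies and exact
integer-combinatorics hypergeometric expectations.
"""

import math
from collections import Counter
from itertools import combinations


def all_partitions(n):
    """All set partitions of range(n) as canonical label tuples (restricted
    growth strings)."""
    results = []

    def grow(prefix, n_used):
        i = len(prefix)
        if i == n:
            results.append(tuple(prefix))
            return
        for lab in range(n_used + 1):
            grow(prefix + [lab], max(n_used, lab + 1))

    grow([], 0)
    return results


def ari_brute(p, t):
    """ARI via explicit pair counting and the expected/max-index form."""
    n = len(p)
    if n < 2:
        return 1.0
    same_both = same_p = same_t = 0
    for i, j in combinations(range(n), 2):
        sp = p[i] == p[j]
        st = t[i] == t[j]
        same_p += sp
        same_t += st
        same_both += sp and st
    total = n * (n - 1) // 2
    expected = same_p * same_t / total
    max_index = (same_p + same_t) / 2
    if max_index == expected:
        return 1.0 if same_both == max_index else 0.0
    return (same_both - expected) / (max_index - expected)


def _entropy_from_counts(counts, n):
    return -sum(c / n * math.log(c / n) for c in counts if c > 0)


def _mi_from_labels(p, t):
    n = len(p)
    joint = Counter(zip(p, t))
    cp = Counter(p)
    ct = Counter(t)
    mi = 0.0
    for (a, b), nij in joint.items():
        mi += nij / n * math.log(n * nij / (cp[a] * ct[b]))
    return mi


def nmi_brute(p, t):
    n = len(p)
    hp = _entropy_from_counts(Counter(p).values(), n)
    ht = _entropy_from_counts(Counter(t).values(), n)
    if max(hp, ht) == 0.0:
        return 1.0
    if min(hp, ht) == 0.0:
        return 0.0
    return _mi_from_labels(p, t) / max(hp, ht)


def emi_brute(p, t):
    """Exact expected MI under random labelings, by integer combinatorics."""
    n = len(p)
    a_counts = list(Counter(p).values())
    b_counts = list(Counter(t).values())
    emi = 0.0
    for ai in a_counts:
        for bj in b_counts:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                prob = (
                    math.comb(bj, nij) * math.comb(n - bj, ai - nij) / math.comb(n, ai)
                )
                emi += prob * nij / n * math.log(n * nij / (ai * bj))
    return emi


def ami_brute(p, t):
    n = len(p)
    hp = _entropy_from_counts(Counter(p).values(), n)
    ht = _entropy_from_counts(Counter(t).values(), n)
    hmax = max(hp, ht)
    if hmax == 0.0:
        return 1.0
    if min(hp, ht) == 0.0:
        return 0.0
    mi = _mi_from_labels(p, t)
    emi = emi_brute(p, t)
    if abs(hmax - emi) < 1e-15:
        return 1.0 if abs(mi - emi) < 1e-15 else 0.0
    return (mi - emi) / (hmax - emi)


def exact_shapley(f_single, x, background, n_features):
    """Exact Shapley values by full coalition enumeration.

    ``f_single`` maps one feature vector to a scalar.  The value of a
    coalition S is the mean of f over background rows with S's features
    replaced by x's values.
    """
    def value(S):
        tot = 0.0
        for b in background:
            v = list(b)
            for i in S:
                v[i] = x[i]
            tot += f_single(v)
        return tot / len(background)

    feats = list(range(n_features))
    phi = [0.0] * n_features
    for i in feats:
        rest = [j for j in feats if j != i]
        for r in range(len(rest) + 1):
            for S in combinations(rest, r):
                w = (
                    math.factorial(len(S))
                    * math.factorial(n_features - len(S) - 1)
                    / math.factorial(n_features)
                )
                phi[i] += w * (value(S + (i,)) - value(S))
    return phi
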