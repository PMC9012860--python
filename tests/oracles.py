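"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: exact 1-D k-means by
enumerating contiguous partitions of the sorted values, and the silhouette
width computed directly from its definition.
"""

from itertools import combinations

import numpy as np


def exact_kmeans_1d(x, k):
    """Globally optimal k-means partition of 1-D data.

    The optimum is contiguous in sorted order, so enumerate all
    compositions.  Returns (ssq, labels aligned to sorted(x)).
    """
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    best_ssq, best_bounds = np.inf, None
    for splits in combinations(range(1, n), k - 1):
        bounds = (0, *splits, n)
        ssq = 0.0
        for a, b in zip(bounds, bounds[1:]):
            seg = xs[a:b]
            ssq += float(((seg - seg.mean()) ** 2).sum())
        if ssq < best_ssq:
            best_ssq, best_bounds = ssq, bounds
    labels = np.empty(n, dtype=int)
    for c, (a, b) in enumerate(zip(best_bounds, best_bounds[1:])):
        labels[a:b] = c
    return best_ssq, labels


def silhouette_brute(x, labels):
    """Average silhouette width from the definition (singletons score 0)."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    s = np.zeros(len(x))
    for i in range(len(x)):
        own = labels[i]
        same = x[(labels == own)]
        if len(same) == 1:
            s[i] = 0.0
            continue
        a = np.abs(same - x[i]).sum() / (len(same) - 1)
        b = min(
            np.abs(x[labels == c] - x[i]).mean() for c in uniq if c != own
        )
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def select_k_oracle(x, k_min=2, k_max=10):
    """K maximising the silhouette of the exact k-means partition; ties
    resolved toward the smaller K."""
    x = np.asarray(x, dtype=float)
    xs = np.sort(x)
    k_hi = min(k_max, len(np.unique(x)) - 1)
    best_k, best_sil = None, -np.inf
    sil_by_k = {}
    for k in range(k_min, k_hi + 1):
        _, labels = exact_kmeans_1d(xs, k)
        sil = silhouette_brute(xs, labels)
        sil_by_k[k] = sil
        if sil > best_sil:
            best_sil, best_k = sil, k
    return best_k, sil_by_k


def trim_oracle(gaps, retention):
    """Smallest value whose cumulative count / n >= retention."""
    v = np.sort(np.asarray(gaps))
    n = len(v)
    for g in v:
        if (v <= g).sum() / n >= retention:
            return float(g)
    return float(v[-1])
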