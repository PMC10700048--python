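"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately re-derive quantities from first principles (exact-integer
enumeration, naive per-locus loops, sort-and-count) without touching the
implementation paths they are used to check.
"""

from itertools import combinations
from math import comb

import numpy as np


def hwe_oracle(n0, n1, n2):
    """Exact-integer enumeration of the conditional HWE distribution."""
    n = n0 + n1 + n2
    na = n1 + 2 * n2
    nr = 2 * n - na
    rare = min(na, nr)

    def ways(h):
        return comb(n, (na - h) // 2) * comb(n - (na - h) // 2, h) * 2**h

    hs = range(rare % 2, rare + 1, 2)
    w = {h: ways(h) for h in hs}
    total = sum(w.values())
    w_obs = w[n1]
    return sum(v for v in w.values() if v <= w_obs) / total


def knn_oracle(X, y, x0, k):
    """Brute-force standardize / sort / count nearest-neighbour class shares."""
    s = X.std(axis=0, ddof=1)
    keep = s > 0
    Z = X[:, keep] / s[keep]
    z0 = x0[keep] / s[keep]
    d = np.linalg.norm(Z - z0, axis=1)
    order = np.argsort(d, kind="stable")[:k]
    classes = np.unique(y)
    return np.array([(y[order] == c).mean() for c in classes])


def naive_sumstats(G, trios):
    """Per-locus loop re-derivation of the full summary-statistic vector."""
    from abcsnp.sumstats import (
        admixture_estimate_locus,
        gene_diversity_locus,
        nei_distance_locus,
        wc_fst_locus,
    )

    counts = G.genotype_counts()
    L, ngrp, _ = counts.shape
    out = []
    for g in range(ngrp):
        vals = []
        for j in range(L):
            c = counts[j, g]
            ref = 2 * c[0] + c[1]
            alt = c[1] + 2 * c[2]
            if ref + alt >= 2:
                vals.append(gene_diversity_locus((ref, alt)))
        out.append(np.mean(vals))

    def freqs(j, g):
        c = counts[j, g]
        tot = 2 * c.sum()
        return (c[1] + 2 * c[2]) / tot if tot else np.nan

    pairs = list(combinations(range(ngrp), 2))
    for i, j in pairs:
        vals = [wc_fst_locus(counts[l, i], counts[l, j]) for l in range(L)]
        vals = [v for v in vals if np.isfinite(v) and v != 0]
        out.append(np.mean(vals))
    for i, j in pairs:
        vals = []
        for l in range(L):
            p, q = freqs(l, i), freqs(l, j)
            vals.append(nei_distance_locus((p, 1 - p), (q, 1 - q)))
        vals = [v for v in vals if np.isfinite(v) and v != 0]
        out.append(np.mean(vals))
    for a, p1, p2 in trios:
        vals = [admixture_estimate_locus(freqs(l, a), freqs(l, p1), freqs(l, p2))
                for l in range(L)]
        vals = [v for v in vals if np.isfinite(v) and v != 0]
        out.append(np.mean(vals))
    return np.array(out)
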