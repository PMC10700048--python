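"""DIYABC-style summary statistics for grouped biallelic genotype matrices.

The statistic vector has a fixed component order:

* per-group mean gene diversity across **all** loci (monomorphic loci
  contribute 0 to this "complete distribution" mean);
* per-pair mean Weir & Cockerham (1984) theta over loci whose per-locus value
  is defined and non-zero (negative estimates are retained — they are
  non-zero);
* per-pair mean Nei (1972) standard distance over loci with defined non-zero
  values;
* per-trio mean admixture estimate (Choisy-style frequency interpolation)
  over loci with defined non-zero values.

With five groups and one trio this gives 5 + 10 + 10 + 1 = 26 components.
Undefined per-locus values (monomorphic overall, zero denominator, no shared
alleles) are carried as NaN sentinels and never silently coerced to zero.
All statistics enter through allele frequencies symmetrically, so the vector
is invariant to allele-label polarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .coalsim import GenotypeMatrix, GroupConfig

__all__ = [
    "SumStatVector",
    "gene_diversity_locus",
    "wc_fst_locus",
    "nei_distance_locus",
    "admixture_estimate_locus",
    "compute_sumstats",
    "DEFAULT_TRIOS",
]

#: default three-sample configuration: LOWER-CENTRAL as the putatively
#: admixed group with UPPER-CENTRAL and SOUTHERN as parents
DEFAULT_TRIOS = ((1, 2, 0),)


@dataclass
class SumStatVector:
    """Ordered named summary statistics with per-component support counts."""

    names: tuple[str, ...]
    values: np.ndarray
    n_contributing: np.ndarray

    def __len__(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.values], columns=list(self.names))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def gene_diversity_locus(allele_counts) -> float:
    """Unbiased gene diversity H = n/(n-1) * (1 - sum p_a^2) at one locus."""
    c = np.asarray(allele_counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("gene diversity requires >= 2 gene copies")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p * p)))


def wc_fst_locus(counts1, counts2) -> float:
    """Weir & Cockerham (1984) theta-hat for two groups at one biallelic locus.

    ``counts1``/``counts2`` are genotype class counts (n_hom_ref, n_het,
    n_hom_alt). Returns NaN when the locus is monomorphic overall
    (a + b + c = 0) or either group has no genotypes.
    """
    counts = np.asarray([counts1, counts2], dtype=float)[None, :, :]
    theta = _wc_theta(counts)
    return float(theta[0])


def nei_distance_locus(p_x, p_y) -> float:
    """Nei (1972) standard genetic distance from per-allele frequencies.

    D = -ln( J_xy / sqrt(J_x J_y) ); NaN when no allele is shared (J_xy = 0,
    infinite distance).
    """
    p_x = np.asarray(p_x, dtype=float)
    p_y = np.asarray(p_y, dtype=float)
    jx = float(np.sum(p_x * p_x))
    jy = float(np.sum(p_y * p_y))
    jxy = float(np.sum(p_x * p_y))
    if jxy <= 0.0:
        return np.nan
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def admixture_estimate_locus(p_admixed: float, p_parent1: float, p_parent2: float) -> float:
    """Frequency-interpolation admixture estimate at one locus.

    f = (p_A - p_P2) / (p_P1 - p_P2), unclipped; NaN when the parents have
    equal frequencies.
    """
    denom = p_parent1 - p_parent2
    if denom == 0.0:
        return np.nan
    return (p_admixed - p_parent2) / denom


# ---------------------------------------------------------------------------
# vectorized cores over (n_loci, n_groups, 3) genotype-class counts

def _freqs(counts: np.ndarray):
    """Diploid sample sizes, alt-allele freqs and observed het freqs."""
    n_dip = counts.sum(axis=2).astype(float)  # (L, G)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (counts[:, :, 1] + 2.0 * counts[:, :, 2]) / (2.0 * n_dip)
        h = counts[:, :, 1] / n_dip
    return n_dip, p, h


def _wc_theta(counts: np.ndarray) -> np.ndarray:
    """Per-locus Weir-Cockerham theta over all groups in ``counts``.

    ``counts``: (L, r, 3). Returns (L,) with NaN where undefined.
    """
    n, p, h = _freqs(counts)
    r = counts.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n.mean(axis=1)
        rnbar = r * nbar
        nc = (rnbar - (n * n).sum(axis=1) / rnbar) / (r - 1.0)
        pbar = (n * p).sum(axis=1) / rnbar
        s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=1) / rnbar
        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0.0, a / denom, np.nan)
    # any group without genotypes, or nbar <= 1, is undefined
    theta = np.where((n > 0).all(axis=1) & (nbar > 1.0), theta, np.nan)
    return theta


def _gene_diversity(counts: np.ndarray) -> np.ndarray:
    """Per-locus per-group unbiased gene diversity; NaN where < 2 copies."""
    n_dip, p, _ = _freqs(counts)
    ncopies = 2.0 * n_dip
    with np.errstate(divide="ignore", invalid="ignore"):
        het = 2.0 * p * (1.0 - p)
        H = ncopies / (ncopies - 1.0) * het
    return np.where(ncopies >= 2.0, H, np.nan)


def _nei_distance(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    jx = p1 * p1 + (1.0 - p1) ** 2
    jy = p2 * p2 + (1.0 - p2) ** 2
    jxy = p1 * p2 + (1.0 - p1) * (1.0 - p2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -np.log(jxy / np.sqrt(jx * jy))
    return np.where(jxy > 0.0, d, np.nan)


def _mean_nonzero(values: np.ndarray, name: str):
    """Mean over defined, non-zero per-locus values; raises when empty."""
    ok = np.isfinite(values) & (values != 0.0)
    k = int(ok.sum())
    if k == 0:
        raise ValueError(f"empty contributing-locus set for statistic {name!r}")
    return float(values[ok].mean()), k


def sumstat_names(group_names, trios=DEFAULT_TRIOS) -> tuple[str, ...]:
    g = list(group_names)
    names = [f"gd_{x}" for x in g]
    names += [f"fst_{g[i]}_{g[j]}" for i, j in combinations(range(len(g)), 2)]
    names += [f"nei_{g[i]}_{g[j]}" for i, j in combinations(range(len(g)), 2)]
    names += [f"adm_{g[a]}_{g[p1]}_{g[p2]}" for a, p1, p2 in trios]
    return tuple(names)


def sumstats_from_counts(
    counts: np.ndarray,
    group_names,
    trios=DEFAULT_TRIOS,
) -> SumStatVector:
    """Compute the summary vector from (n_loci, n_groups, 3) genotype counts."""
    L, G, _ = counts.shape
    names = sumstat_names(group_names, trios)
    values: list[float] = []
    support: list[int] = []

    H = _gene_diversity(counts)  # (L, G); complete-distribution mean
    for g in range(G):
        col = H[:, g]
        defined = np.isfinite(col)
        if not defined.any():
            raise ValueError(f"empty contributing-locus set for statistic {names[g]!r}")
        values.append(float(col[defined].mean()))
        support.append(int(defined.sum()))

    _, p, _ = _freqs(counts)
    pairs = list(combinations(range(G), 2))
    idx = len(values)
    for i, j in pairs:
        theta = _wc_theta(counts[:, (i, j), :])
        v, k = _mean_nonzero(theta, names[idx])
        values.append(v)
        support.append(k)
        idx += 1
    for i, j in pairs:
        d = _nei_distance(p[:, i], p[:, j])
        v, k = _mean_nonzero(d, names[idx])
        values.append(v)
        support.append(k)
        idx += 1
    for a, p1, p2 in trios:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (p[:, a] - p[:, p2]) / (p[:, p1] - p[:, p2])
        f = np.where(p[:, p1] != p[:, p2], f, np.nan)
        v, k = _mean_nonzero(f, names[idx])
        values.append(v)
        support.append(k)
        idx += 1

    return SumStatVector(names, np.asarray(values), np.asarray(support))


def compute_sumstats(
    G: GenotypeMatrix,
    groups: GroupConfig | None = None,
    trios=DEFAULT_TRIOS,
) -> SumStatVector:
    """The ordered summary-statistic vector of a grouped genotype matrix.

    ``groups`` defaults to the matrix's own group labels; it is accepted to
    pin the component order explicitly.
    """
    if groups is not None and tuple(groups.names) != tuple(G.group_names):
        raise ValueError("group config does not match matrix group labels")
    if G.n_groups < 2:
        raise ValueError("at least two groups required")
    if G.n_loci < 1:
        raise ValueError("at least one locus required")
    return sumstats_from_counts(G.genotype_counts(), G.group_names, trios)
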