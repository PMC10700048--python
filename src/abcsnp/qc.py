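"""Genotype-matrix QC filter cascade.

Stages, applied in narrative order: biallelic-only, individual missingness
(< 30% kept), pooled minor-allele frequency (> 5% kept), Hardy-Weinberg exact
test (p <= .01 removed; pooled sample by default, per-group available),
global multi-group Weir-Cockerham theta outliers (theta > 0.1 removed by
default; the direction is configurable since retaining only high-FST loci
would bias demographic inference), and greedy all-pairs LD pruning at
r^2 >= 0.8. Complete-case locus selection is a separate step used to prepare
the ABC input.

Every stage returns a new matrix plus a :class:`FilterStage` record; the
cascade report telescopes (loci out of stage k = loci into stage k+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import lgamma, log

import numpy as np

from .coalsim import GenotypeMatrix
from .sumstats import _wc_theta

__all__ = [
    "QCConfig",
    "FilterStage",
    "FilterReport",
    "filter_biallelic",
    "filter_individual_missing",
    "filter_maf",
    "hwe_exact_pvalue",
    "filter_hwe",
    "filter_fst_outliers",
    "ld_prune",
    "complete_case",
    "run_cascade",
]


@dataclass(frozen=True)
class QCConfig:
    max_ind_missing: float = 0.30
    min_maf: float = 0.05
    hwe_alpha: float = 0.01
    hwe_per_group: bool = False
    fst_threshold: float = 0.10
    fst_mode: str = "remove_above"  # or "remove_below"
    ld_r2: float = 0.80


@dataclass
class FilterStage:
    name: str
    threshold: float | None
    n_loci_in: int
    n_loci_out: int
    n_individuals_in: int
    n_individuals_out: int
    removed_ids: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    stages: list[FilterStage] = field(default_factory=list)

    def append(self, stage: FilterStage) -> None:
        if self.stages:
            prev = self.stages[-1]
            if (stage.n_loci_in != prev.n_loci_out
                    or stage.n_individuals_in != prev.n_individuals_out):
                raise ValueError("filter report does not telescope")
        self.stages.append(stage)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "threshold": s.threshold,
                    "loci_in": s.n_loci_in,
                    "loci_out": s.n_loci_out,
                    "individuals_in": s.n_individuals_in,
                    "individuals_out": s.n_individuals_out,
                    "n_removed": len(s.removed_ids),
                }
                for s in self.stages
            ]
        )


def _stage(name, threshold, G, G2, removed):
    return FilterStage(name, threshold, G.n_loci, G2.n_loci,
                       G.n_individuals, G2.n_individuals, list(removed))


def filter_biallelic(G: GenotypeMatrix) -> tuple[GenotypeMatrix, FilterStage]:
    """Drop loci with more than two observed alleles.

    Genotype codes can only represent two alleles; multi-allelic loci are
    flagged by the per-locus ``n_alleles`` metadata carried from VCF input.
    Matrices without that metadata are already biallelic by construction.
    """
    if G.n_alleles is None:
        keep = np.ones(G.n_loci, dtype=bool)
    else:
        keep = G.n_alleles <= 2
    G2 = G.select_loci(keep)
    removed = [G.locus_ids[j] for j in np.flatnonzero(~keep)]
    return G2, _stage("biallelic", None, G, G2, removed)


def filter_individual_missing(
    G: GenotypeMatrix, max_rate: float = 0.30
) -> tuple[GenotypeMatrix, FilterStage]:
    """Remove individuals whose missing-call fraction is >= ``max_rate``."""
    rates = (G.genotypes < 0).mean(axis=1)
    keep = rates < max_rate
    if not keep.any():
        raise ValueError("individual-missingness filter removed every individual")
    G2 = G.select_individuals(keep)
    removed = [G.individual_ids[i] for i in np.flatnonzero(~keep)]
    return G2, _stage("individual_missing", max_rate, G, G2, removed)


def _pooled_maf(G: GenotypeMatrix) -> np.ndarray:
    gt = G.genotypes
    present = gt >= 0
    alt = np.where(present, gt, 0).sum(axis=0)
    copies = 2.0 * present.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / copies
    p = np.where(copies > 0, p, 0.0)
    return np.minimum(p, 1.0 - p)


def filter_maf(G: GenotypeMatrix, min_maf: float = 0.05) -> tuple[GenotypeMatrix, FilterStage]:
    """Keep loci whose pooled non-missing minor-allele frequency exceeds ``min_maf``."""
    maf = _pooled_maf(G)
    keep = maf > min_maf
    G2 = G.select_loci(keep)
    removed = [G.locus_ids[j] for j in np.flatnonzero(~keep)]
    return G2, _stage("maf", min_maf, G, G2, removed)


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test for one biallelic locus.

    Conditions on the allele counts and enumerates every heterozygote count
    of matching parity; the p-value is the total probability of
    configurations no more probable than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_alt = n_het + 2 * n_hom_alt
    n_ref = 2 * n - n_alt
    rare = min(n_alt, n_ref)
    # log P(h) up to a shared constant: log[ n! 2^h / (homR! h! homA!) ]
    def logp(h: int) -> float:
        ha = (n_alt - h) // 2
        hr = (n_ref - h) // 2
        return lgamma(n + 1) - lgamma(ha + 1) - lgamma(h + 1) - lgamma(hr + 1) + h * log(2.0)

    hs = list(range(rare % 2, rare + 1, 2))
    logs = np.array([logp(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(n_het)]
    return float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())


def filter_hwe(
    G: GenotypeMatrix, alpha: float = 0.01, per_group: bool = False
) -> tuple[GenotypeMatrix, FilterStage]:
    """Remove loci failing the exact HWE test at level ``alpha``.

    Tests the pooled sample by default; with ``per_group`` a locus is removed
    if it fails in any group (Wahlund-effect-robust variant).
    """
    counts = G.genotype_counts()  # (L, G, 3)
    if per_group:
        samples = [counts[:, g, :] for g in range(G.n_groups)]
    else:
        samples = [counts.sum(axis=1)]
    keep = np.ones(G.n_loci, dtype=bool)
    for sample in samples:
        for j in range(G.n_loci):
            if keep[j]:
                p = hwe_exact_pvalue(*sample[j])
                if p <= alpha:
                    keep[j] = False
    G2 = G.select_loci(keep)
    removed = [G.locus_ids[j] for j in np.flatnonzero(~keep)]
    return G2, _stage("hwe", alpha, G, G2, removed)


def filter_fst_outliers(
    G: GenotypeMatrix,
    threshold: float = 0.10,
    mode: str = "remove_above",
) -> tuple[GenotypeMatrix, FilterStage]:
    """Remove per-locus global Weir-Cockerham theta outliers.

    Undefined theta (globally monomorphic loci) is treated as non-outlier.
    """
    theta = _wc_theta(G.genotype_counts())
    if mode == "remove_above":
        drop = np.isfinite(theta) & (theta > threshold)
    elif mode == "remove_below":
        drop = np.isfinite(theta) & (theta <= threshold)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    G2 = G.select_loci(~drop)
    removed = [G.locus_ids[j] for j in np.flatnonzero(drop)]
    return G2, _stage("fst_outlier", threshold, G, G2, removed)


def _pairwise_r2(G: GenotypeMatrix, block: int = 512) -> np.ndarray:
    """Pairwise-complete squared genotype correlation between all locus pairs."""
    X = G.genotypes.astype(float)
    M = (X >= 0).astype(float)
    X = np.where(X >= 0, X, 0.0)
    L = X.shape[1]
    r2 = np.zeros((L, L))
    for a in range(0, L, block):
        Xa, Ma = X[:, a:a + block], M[:, a:a + block]
        for b in range(a, L, block):
            Xb, Mb = X[:, b:b + block], M[:, b:b + block]
            n = Ma.T @ Mb
            sx = (Xa * Ma).T @ Mb
            sy = Ma.T @ (Xb * Mb)
            sxy = Xa.T @ Xb
            sxx = (Xa * Xa).T @ Mb
            syy = Ma.T @ (Xb * Xb)
            with np.errstate(divide="ignore", invalid="ignore"):
                cov = sxy - sx * sy / n
                vx = sxx - sx * sx / n
                vy = syy - sy * sy / n
                r = cov / np.sqrt(vx * vy)
            r = np.where((n > 1) & (vx > 0) & (vy > 0), r, 0.0)
            r2[a:a + block, b:b + block] = r * r
            if b != a:
                r2[b:b + block, a:a + block] = (r * r).T
    return r2


def ld_prune(G: GenotypeMatrix, r2_threshold: float = 0.80) -> tuple[GenotypeMatrix, FilterStage]:
    """Greedy all-pairs LD pruning.

    For each locus pair with r^2 >= threshold (iterated in locus order), the
    member with higher missingness is dropped; ties go to the lower-MAF
    member, then to the later locus id. GBS tags have no genomic order, so no
    windowing is applied.
    """
    r2 = _pairwise_r2(G)
    miss = (G.genotypes < 0).mean(axis=0)
    maf = _pooled_maf(G)
    alive = np.ones(G.n_loci, dtype=bool)
    ii, jj = np.nonzero(np.triu(r2 >= r2_threshold, k=1))
    for i, j in zip(ii, jj):
        if not (alive[i] and alive[j]):
            continue
        if miss[i] != miss[j]:
            drop = i if miss[i] > miss[j] else j
        elif maf[i] != maf[j]:
            drop = i if maf[i] < maf[j] else j
        else:
            drop = j
        alive[drop] = False
    G2 = G.select_loci(alive)
    removed = [G.locus_ids[j] for j in np.flatnonzero(~alive)]
    return G2, _stage("ld_prune", r2_threshold, G, G2, removed)


def complete_case(G: GenotypeMatrix) -> tuple[GenotypeMatrix, FilterStage]:
    """Keep only loci with no missing genotype call (the ABC input set)."""
    keep = (G.genotypes >= 0).all(axis=0)
    G2 = G.select_loci(keep)
    removed = [G.locus_ids[j] for j in np.flatnonzero(~keep)]
    return G2, _stage("complete_case", None, G, G2, removed)


def run_cascade(
    G: GenotypeMatrix, config: QCConfig = QCConfig()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full filter cascade; complete-case selection is separate."""
    report = FilterReport()
    G, st = filter_biallelic(G)
    report.append(st)
    G, st = filter_individual_missing(G, config.max_ind_missing)
    report.append(st)
    G, st = filter_maf(G, config.min_maf)
    report.append(st)
    G, st = filter_hwe(G, config.hwe_alpha, config.hwe_per_group)
    report.append(st)
    G, st = filter_fst_outliers(G, config.fst_threshold, config.fst_mode)
    report.append(st)
    G, st = ld_prune(G, config.ld_r2)
    report.append(st)
    return G, report
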