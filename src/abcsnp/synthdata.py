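"""Synthetic datasets: a stand-in observed matrix, raw QC fixtures, toys.

``make_observed`` emulates the study design this package targets: 124
diploid individuals pooled from nine sampled populations (12-15 individuals
each) into five genetic groups, genotyped at 693 fully observed biallelic
SNPs, simulated under the divergence scenario 1 with the posterior-mean
truth parameters. Using the inferred posterior means as the generating truth
makes end-to-end recovery tests double as a plausibility check of the
inference itself.

``make_raw`` builds a larger matrix with *planted* QC violations (low-MAF
columns, Hardy-Weinberg heterozygote deficits, fixed inter-group
differences, duplicated locus blocks, beta-distributed per-individual
missingness) on a base of loci rejection-sampled to pass every filter with a
safety margin, so each filter's removal set is known exactly.

Everything is regenerable bit-identically from a :class:`TruthRecord`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalsim import (
    DEFAULT_GROUP_SIZES,
    GenotypeMatrix,
    GroupConfig,
    default_groups,
    simulate_dataset,
)
from .qc import _pooled_maf, hwe_exact_pvalue
from .scenarios import ParameterDraw, builtin_scenarios
from .sumstats import _wc_theta

__all__ = [
    "TruthRecord",
    "TRUE_PARAMS",
    "make_observed",
    "make_raw",
    "make_worked_example",
    "RawInjection",
]

#: generating truth for the stand-in observed dataset: the posterior means of
#: the divergence analysis (sizes in diploid individuals, times in generations)
TRUE_PARAMS = {
    "NA": 5.98e5,
    "N1": 3.44e3,
    "N2": 2.71e3,
    "N3": 2.60e3,
    "N4": 6.81e2,
    "N5": 3.65e2,
    "t1": 2.61e2,
    "t2": 3.51e2,
    "t3": 6.29e2,
    "t4": 1.26e3,
}

#: nine source populations of 12-15 individuals pooled into the five groups
SUBPOPULATION_SIZES = {
    "SOUTHERN": (14, 14),
    "LOWER-CENTRAL": (14, 14, 13),
    "UPPER-CENTRAL": (14, 13),
    "EASTERN": (14,),
    "NORTHERN": (14,),
}


@dataclass(frozen=True)
class TruthRecord:
    """Everything needed to regenerate a synthetic dataset bit-identically."""

    scenario_id: int
    values: dict[str, float]
    seed: int
    group_names: tuple[str, ...]
    group_counts: tuple[int, ...]
    n_loci: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "scenario_id": self.scenario_id,
            "values": self.values,
            "seed": self.seed,
            "group_names": list(self.group_names),
            "group_counts": list(self.group_counts),
            "n_loci": self.n_loci,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(d["scenario_id"], d["values"], d["seed"],
                   tuple(d["group_names"]), tuple(d["group_counts"]), d["n_loci"])


def _subpopulation_ids(groups: GroupConfig) -> list[str]:
    ids = []
    for name, count in zip(groups.names, groups.counts):
        sizes = SUBPOPULATION_SIZES.get(name, (count,))
        assert sum(sizes) == count
        k = 0
        for pop_i, size in enumerate(sizes, start=1):
            for _ in range(size):
                ids.append(f"{name}-P{pop_i}-{k:03d}")
                k += 1
    return ids


def make_observed(
    seed: int,
    n_loci: int = 693,
    truth: dict[str, float] | None = None,
    groups: GroupConfig | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate the stand-in observed dataset (124 x 693, no missing data)."""
    groups = groups or default_groups()
    truth = dict(truth or TRUE_PARAMS)
    scenario = builtin_scenarios()[0]
    record = TruthRecord(scenario.id, truth, seed, groups.names, groups.counts, n_loci)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    draw = ParameterDraw(scenario_id=scenario.id, values=truth)
    G = simulate_dataset(scenario, draw, groups, n_loci, rng)
    G.individual_ids = _subpopulation_ids(groups)
    return G, record


def regenerate(record: TruthRecord) -> GenotypeMatrix:
    """Rebuild a dataset from its truth record (bit-identical)."""
    groups = GroupConfig(record.group_names, record.group_counts)
    G, _ = make_observed(record.seed, record.n_loci, record.values, groups)
    return G


@dataclass(frozen=True)
class RawInjection:
    """Planted-violation fractions for the raw QC fixture."""

    frac_low_maf: float = 0.10
    frac_hwe: float = 0.02
    frac_fst: float = 0.02
    n_dup_blocks: int = 20  # blocks of 3 identical columns (2 pruned each)
    missing_beta: tuple[float, float] = (2.0, 38.0)  # mean 5% per individual
    n_bad_individuals: int = 3  # missing rate drawn in [0.35, 0.5]

    def zero(self) -> "RawInjection":
        return RawInjection(0.0, 0.0, 0.0, 0, (0.0, 0.0), 0)


# rejection margins for the clean base loci, slightly stricter than the
# filter thresholds; candidates are evaluated exactly as the cascade will see
# them (missingness applied, high-missingness individuals excluded)
_BASE_MAF = 0.055
_BASE_HWE_P = 0.02
_BASE_THETA = 0.095


def _clean_base(
    rng: np.random.Generator,
    groups: GroupConfig,
    n_loci: int,
    rates: np.ndarray,
    good: np.ndarray,
) -> np.ndarray:
    """Simulate loci, inject missingness, keep those passing all filters.

    ``rates`` are per-individual missing-call probabilities; margins are
    checked on the submatrix of ``good`` individuals, matching the state of
    the matrix when the locus filters run.
    """
    scenario = builtin_scenarios()[0]
    draw = ParameterDraw(scenario_id=scenario.id, values=TRUE_PARAMS)
    n_ind = groups.n_individuals
    cols: list[np.ndarray] = []
    total = 0
    while total < n_loci:
        G = simulate_dataset(scenario, draw, groups, max(n_loci, 500), rng)
        mask = rng.random((n_ind, G.n_loci)) < rates[:, None]
        G.genotypes = np.where(mask, -1, G.genotypes).astype(np.int8)
        sub = G.select_individuals(good)
        maf_ok = _pooled_maf(sub) > _BASE_MAF
        counts = sub.genotype_counts()
        theta = _wc_theta(counts)
        theta_ok = ~(np.isfinite(theta) & (theta > _BASE_THETA))
        pooled = counts.sum(axis=1)
        hwe_ok = np.array([
            hwe_exact_pvalue(*pooled[j]) > _BASE_HWE_P for j in range(sub.n_loci)
        ])
        keep = maf_ok & theta_ok & hwe_ok
        cols.append(G.genotypes[:, keep])
        total += int(keep.sum())
    return np.concatenate(cols, axis=1)[:, :n_loci]


def make_raw(
    seed: int,
    n_loci: int = 5000,
    injection: RawInjection = RawInjection(),
) -> tuple[GenotypeMatrix, dict]:
    """Raw genotype matrix with planted QC violations and exact bookkeeping.

    Returns the matrix and a record mapping each cascade stage to the ids it
    is expected to remove. With a zero injection the cascade is the identity
    on loci.
    """
    groups = default_groups()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    n_ind = groups.n_individuals
    gidx = groups.individual_groups()

    n_low = int(round(injection.frac_low_maf * n_loci))
    n_hwe = int(round(injection.frac_hwe * n_loci))
    n_fst = int(round(injection.frac_fst * n_loci))
    n_dup_extra = 2 * injection.n_dup_blocks  # block of 3 keeps 1
    n_base = n_loci - n_low - n_hwe - n_fst - n_dup_extra
    if n_base <= injection.n_dup_blocks:
        raise ValueError("injection fractions leave no base loci")

    record: dict[str, list[str]] = {
        "individual_missing": [], "maf": [], "hwe": [], "fst_outlier": [],
        "ld_prune": [],
    }
    individual_ids = _subpopulation_ids(groups)

    # per-individual missingness hits base columns only (planted columns stay
    # fully observed so their removal sets are exact); bad individuals get a
    # base-column rate scaled so their OVERALL missing fraction lands in
    # [0.35, 0.50], past the 30% removal threshold
    rates = rng.beta(*injection.missing_beta, size=n_ind) \
        if injection.missing_beta != (0.0, 0.0) else np.zeros(n_ind)
    bad = rng.choice(n_ind, size=injection.n_bad_individuals, replace=False) \
        if injection.n_bad_individuals else np.array([], dtype=int)
    overall_target = rng.uniform(0.35, 0.50, size=len(bad))
    rates[bad] = np.minimum(overall_target * n_loci / n_base, 0.95)
    record["individual_missing"] = [individual_ids[i] for i in sorted(bad)]
    good = np.setdiff1d(np.arange(n_ind), bad)

    base = _clean_base(rng, groups, n_base, rates, good)
    columns = [base]
    ids = [f"base{j:05d}" for j in range(n_base)]

    # low-MAF loci: two alt copies in the pooled sample (MAF ~ 0.008)
    for j in range(n_low):
        col = np.zeros(n_ind, dtype=np.int8)
        col[rng.choice(n_ind, size=2, replace=False)] = 1
        columns.append(col[:, None])
        ids.append(f"lowmaf{j:05d}")
        record["maf"].append(ids[-1])

    # HWE violators: total heterozygote deficit at intermediate frequency
    for j in range(n_hwe):
        col = np.zeros(n_ind, dtype=np.int8)
        col[rng.permutation(n_ind)[: n_ind // 2]] = 2
        columns.append(col[:, None])
        ids.append(f"hwe{j:05d}")
        record["hwe"].append(ids[-1])

    # FST outliers: first group all heterozygous, the rest homozygous
    # reference — strong differentiation (theta ~ 0.5) whose within-group
    # heterozygote excess offsets the Wahlund deficit, so the pooled HWE test
    # passes and the locus survives to the FST stage
    for j in range(n_fst):
        col = np.where(gidx == 0, 1, 0).astype(np.int8)
        columns.append(col[:, None])
        ids.append(f"fst{j:05d}")
        record["fst_outlier"].append(ids[-1])

    # duplicated blocks: 2 extra identical copies of a base column
    for b in range(injection.n_dup_blocks):
        src = base[:, b][:, None]
        for copy in (1, 2):
            columns.append(src.copy())
            ids.append(f"dup{b:03d}_{copy}")
            record["ld_prune"].append(ids[-1])

    genotypes = np.concatenate(columns, axis=1)
    G = GenotypeMatrix(genotypes, gidx, groups.names,
                       individual_ids=individual_ids, locus_ids=ids)
    return G, record


def make_worked_example() -> GenotypeMatrix:
    """Tiny hand-checkable matrix: 3 groups x 4 individuals x 6 loci.

    Locus 0 in group A has two missing calls and two heterozygotes, so its
    within-group allele counts are (2, 2) and its unbiased gene diversity is
    (4/3)(1 - 1/2) = 2/3. Groups A and B share identical columns at locus 5
    (Nei distance 0 there).
    """
    A = np.array([
        [1, 0, 2, 1, 0, 1],
        [1, 0, 2, 1, 0, 1],
        [-1, 1, 2, 0, 0, 2],
        [-1, 1, 1, 0, 0, 0],
    ])
    B = np.array([
        [0, 2, 0, 1, 1, 1],
        [0, 2, 0, 1, 1, 1],
        [1, 2, 0, 2, 0, 2],
        [1, 1, 1, 2, 0, 0],
    ])
    C = np.array([
        [2, 0, 1, 0, 2, 0],
        [2, 0, 1, 0, 2, 1],
        [2, 0, 0, 1, 2, 1],
        [1, 0, 0, 1, 1, 2],
    ])
    genotypes = np.vstack([A, B, C]).astype(np.int8)
    gidx = np.repeat([0, 1, 2], 4)
    return GenotypeMatrix(genotypes, gidx, ("A", "B", "C"))
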