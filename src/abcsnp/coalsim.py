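"""Hudson-style coalescent simulation of independent biallelic SNP loci.

Each locus is an independent realisation of the structured coalescent under a
scenario instantiated with one prior draw: within a deme of diploid size N a
pair of lineages coalesces at rate 1/(2N) per generation (continuous-time
exponential approximation, piecewise constant between demographic events);
merge events move all lineages of the source deme into the destination;
admixture events send each lineage of the admixed deme independently to
parent 1 with probability ra, else parent 2. One mutation is then placed
uniformly on the genealogy's branches (root branch excluded), so every locus
segregates in the pooled sample — the SNP-marker convention with the
minor-allele-frequency criterion left at its default, i.e. no extra MAF
rejection. Gene copies are paired into diploids in sampling order within each
deme (equivalent to random pairing by exchangeability).

The per-tree machinery is compiled with numba; ``simulate_dataset`` fuses
tree simulation, mutation placement and genotype formation in one kernel call
per dataset, which is what makes million-row reference tables feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .scenarios import GROUP_NAMES, ParameterDraw, Scenario, validate

__all__ = [
    "GroupConfig",
    "GenotypeMatrix",
    "Genealogy",
    "simulate_genealogy",
    "place_mutation",
    "simulate_dataset",
]

#: per-group diploid sample sizes of the study design (124 individuals pooled
#: from 9 populations of 12-15 into five groups)
DEFAULT_GROUP_SIZES = {
    "SOUTHERN": 28,
    "LOWER-CENTRAL": 41,
    "UPPER-CENTRAL": 27,
    "EASTERN": 14,
    "NORTHERN": 14,
}


@dataclass(frozen=True)
class GroupConfig:
    """Ordered group names with diploid sample counts (gene copies = 2x)."""

    names: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("group names must be unique")
        if len(self.names) != len(self.counts):
            raise ValueError("names and counts length mismatch")
        if any(c < 1 for c in self.counts):
            raise ValueError("sample counts must be >= 1")

    @classmethod
    def default(cls) -> "GroupConfig":
        return cls(tuple(DEFAULT_GROUP_SIZES), tuple(DEFAULT_GROUP_SIZES.values()))

    @property
    def n_individuals(self) -> int:
        return int(sum(self.counts))

    @property
    def n_copies(self) -> np.ndarray:
        return 2 * np.asarray(self.counts, dtype=np.int64)

    def individual_groups(self) -> np.ndarray:
        """Group index (into ``names``) of each individual, in block order."""
        return np.repeat(np.arange(len(self.names)), self.counts)


@dataclass
class GenotypeMatrix:
    """Individuals x loci biallelic genotypes with group labels.

    ``genotypes`` holds copies of the derived (or minor/alternate) allele in
    {0, 1, 2}, with -1 for missing. All shipped statistics are invariant to
    allele-label polarity.
    """

    genotypes: np.ndarray  # int8 (n_individuals, n_loci)
    group_indices: np.ndarray  # int per individual, into group_names
    group_names: tuple[str, ...]
    individual_ids: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)
    n_alleles: np.ndarray | None = None  # per-locus observed allele count (VCF input)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.group_indices = np.asarray(self.group_indices, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        n_ind, n_loci = self.genotypes.shape
        if self.group_indices.shape != (n_ind,):
            raise ValueError("one group index per individual required")
        bad = ~np.isin(self.genotypes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i:03d}" for i in range(n_ind)]
        if not self.locus_ids:
            self.locus_ids = [f"locus{j:05d}" for j in range(n_loci)]
        if len(self.individual_ids) != n_ind or len(self.locus_ids) != n_loci:
            raise ValueError("id lists must match matrix shape")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def group_config(self) -> GroupConfig:
        counts = tuple(
            int((self.group_indices == g).sum()) for g in range(self.n_groups)
        )
        return GroupConfig(self.group_names, counts)

    def genotype_counts(self) -> np.ndarray:
        """Per-locus, per-group genotype class counts.

        Returns an int64 array of shape (n_loci, n_groups, 3) with counts of
        genotypes 0, 1, 2 among non-missing calls.
        """
        out = np.zeros((self.n_loci, self.n_groups, 3), dtype=np.int64)
        for g in range(self.n_groups):
            sub = self.genotypes[self.group_indices == g]
            for code in (0, 1, 2):
                out[:, g, code] = (sub == code).sum(axis=0)
        return out

    def select_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.genotypes[:, keep],
            self.group_indices,
            self.group_names,
            list(self.individual_ids),
            [self.locus_ids[j] for j in keep],
            None if self.n_alleles is None else self.n_alleles[keep],
        )

    def select_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.genotypes[keep],
            self.group_indices[keep],
            self.group_names,
            [self.individual_ids[i] for i in keep],
            list(self.locus_ids),
            self.n_alleles,
        )


@dataclass
class Genealogy:
    """A coalescent tree over ``n`` sampled gene copies.

    Nodes 0..n-1 are leaves at time 0; internal nodes are numbered in
    coalescence order, the root is node 2n-2. ``parent[v]`` is -1 for the
    root; branch length of v is time[parent[v]] - time[v].
    """

    times: np.ndarray
    parent: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_demes: np.ndarray  # deme index of each leaf

    @property
    def n_leaves(self) -> int:
        return (len(self.times) + 1) // 2

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(len(self.times))
        non_root = self.parent >= 0
        bl[non_root] = self.times[self.parent[non_root]] - self.times[non_root]
        return bl

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaves_below(self, node: int) -> np.ndarray:
        n = self.n_leaves
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend((self.left[v], self.right[v]))
        return np.sort(np.asarray(out, dtype=np.int64))


# ---------------------------------------------------------------------------
# numba kernels

_ERR_NO_SIZE = 1  # >=2 lineages in a deme with no declared (positive) size


@njit(cache=True)
def _sim_tree(n_copies, sizes0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_rate,
              ev_newsize, times, parent, left, right, act, cnt):
    """Simulate one genealogy in place; returns an error code (0 = ok)."""
    n_demes = n_copies.shape[0]
    n = 0
    for d in range(n_demes):
        n += n_copies[d]
    sizes = sizes0.copy()
    # init active lineages: leaves in deme blocks
    base = 0
    for d in range(n_demes):
        cnt[d] = n_copies[d]
        for i in range(n_copies[d]):
            act[d, i] = base + i
        base += n_copies[d]
    for v in range(2 * n - 1):
        parent[v] = -1
        times[v] = 0.0
    next_node = n
    n_ev = ev_time.shape[0]
    t_start = 0.0
    for e in range(n_ev + 1):
        t_end = ev_time[e] if e < n_ev else np.inf
        for d in range(n_demes):
            k = cnt[d]
            if k < 2:
                continue
            if sizes[d] <= 0.0:
                return _ERR_NO_SIZE
            t = t_start
            while k >= 2:
                rate = k * (k - 1) / (4.0 * sizes[d])
                t += np.random.exponential(1.0 / rate)
                if t > t_end:
                    break
                i = np.random.randint(0, k)
                j = np.random.randint(0, k - 1)
                if j >= i:
                    j += 1
                if i > j:
                    i, j = j, i
                u = act[d, i]
                v = act[d, j]
                times[next_node] = t
                left[next_node] = u
                right[next_node] = v
                parent[u] = next_node
                parent[v] = next_node
                # remove slots j then i (j > i), then append the parent
                act[d, j] = act[d, k - 1]
                act[d, i] = act[d, k - 2]
                act[d, k - 2] = next_node
                next_node += 1
                k -= 1
            cnt[d] = k
        if e < n_ev:
            a = ev_a[e]
            if ev_kind[e] == 0:  # merge a -> b
                b = ev_b[e]
                for i in range(cnt[a]):
                    act[b, cnt[b]] = act[a, i]
                    cnt[b] += 1
                cnt[a] = 0
                if ev_newsize[e] > 0.0:
                    sizes[b] = ev_newsize[e]
            else:  # admixture: a -> b w.p. rate else c
                b = ev_b[e]
                c = ev_c[e]
                for i in range(cnt[a]):
                    if np.random.random() < ev_rate[e]:
                        act[b, cnt[b]] = act[a, i]
                        cnt[b] += 1
                    else:
                        act[c, cnt[c]] = act[a, i]
                        cnt[c] += 1
                cnt[a] = 0
            t_start = t_end
    return 0


@njit(cache=True)
def _place_mutation_counts(times, parent, left, right, n, derived):
    """Place one uniform mutation; fill per-leaf derived indicators."""
    total = 0.0
    for v in range(2 * n - 2):  # root (2n-2) excluded
        total += times[parent[v]] - times[v]
    u = np.random.random() * total
    m = 2 * n - 3
    acc = 0.0
    for v in range(2 * n - 2):
        acc += times[parent[v]] - times[v]
        if u < acc:
            m = v
            break
    for i in range(n):
        derived[i] = 0
    # stack traversal from m
    stack = np.empty(2 * n, dtype=np.int64)
    top = 0
    stack[top] = m
    top += 1
    while top > 0:
        top -= 1
        v = stack[top]
        if v < n:
            derived[v] = 1
        else:
            stack[top] = left[v]
            top += 1
            stack[top] = right[v]
            top += 1
    return m


@njit(cache=True)
def _sim_dataset(n_loci, n_copies, sizes0, ev_time, ev_kind, ev_a, ev_b, ev_c,
                 ev_rate, ev_newsize, seed, genotypes):
    """Simulate ``n_loci`` independent SNP loci; fill the genotype matrix."""
    np.random.seed(seed)
    n_demes = n_copies.shape[0]
    n = 0
    for d in range(n_demes):
        n += n_copies[d]
    times = np.empty(2 * n - 1)
    parent = np.empty(2 * n - 1, dtype=np.int64)
    left = np.empty(2 * n - 1, dtype=np.int64)
    right = np.empty(2 * n - 1, dtype=np.int64)
    act = np.empty((n_demes, n), dtype=np.int64)
    cnt = np.empty(n_demes, dtype=np.int64)
    derived = np.empty(n, dtype=np.int8)
    n_ind = n // 2
    for l in range(n_loci):
        err = _sim_tree(n_copies, sizes0, ev_time, ev_kind, ev_a, ev_b, ev_c,
                        ev_rate, ev_newsize, times, parent, left, right, act, cnt)
        if err != 0:
            return err
        _place_mutation_counts(times, parent, left, right, n, derived)
        for i in range(n_ind):
            genotypes[i, l] = derived[2 * i] + derived[2 * i + 1]
    return 0


@njit(cache=True)
def _sim_tree_seeded(seed, n_copies, sizes0, ev_time, ev_kind, ev_a, ev_b,
                     ev_c, ev_rate, ev_newsize, times, parent, left, right,
                     act, cnt):
    np.random.seed(seed)
    return _sim_tree(n_copies, sizes0, ev_time, ev_kind, ev_a, ev_b, ev_c,
                     ev_rate, ev_newsize, times, parent, left, right, act, cnt)


# ---------------------------------------------------------------------------
# scenario -> kernel arrays

def _instantiate(scenario: Scenario, draw: ParameterDraw, groups: GroupConfig):
    bad = validate(scenario)
    if bad:
        raise ValueError(f"invalid scenario {scenario.id}: {bad}")
    if draw.scenario_id != scenario.id:
        raise ValueError("parameter draw does not match scenario")
    if len(groups.names) != len(scenario.demes):
        raise ValueError("group config must have one group per sampled deme")
    deme_index = {d: i for i, d in enumerate(scenario.demes)}
    sizes0 = np.array([draw[s] for s in scenario.size_symbols], dtype=np.float64)
    n_ev = len(scenario.events)
    ev_time = np.empty(n_ev)
    ev_kind = np.empty(n_ev, dtype=np.int64)
    ev_a = np.empty(n_ev, dtype=np.int64)
    ev_b = np.empty(n_ev, dtype=np.int64)
    ev_c = np.full(n_ev, -1, dtype=np.int64)
    ev_rate = np.zeros(n_ev)
    ev_newsize = np.full(n_ev, -1.0)
    for i, ev in enumerate(scenario.events):
        ev_time[i] = draw[ev.time_symbol]
        if ev.kind == "merge":
            ev_kind[i] = 0
            ev_a[i] = deme_index[ev.source]
            ev_b[i] = deme_index[ev.dest]
        else:
            ev_kind[i] = 1
            ev_a[i] = deme_index[ev.admixed]
            ev_b[i] = deme_index[ev.parent1]
            ev_c[i] = deme_index[ev.parent2]
            ev_rate[i] = draw[ev.rate_symbol]
        if ev.dest_size_symbol is not None:
            ev_newsize[i] = draw[ev.dest_size_symbol]
    order = np.argsort(ev_time, kind="stable")
    if not np.all(np.diff(ev_time[order]) > 0):
        raise ValueError("instantiated event times must be strictly increasing")
    return (sizes0, ev_time[order], ev_kind[order], ev_a[order], ev_b[order],
            ev_c[order], ev_rate[order], ev_newsize[order])


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def simulate_genealogy(
    scenario: Scenario,
    draw: ParameterDraw,
    groups: GroupConfig,
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy of the pooled sample under the scenario."""
    arrays = _instantiate(scenario, draw, groups)
    n_copies = groups.n_copies
    n = int(n_copies.sum())
    n_demes = len(n_copies)
    times = np.empty(2 * n - 1)
    parent = np.empty(2 * n - 1, dtype=np.int64)
    left = np.empty(2 * n - 1, dtype=np.int64)
    right = np.empty(2 * n - 1, dtype=np.int64)
    act = np.empty((n_demes, n), dtype=np.int64)
    cnt = np.empty(n_demes, dtype=np.int64)
    err = _sim_tree_seeded(_kernel_seed(rng), n_copies, *arrays,
                           times, parent, left, right, act, cnt)
    if err == _ERR_NO_SIZE:
        raise ValueError("lineages remain in a deme with no declared size")
    leaf_demes = np.repeat(np.arange(n_demes), n_copies)
    return Genealogy(times, parent, left, right, leaf_demes)


def place_mutation(tree: Genealogy, rng: np.random.Generator) -> np.ndarray:
    """Drop a single mutation uniformly on the branches (root excluded).

    Returns the 0/1 derived-allele indicator per leaf; the locus segregates
    by construction (1 <= derived count <= n-1).
    """
    n = tree.n_leaves
    if n < 2:
        raise ValueError("tree must have at least 2 leaves")
    bl = tree.branch_lengths()[: 2 * n - 2]  # root branch excluded
    u = rng.uniform(0.0, bl.sum())
    node = int(np.searchsorted(np.cumsum(bl), u))
    node = min(node, 2 * n - 3)
    derived = np.zeros(n, dtype=np.int8)
    derived[tree.leaves_below(node)] = 1
    return derived


def simulate_dataset(
    scenario: Scenario,
    draw: ParameterDraw,
    groups: GroupConfig,
    n_loci: int,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Simulate a complete genotype matrix of independent SNP loci.

    Loci are independent genealogy + single-mutation realisations; diploid
    genotypes pair consecutive gene copies within each individual's deme.
    The result has no missing data and every locus is polymorphic in the
    pooled sample.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    arrays = _instantiate(scenario, draw, groups)
    genotypes = np.empty((groups.n_individuals, n_loci), dtype=np.int8)
    err = _sim_dataset(n_loci, groups.n_copies, *arrays,
                       _kernel_seed(rng), genotypes)
    if err == _ERR_NO_SIZE:
        raise ValueError("lineages remain in a deme with no declared size")
    return GenotypeMatrix(
        genotypes,
        groups.individual_groups(),
        groups.names,
    )


def default_groups() -> GroupConfig:
    """The five study groups with their default diploid sample sizes."""
    return GroupConfig(tuple(GROUP_NAMES), tuple(DEFAULT_GROUP_SIZES[g] for g in GROUP_NAMES))
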