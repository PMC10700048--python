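"""Summary statistics: hand values, a naive per-locus oracle, invariances."""

import numpy as np
import pytest
from _oracles import naive_sumstats
from hypothesis import given, settings
from hypothesis import strategies as st

from abcsnp.coalsim import GenotypeMatrix, GroupConfig, simulate_dataset
from abcsnp.scenarios import ParameterDraw, Scenario
from abcsnp.sumstats import (
    admixture_estimate_locus,
    compute_sumstats,
    gene_diversity_locus,
    nei_distance_locus,
    sumstats_from_counts,
    wc_fst_locus,
)


# ---------------------------------------------------------------------------
# independent transcription of the Weir-Cockerham (1984) two-population
# variance components, used as a dual-implementation oracle

def wc_components_oracle(counts1, counts2):
    r = 2
    n = [sum(counts1), sum(counts2)]
    p = [(c[1] + 2 * c[2]) / (2 * s) for c, s in zip((counts1, counts2), n)]
    h = [c[1] / s for c, s in zip((counts1, counts2), n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, a + b + c


def wc_theta_oracle(counts1, counts2):
    a, denom = wc_components_oracle(counts1, counts2)
    return a / denom if denom != 0 else float("nan")


def _null_components(counts):
    """Per-locus (a, a+b+c) arrays over a two-group counts tensor."""
    a = np.empty(len(counts))
    abc = np.empty(len(counts))
    for l in range(len(counts)):
        a[l], abc[l] = wc_components_oracle(counts[l, 0], counts[l, 1])
    return a, abc


class TestPerLocus:
    @pytest.mark.parametrize("counts, expected", [
        ((4, 0), 0.0),
        ((2, 2), 2.0 / 3.0),
        ((1, 1), 1.0),
    ])
    def test_gene_diversity_hand_values(self, counts, expected):
        assert gene_diversity_locus(counts) == pytest.approx(expected)

    def test_gene_diversity_needs_two_copies(self):
        with pytest.raises(ValueError):
            gene_diversity_locus((1, 0))

    def test_fst_identical_groups_nonpositive(self):
        assert wc_fst_locus((5, 10, 5), (5, 10, 5)) <= 0

    def test_fst_fixed_difference_is_one(self):
        assert wc_fst_locus((20, 0, 0), (0, 0, 20)) == pytest.approx(1.0)

    def test_fst_monomorphic_undefined(self):
        assert np.isnan(wc_fst_locus((10, 0, 0), (7, 0, 0)))

    def test_fst_matches_independent_transcription(self):
        cases = [((5, 5, 0), (0, 5, 5)), ((3, 4, 5), (8, 2, 1)),
                 ((10, 0, 2), (1, 9, 4)), ((2, 2, 2), (6, 1, 0))]
        for c1, c2 in cases:
            assert wc_fst_locus(c1, c2) == pytest.approx(wc_theta_oracle(c1, c2))

    @pytest.mark.parametrize("px, py, expected", [
        ((0.5, 0.5), (0.5, 0.5), 0.0),
        ((0.8, 0.2), (0.3, 0.7), -np.log(0.38 / np.sqrt(0.68 * 0.58))),
    ])
    def test_nei_hand_values(self, px, py, expected):
        assert nei_distance_locus(px, py) == pytest.approx(expected)

    def test_nei_disjoint_alleles_undefined(self):
        assert np.isnan(nei_distance_locus((1.0, 0.0), (0.0, 1.0)))

    @pytest.mark.parametrize("pa, p1, p2, expected", [
        (0.8, 0.8, 0.2, 1.0),
        (0.2, 0.8, 0.2, 0.0),
        (0.5, 0.8, 0.2, 0.5),
    ])
    def test_admixture_hand_values(self, pa, p1, p2, expected):
        assert admixture_estimate_locus(pa, p1, p2) == pytest.approx(expected)

    def test_admixture_equal_parents_undefined(self):
        assert np.isnan(admixture_estimate_locus(0.5, 0.4, 0.4))


@pytest.fixture(scope="module")
def random_matrix():
    rng = np.random.default_rng(42)
    geno = rng.integers(0, 3, size=(15, 40)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.05] = -1
    gidx = np.repeat([0, 1, 2], 5)
    return GenotypeMatrix(geno, gidx, ("A", "B", "C"))


class TestVector:
    def test_five_groups_default_trio_gives_26(self, rng):
        single = Scenario(id=93, events=(), demes=("Pop1",), size_symbols=("N1",))
        g1 = GroupConfig(("X",), (10,))
        G = simulate_dataset(single, ParameterDraw(93, {"N1": 200.0}), g1, 60, rng)
        groups5 = GroupConfig(("G1", "G2", "G3", "G4", "G5"), (2, 2, 2, 2, 2))
        G5 = GenotypeMatrix(G.genotypes, groups5.individual_groups(), groups5.names)
        assert len(compute_sumstats(G5)) == 26

    def test_matches_naive_oracle(self, worked_example, random_matrix):
        for G, trios in ((worked_example, ((0, 1, 2),)),
                         (random_matrix, ((2, 0, 1),))):
            got = compute_sumstats(G, trios=trios)
            expected = naive_sumstats(G, trios)
            np.testing.assert_allclose(got.values, expected, rtol=1e-12)

    def test_all_monomorphic_raises_empty_set(self):
        geno = np.zeros((8, 5), dtype=np.int8)
        G = GenotypeMatrix(geno, np.repeat([0, 1], 4), ("A", "B"))
        with pytest.raises(ValueError, match="empty contributing"):
            compute_sumstats(G, trios=())

    def test_polarity_invariance(self, random_matrix, rng):
        flipped = random_matrix.genotypes.copy()
        flip = rng.random(flipped.shape[1]) < 0.5
        cols = flipped[:, flip]
        cols[cols >= 0] = 2 - cols[cols >= 0]
        flipped[:, flip] = cols
        G2 = GenotypeMatrix(flipped, random_matrix.group_indices,
                            random_matrix.group_names)
        a = compute_sumstats(random_matrix, trios=((0, 1, 2),))
        b = compute_sumstats(G2, trios=((0, 1, 2),))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_permutation_and_locus_order_invariance(self, random_matrix, pyrandom):
        """Shuffling loci, or individuals within groups, changes nothing."""
        G = random_matrix
        locus_perm = list(range(G.n_loci))
        pyrandom.shuffle(locus_perm)
        ind_perm = []
        for g in range(G.n_groups):
            idx = list(np.flatnonzero(G.group_indices == g))
            pyrandom.shuffle(idx)
            ind_perm.extend(idx)
        G2 = G.select_individuals(np.array(ind_perm)).select_loci(np.array(locus_perm))
        a = compute_sumstats(G, trios=((0, 1, 2),))
        b = compute_sumstats(G2, trios=((0, 1, 2),))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_null_split_fst_centers_on_zero(self, rng):
        """Two pseudo-groups carved from one panmictic deme: mean theta ~ 0."""
        single = Scenario(id=92, events=(), demes=("Pop1",), size_symbols=("N1",))
        g1 = GroupConfig(("X",), (20,))
        G = simulate_dataset(single, ParameterDraw(92, {"N1": 500.0}), g1, 10_000, rng)
        pseudo = GenotypeMatrix(G.genotypes, np.repeat([0, 1], 10), ("A", "B"))
        from abcsnp.sumstats import _wc_theta

        counts = pseudo.genotype_counts()
        theta = _wc_theta(counts)
        vals = theta[np.isfinite(theta) & (theta != 0)]
        # the per-locus mean of ratios carries a small O(1/n) negative bias;
        # the multilocus ratio-of-sums estimator is the quantity whose null
        # expectation is zero to Monte-Carlo accuracy
        assert abs(vals.mean()) < 0.01
        a, abc = _null_components(counts)
        assert abs(a.sum() / abc.sum()) < 0.005

    def test_divergence_monotonicity(self, two_deme, pair_groups, rng):
        """Mean FST and Nei D increase with the split time."""
        fsts, neis = [], []
        for t in (50, 120, 280, 650, 1500):
            d = ParameterDraw(two_deme.id,
                              {"N1": 800.0, "N2": 800.0, "NA": 800.0, "t1": float(t)})
            G = simulate_dataset(two_deme, d, pair_groups, 3000, rng)
            ss = compute_sumstats(G, trios=())
            fsts.append(ss["fst_A_B"])
            neis.append(ss["nei_A_B"])
        ordered = sum(b > a for a, b in zip(fsts, fsts[1:]))
        ordered += sum(b > a for a, b in zip(neis, neis[1:]))
        assert ordered >= 7  # at least 7/8 adjacent comparisons ordered
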