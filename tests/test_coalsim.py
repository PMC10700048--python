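"""Coalescent simulator: closed-form checks and an msprime cross-check."""

import numpy as np
import pytest

from abcsnp.coalsim import (
    GenotypeMatrix,
    GroupConfig,
    default_groups,
    place_mutation,
    simulate_dataset,
    simulate_genealogy,
)
from abcsnp.scenarios import DemographicEvent, ParameterDraw, Scenario
from abcsnp.sumstats import compute_sumstats
from abcsnp.synthdata import TRUE_PARAMS


def _draw(scenario, **values):
    return ParameterDraw(scenario_id=scenario.id, values=values)


class TestSingleDeme:
    def test_pairwise_tmrca_mean_is_2n(self, single_deme, rng):
        """E[T2] = 2N generations for two gene copies in a deme of size N."""
        N = 1000.0
        d = _draw(single_deme, N1=N)
        g = GroupConfig(("A",), (1,))
        t = np.array([
            simulate_genealogy(single_deme, d, g, rng).times[-1]
            for _ in range(8000)
        ])
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert abs(t.mean() - 2 * N) < 3 * se

    def test_total_length_matches_harmonic_expectation(self, single_deme, rng):
        """E[L] = 4N * H_{n-1} for n gene copies."""
        N, n_dip = 500.0, 6
        d = _draw(single_deme, N1=N)
        g = GroupConfig(("A",), (n_dip,))
        L = np.array([
            simulate_genealogy(single_deme, d, g, rng).total_length
            for _ in range(8000)
        ])
        expected = 4 * N * sum(1.0 / i for i in range(1, 2 * n_dip))
        se = L.std(ddof=1) / np.sqrt(len(L))
        assert abs(L.mean() - expected) < 3 * se

    def test_missing_size_raises(self, rng):
        scn = Scenario(id=97, events=(), demes=("Pop1",), size_symbols=("N1",))
        with pytest.raises(ValueError, match="no declared size"):
            simulate_genealogy(scn, _draw(scn, N1=0.0), GroupConfig(("A",), (2,)), rng)


class TestStructure:
    def test_merge_confines_early_coalescence(self, two_deme, rng):
        """With tiny deme sizes, only the root coalescence is above the merge."""
        t_merge = 2000.0
        d = _draw(two_deme, N1=5.0, N2=5.0, NA=1e5, t1=t_merge)
        g = GroupConfig(("A", "B"), (5, 5))
        for _ in range(50):
            tree = simulate_genealogy(two_deme, d, g, rng)
            internal = tree.times[tree.n_leaves:]
            assert (internal > t_merge).sum() == 1  # only the cross-deme root

    def test_admixture_rate_one_equals_merge(self, rng):
        """ra = 1 sends every admixed lineage to parent 1 (a pure merge)."""
        demes = ("Pop1", "Pop2", "Pop3")
        admix = Scenario(
            id=96,
            events=(
                DemographicEvent(time_symbol="t1", kind="admixture", admixed="Pop3",
                                 parent1="Pop1", parent2="Pop2", rate_symbol="ra"),
                DemographicEvent(time_symbol="t2", kind="merge", source="Pop2",
                                 dest="Pop1", dest_size_symbol="NA"),
            ),
            demes=demes, size_symbols=("N1", "N2", "N3"),
        )
        merge = Scenario(
            id=95,
            events=(
                DemographicEvent(time_symbol="t1", kind="merge", source="Pop3",
                                 dest="Pop1"),
                DemographicEvent(time_symbol="t2", kind="merge", source="Pop2",
                                 dest="Pop1", dest_size_symbol="NA"),
            ),
            demes=demes, size_symbols=("N1", "N2", "N3"),
        )
        g = GroupConfig(("A", "B", "C"), (4, 4, 4))
        kw = dict(N1=500.0, N2=500.0, N3=500.0, NA=800.0, t1=100.0, t2=400.0)
        t_admix = [simulate_genealogy(admix, _draw(admix, ra=1.0, **kw), g, rng).times[-1]
                   for _ in range(4000)]
        t_merge = [simulate_genealogy(merge, _draw(merge, **kw), g, rng).times[-1]
                   for _ in range(4000)]
        se = np.hypot(np.std(t_admix) / np.sqrt(len(t_admix)),
                      np.std(t_merge) / np.sqrt(len(t_merge)))
        assert abs(np.mean(t_admix) - np.mean(t_merge)) < 4 * se


class TestMutation:
    def test_two_leaf_symmetry(self, single_deme, rng):
        d = _draw(single_deme, N1=200.0)
        g = GroupConfig(("A",), (1,))
        hits = 0
        reps = 10_000
        for _ in range(reps):
            tree = simulate_genealogy(single_deme, d, g, rng)
            hits += int(place_mutation(tree, rng)[0] == 1)
        se = np.sqrt(0.25 / reps)
        assert abs(hits / reps - 0.5) < 3 * se

    def test_every_locus_polymorphic(self, single_deme, rng):
        d = _draw(single_deme, N1=300.0)
        g = GroupConfig(("A",), (14,))
        G = simulate_dataset(single_deme, d, g, 2000, rng)
        derived = G.genotypes.sum(axis=0)
        assert derived.min() >= 1
        assert derived.max() <= 2 * 14 - 1
        assert (G.genotypes >= 0).all()


class TestDataset:
    def test_shape_and_determinism(self, scenarios, priors, rng):
        from abcsnp.scenarios import sample_prior

        groups = GroupConfig(("A",), (14,))
        single = Scenario(id=94, events=(), demes=("Pop1",), size_symbols=("N1",))
        d = _draw(single, N1=100.0)
        G = simulate_dataset(single, d, groups, 100, np.random.default_rng(3))
        assert G.genotypes.shape == (14, 100)
        G2 = simulate_dataset(single, d, groups, 100, np.random.default_rng(3))
        assert np.array_equal(G.genotypes, G2.genotypes)

    def test_draw_scenario_mismatch_raises(self, scenarios, rng):
        d = ParameterDraw(scenario_id=2, values=TRUE_PARAMS)
        with pytest.raises(ValueError, match="does not match"):
            simulate_dataset(scenarios[0], d, default_groups(), 10, rng)

    def test_oldest_split_accumulates_most_drift(self, scenarios, rng):
        """FST to the basal group exceeds FST between the youngest split pair."""
        d = ParameterDraw(scenario_id=1, values=TRUE_PARAMS)
        groups = default_groups()
        wins = 0
        reps = 40
        for _ in range(reps):
            G = simulate_dataset(scenarios[0], d, groups, 693, rng)
            ss = compute_sumstats(G)
            basal = ss["fst_SOUTHERN_UPPER-CENTRAL"]
            young = ss["fst_LOWER-CENTRAL_UPPER-CENTRAL"]
            wins += int(basal > young)
        assert wins >= int(0.95 * reps)


class TestMsprimeCrossCheck:
    """Independent structured-coalescent oracle for the two-deme split."""

    def test_split_model_tmrca_and_length(self, two_deme, rng):
        msprime = pytest.importorskip("msprime")
        N1, N2, NA, t_split = 400.0, 900.0, 1500.0, 350.0
        n1, n2 = 4, 4  # diploids per deme
        reps = 3000

        d = _draw(two_deme, N1=N1, N2=N2, NA=NA, t1=t_split)
        g = GroupConfig(("A", "B"), (n1, n2))
        ours_t, ours_L = [], []
        for _ in range(reps):
            tree = simulate_genealogy(two_deme, d, g, rng)
            ours_t.append(tree.times[-1])
            ours_L.append(tree.total_length)

        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=N1)
        dem.add_population(name="B", initial_size=N2)
        dem.add_population(name="ANC", initial_size=NA)
        dem.add_population_split(time=t_split, derived=["A", "B"], ancestral="ANC")
        ms_t, ms_L = [], []
        for ts in msprime.sim_ancestry(
            samples={"A": n1, "B": n2}, demography=dem, ploidy=2,
            num_replicates=reps, random_seed=12345,
        ):
            tr = ts.first()
            ms_t.append(tr.time(tr.root))
            ms_L.append(tr.total_branch_length)

        for ours, ms in ((ours_t, ms_t), (ours_L, ms_L)):
            ours, ms = np.asarray(ours), np.asarray(ms)
            se = np.hypot(ours.std() / np.sqrt(reps), ms.std() / np.sqrt(reps))
            assert abs(ours.mean() - ms.mean()) < 4 * se


class TestGenotypeMatrix:
    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError, match="codes"):
            GenotypeMatrix(np.array([[0, 3]]), np.array([0]), ("A",))

    def test_counts_sum_to_individuals(self, worked_example):
        counts = worked_example.genotype_counts()
        per_group = counts.sum(axis=2)  # non-missing individuals per locus/group
        assert per_group.max() <= 4
        assert counts.shape == (6, 3, 3)
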