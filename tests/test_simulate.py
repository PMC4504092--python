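"""Coalescent simulator: scenario catalogue, priors, neutral expectations,
degenerate-admixture equivalence, and an independent-simulator cross-check."""

import numpy as np
import pytest
from scipy import stats as sps

from minkpop.datamodel import collapse_haplotypes
from minkpop.diversity import segregating_sites
from minkpop.simulate import (
    Admixture,
    DemographicScenario,
    MutationModel,
    Prior,
    PriorSpec,
    SampleConfig,
    Split,
    default_priors,
    generate_mink_like,
    mink_scenarios,
    sample_priors,
    simulate_coalescent,
)

ONE_POP = DemographicScenario(
    name="one_pop", populations=["NE"], events=[]
)


def seq_sample(n, L=1000):
    return SampleConfig(genotypes={"NE": 0}, sequences={"NE": n}, seq_length=L)


class TestScenarios:
    def test_fourteen_scenarios(self):
        scens = mink_scenarios()
        assert len(scens) == 14
        assert [s.name for s in scens] == [f"scenario_{i}" for i in range(1, 15)]

    def test_scenario2_structure(self):
        s2 = mink_scenarios()[1]
        kinds = [type(e).__name__ for e in s2.events]
        assert kinds[:3] == ["Split", "Admixture", "Split"]
        split1, admix, split2 = s2.events[:3]
        assert (split1.derived, split1.ancestor, split1.t) == ("SP", "FR", "T1")
        assert (admix.derived, admix.source_a, admix.source_b) == ("FR", "NE", "SE")
        assert admix.t == "T2"
        assert (split2.derived, split2.ancestor, split2.t) == ("SE", "NE", "T3")

    def test_scenario5_no_west_split(self):
        s5 = mink_scenarios()[4]
        first = s5.events[0]
        # FR and SP are effectively one western deme: split at 1 generation
        assert isinstance(first, Split) and first.t == "1"

    def test_all_collapse_to_single_ancestor(self):
        for s in mink_scenarios():
            s._validate_collapse()  # raises on malformed schedules


class TestPriors:
    def test_uniform_mean(self):
        rng = np.random.default_rng(0)
        pr = Prior("uniform", 100, 10000)
        draws = np.array([pr.draw(rng) for _ in range(200000)])
        assert abs(draws.mean() - 5050) / 5050 < 0.01

    def test_order_constraints_enforced(self):
        spec = default_priors()
        rng = np.random.default_rng(1)
        s2 = mink_scenarios()[1]
        for _ in range(200):
            d = sample_priors(s2, spec, rng)
            assert d["T1"] <= d["T2"] <= d["T3"]

    def test_deterministic_draws(self):
        spec = default_priors()
        s1 = mink_scenarios()[0]
        d1 = [sample_priors(s1, spec, np.random.default_rng(42)) for _ in range(1)]
        d2 = [sample_priors(s1, spec, np.random.default_rng(42)) for _ in range(1)]
        assert d1 == d2

    def test_missing_prior_raises(self):
        spec = PriorSpec(priors={"N_NE": Prior("uniform", 10, 20)})
        with pytest.raises(ValueError):
            sample_priors(mink_scenarios()[0], spec, np.random.default_rng(0))


class TestNeutralExpectations:
    def test_single_sequence_no_variation(self):
        ds = simulate_coalescent(
            ONE_POP, {"N_NE": 1000.0}, seq_sample(1), MutationModel(), rng=0
        )
        assert segregating_sites(ds.alignment) == 0

    def test_watterson_small(self):
        # quick version (n=10, 400 reps); the full calibration lives in the
        # acceptance suite
        n, N, L = 10, 1000.0, 1000
        mut = MutationModel(mtdna_rate=1e-5)
        theta = 2 * (N / 2) * mut.mtdna_rate * L  # per-locus theta for mtDNA
        expect = theta * sum(1.0 / i for i in range(1, n))
        rng = np.random.default_rng(7)
        S = [
            segregating_sites(
                simulate_coalescent(
                    ONE_POP, {"N_NE": N}, seq_sample(n, L), mut, rng=rng
                ).alignment
            )
            for _ in range(400)
        ]
        se = np.std(S, ddof=1) / np.sqrt(len(S))
        assert abs(np.mean(S) - expect) < 3 * se

    def test_site_frequency_spectrum(self):
        # aggregated derived-allele counts follow E[xi_i] ~ 1/i
        from minkpop._kernels import sim_mtdna

        n, N, L = 10, 1000.0, 2000
        mut = MutationModel(mtdna_rate=2e-5)
        rng = np.random.default_rng(11)
        sfs = np.zeros(n - 1)
        lin = np.zeros(n, np.int64)
        sizes = np.array([N / 2])
        empty_f = np.zeros(0)
        empty_i = np.zeros(0, np.int64)
        for _ in range(2000):
            states, _ = sim_mtdna(
                int(rng.integers(2**31 - 1)), lin, sizes, empty_f, empty_i,
                empty_i, empty_i, empty_i, empty_f, mut.mtdna_rate, L,
            )
            if states.shape[1]:
                # one random mutation per replicate keeps the counts i.i.d.
                # (mutations within a replicate share a genealogy)
                d = states.sum(axis=0)
                c = int(rng.choice(d))
                if 1 <= c <= n - 1:
                    sfs[c - 1] += 1
        expected = (1.0 / np.arange(1, n)) / (1.0 / np.arange(1, n)).sum()
        chi2, p = sps.chisquare(sfs, expected * sfs.sum())
        assert p > 0.01

    def test_admixture_r1_equals_pure_split(self):
        # r = 1 sends every lineage to source_a: statistically a plain split
        sample = seq_sample(12, 800)
        mut = MutationModel(mtdna_rate=2e-5)
        admix = DemographicScenario(
            name="admix", populations=["NE", "FR"],
            events=[Admixture("500", "FR", "NE", "NE", "r")],
        )
        split = DemographicScenario(
            name="split", populations=["NE", "FR"],
            events=[Split("500", "FR", "NE")],
        )
        sample2 = SampleConfig(
            genotypes={}, sequences={"NE": 6, "FR": 6}, seq_length=800
        )
        params = {"N_NE": 800.0, "N_FR": 800.0, "r": 1.0}
        rng = np.random.default_rng(3)
        Sa = [
            segregating_sites(
                simulate_coalescent(admix, params, sample2, mut, rng=rng).alignment
            )
            for _ in range(300)
        ]
        Sb = [
            segregating_sites(
                simulate_coalescent(split, params, sample2, mut, rng=rng).alignment
            )
            for _ in range(300)
        ]
        se = np.sqrt(np.var(Sa, ddof=1) / 300 + np.var(Sb, ddof=1) / 300)
        assert abs(np.mean(Sa) - np.mean(Sb)) < 3 * se


class TestMsprimeCrossCheck:
    def test_two_population_split_mean_s(self):
        """Mean segregating sites of a two-deme split history agrees with an
        independent coalescent simulator within Monte-Carlo error."""
        msprime = pytest.importorskip("msprime")
        N, T, L, n_per = 1000.0, 800.0, 1000, 8
        mut = MutationModel(mtdna_rate=2e-5)
        scen = DemographicScenario(
            name="split", populations=["NE", "FR"],
            events=[Split(str(T), "FR", "NE")],
        )
        sample = SampleConfig(
            genotypes={}, sequences={"NE": n_per, "FR": n_per}, seq_length=L
        )
        rng = np.random.default_rng(5)
        mine = [
            segregating_sites(
                simulate_coalescent(
                    scen, {"N_NE": N, "N_FR": N}, sample, mut, rng=rng
                ).alignment
            )
            for _ in range(300)
        ]
        dem = msprime.Demography()
        dem.add_population(name="NE", initial_size=N / 2)
        dem.add_population(name="FR", initial_size=N / 2)
        dem.add_population(name="ANC", initial_size=N / 2)
        dem.add_population_split(time=T, derived=["FR"], ancestral="ANC")
        # keep NE as its own deme until T as well, then merge into ANC
        dem.add_population_split(time=T, derived=["NE"], ancestral="ANC")
        theirs = []
        for k, ts in enumerate(
            msprime.sim_ancestry(
                samples={"NE": n_per, "FR": n_per}, demography=dem, ploidy=1,
                sequence_length=L, num_replicates=300, random_seed=12345,
            )
        ):
            mts = msprime.sim_mutations(
                ts, rate=mut.mtdna_rate, random_seed=k + 1,
                discrete_genome=False,  # effectively infinite sites
            )
            theirs.append(mts.num_sites)
        theirs = np.array(theirs)
        mine = np.array(mine)
        se = np.sqrt(mine.var(ddof=1) / len(mine) + theirs.var(ddof=1) / len(theirs))
        assert abs(mine.mean() - theirs.mean()) < 3 * se


class TestMinkLike:
    def test_totals(self, mink_dataset):
        assert mink_dataset.genotypes.n == 313
        assert len(mink_dataset.alignment.ids) == 157

    def test_regional_sizes(self, mink_dataset):
        g = mink_dataset.genotypes
        sizes = {p: sum(1 for i in g.individuals if g.pop_of[i] == p)
                 for p in g.populations}
        assert sizes == {"NE": 107, "SE": 44, "FR": 73, "SP": 89}

    def test_determinism(self):
        a = generate_mink_like(3, seed=5)
        b = generate_mink_like(3, seed=5)
        assert np.array_equal(a.genotypes.alleles, b.genotypes.alleles)
        assert a.alignment.seqs == b.alignment.seqs
        assert a.params == b.params

    def test_ground_truth_recorded(self, mink_dataset):
        assert mink_dataset.scenario == "scenario_2"
        assert "T2" in mink_dataset.params

    def test_haplotype_collapse_consistent(self, mink_dataset):
        t = collapse_haplotypes(mink_dataset.alignment)
        assert t.n == 157 and len(t.haplotypes) >= 1
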