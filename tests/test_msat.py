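"""Microsatellite summaries, exact tests and null-allele EM."""

import itertools
import math
from collections import Counter

import numpy as np
from scipy import stats as sps

from minkpop.datamodel import GenotypeMatrix
from minkpop.msat import (
    bonferroni,
    f_is,
    hwe_test,
    ld_test,
    null_allele_em,
    summarize_msat,
)

from conftest import make_genotypes


class TestSummaries:
    def test_monomorphic_locus(self):
        g = make_genotypes({"A": [[(7, 7)], [(7, 7)], [(7, 7)]]})
        row = summarize_msat(g)[1]
        assert row.ho == 0.0 and row.he == 0.0 and row.allelic_diversity == 1.0

    def test_unbiased_he_hand_value(self):
        g = make_genotypes({"A": [[(1, 2)], [(1, 2)]]})
        row = summarize_msat(g)[1]
        assert row.ho == 1.0
        assert abs(row.he - (4.0 / 3.0) * 0.5) < 1e-12

    def test_private_alleles(self, toy_genotypes):
        rows = {r.label: r for r in summarize_msat(toy_genotypes)}
        # pop A alleles: {10,12,14} x {20,22}; pop B: {14,16} x {24,26}
        # private to A: 10,12 at L0; 20,22 at L1 -> 4
        assert rows["A"].private_alleles == 4
        assert rows["B"].private_alleles == 3  # 16; 24,26

    def test_he_invariant_to_relabeling(self, toy_genotypes):
        g2 = GenotypeMatrix(
            toy_genotypes.individuals,
            toy_genotypes.loci,
            np.where(
                toy_genotypes.alleles > 0,
                toy_genotypes.alleles + 100,
                toy_genotypes.alleles,
            ),
            toy_genotypes.pop_of,
        )
        a = summarize_msat(toy_genotypes)[0]
        b = summarize_msat(g2)[0]
        assert abs(a.he - b.he) < 1e-12 and abs(a.ho - b.ho) < 1e-12


class TestFis:
    def test_hw_proportions_near_zero(self):
        # exact Hardy-Weinberg genotype proportions at p = 0.5
        genos = (
            [[(10, 10)]] * 200 + [[(10, 12)]] * 400 + [[(12, 12)]] * 200
        )
        g = make_genotypes({"A": genos})
        assert abs(f_is(g, "A")) < 0.02

    def test_all_homozygotes_is_one(self):
        g = make_genotypes({"A": [[(10, 10)]] * 5 + [[(12, 12)]] * 5})
        assert abs(f_is(g, "A") - 1.0) < 1e-12

    def test_indicator_anova_oracle(self):
        """Multi-allele 10-individual table equals the variance-component
        estimate computed from the classic one-population indicator ANOVA:
        f = (MSA - MSW) / (MSA + MSW) summed over alleles and loci."""
        rng = np.random.default_rng(42)
        genos = [
            [tuple(rng.choice([10, 12, 14], size=2)) for _ in range(3)]
            for _ in range(10)
        ]
        g = make_genotypes({"A": [list(map(tuple, row)) for row in genos]})
        num = den = 0.0
        for l in range(3):
            pairs = np.array([list(genos[i][l]) for i in range(10)], float)
            n = len(pairs)
            for allele in np.unique(pairs):
                x = (pairs == allele).astype(float)  # indicator per copy
                xb = x.mean(axis=1)
                p = x.mean()
                if p in (0.0, 1.0):
                    continue
                msw = float(((x[:, 0] - x[:, 1]) ** 2 / 2.0).sum()) / n
                msa = float((2 * (xb - p) ** 2).sum()) / (n - 1)
                num += msa - msw
                den += msa + msw
        oracle = num / den
        assert abs(f_is(g, "A") - oracle) < 1e-9

    def test_monomorphic_undefined(self):
        g = make_genotypes({"A": [[(9, 9)], [(9, 9)], [(9, 9)]]})
        assert math.isnan(f_is(g, "A"))


def _enumerate_hwe_p(pairs: np.ndarray) -> float:
    """Exact probability-ordering HWE p by full enumeration of allele
    pairings (oracle for tiny samples)."""
    copies = tuple(sorted(pairs.ravel().tolist()))
    n = len(copies) // 2

    def table_key(perm):
        gens = tuple(sorted(tuple(sorted(perm[2 * i: 2 * i + 2]))
                            for i in range(n)))
        return gens

    def log_prob_stat(perm):
        gens = [tuple(sorted(perm[2 * i: 2 * i + 2])) for i in range(n)]
        het = sum(1 for a, b in gens if a != b)
        cnt = Counter(gens)
        return het * math.log(2) - sum(math.lgamma(c + 1) for c in cnt.values())

    weights: dict[tuple, int] = {}
    stats: dict[tuple, float] = {}
    for perm in set(itertools.permutations(copies)):
        key = table_key(perm)
        weights[key] = weights.get(key, 0) + 1
        stats[key] = log_prob_stat(perm)
    obs_stat = log_prob_stat(tuple(pairs.ravel().tolist()))
    total = sum(weights.values())
    hit = sum(w for k, w in weights.items() if stats[k] <= obs_stat + 1e-12)
    return hit / total


class TestHwe:
    def test_monomorphic_is_one(self):
        g = make_genotypes({"A": [[(5, 5)]] * 6})
        assert hwe_test(g, "A", 0, reps=100, rng=0) == 1.0

    def test_enumeration_oracle(self):
        pairs = np.array([[10, 10], [10, 12], [12, 12], [10, 10]])
        g = make_genotypes({"A": [[tuple(p)] for p in pairs]})
        exact = _enumerate_hwe_p(pairs)
        mc = hwe_test(g, "A", 0, reps=20000, rng=1)
        assert abs(mc - exact) < 0.02

    def test_deterministic(self, toy_genotypes):
        a = hwe_test(toy_genotypes, "A", 0, reps=500, rng=7)
        b = hwe_test(toy_genotypes, "A", 0, reps=500, rng=7)
        assert a == b


class TestLd:
    def test_duplicated_locus_maximal_association(self):
        rng = np.random.default_rng(0)
        genos = []
        for _ in range(40):
            pair = tuple(sorted(rng.choice([10, 12, 14], size=2)))
            genos.append([pair, pair])
        g = make_genotypes({"A": genos})
        reps = 199
        p = ld_test(g, "A", 0, 1, reps=reps, rng=1)
        assert p <= 2.0 / (reps + 1)

    def test_independent_loci_uniform_p(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(150):
            genos = [
                [tuple(sorted(rng.choice([10, 12], size=2))),
                 tuple(sorted(rng.choice([20, 22], size=2)))]
                for _ in range(40)
            ]
            g = make_genotypes({"A": genos})
            pvals.append(ld_test(g, "A", 0, 1, reps=199,
                                 rng=int(rng.integers(2**31 - 1))))
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_monomorphic_is_one(self):
        g = make_genotypes({"A": [[(5, 5), (7, 8)], [(5, 5), (7, 7)],
                                  [(5, 5), (8, 8)]]})
        assert ld_test(g, "A", 0, 1, reps=100, rng=0) == 1.0


def simulate_null_locus(n: int, null_freq: float, seed: int) -> GenotypeMatrix:
    """HWE genotypes at one locus with a non-amplifying allele."""
    rng = np.random.default_rng(seed)
    visible = np.array([10, 12, 14, 16])
    pv = np.array([0.3, 0.3, 0.2, 0.2]) * (1 - null_freq)
    freqs = np.append(pv, null_freq)
    alleles = np.append(visible, -7)  # -7: internal null marker
    genos = []
    for _ in range(n):
        a, b = rng.choice(alleles, size=2, p=freqs)
        if a == -7 and b == -7:
            genos.append([(-1, -1)])  # null homozygote -> missing
        elif a == -7:
            genos.append([(int(b), int(b))])  # apparent homozygote
        elif b == -7:
            genos.append([(int(a), int(a))])
        else:
            genos.append([(int(a), int(b))])
    return make_genotypes({"A": genos})


class TestNullAlleleEM:
    def test_no_nulls_near_zero(self):
        g = simulate_null_locus(400, 0.0, seed=3)
        est = null_allele_em(g, "A", 0)
        assert est.converged and est.frequency < 0.02

    def test_recovers_planted_frequency(self):
        g = simulate_null_locus(200, 0.2, seed=4)
        est = null_allele_em(g, "A", 0)
        assert est.converged
        assert abs(est.frequency - 0.2) <= 0.05

    def test_likelihood_monotone(self):
        g = simulate_null_locus(150, 0.15, seed=5)
        est = null_allele_em(g, "A", 0)
        diffs = np.diff(est.loglik_trace)
        assert (diffs >= -1e-9).all()


class TestBonferroni:
    def test_study_scale_threshold(self):
        thr, _ = bonferroni([0.5] * 275)
        assert round(thr, 6) == 0.000182

    def test_single_test(self):
        thr, flags = bonferroni([0.03], alpha=0.05)
        assert thr == 0.05 and flags == [True]

    def test_arithmetic(self):
        thr, _ = bonferroni([1.0] * 55, alpha=0.055)
        assert abs(thr - 0.001) < 1e-12
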