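"""Fixation indices, AMOVA variance components and the SAMOVA search."""

import itertools
import math

import numpy as np
import pytest

from minkpop.datamodel import HaplotypeAlignment
from minkpop.differentiation import (
    amova,
    f_st_pairwise,
    phi_st_pairwise,
    r_st_pairwise,
    samova,
    sequence_distance_matrix,
    slatkin_rst,
    wc_theta,
)

from conftest import make_genotypes


def aln_from(seqs, pops):
    ids = [f"s{i}" for i in range(len(seqs))]
    return HaplotypeAlignment(ids=ids, seqs=list(seqs),
                              pop_of=dict(zip(ids, pops)))


class TestWcTheta:
    def test_identical_frequencies_near_zero(self):
        # two pops with the same exact genotype composition
        block = [[(10, 10)]] * 25 + [[(10, 12)]] * 50 + [[(12, 12)]] * 25
        g = make_genotypes({"A": block, "B": block})
        assert abs(wc_theta(g)) < 0.02

    def test_alternate_fixation_is_one(self):
        g = make_genotypes({"A": [[(10, 10)]] * 8, "B": [[(20, 20)]] * 8})
        assert abs(wc_theta(g) - 1.0) < 1e-12

    def test_indicator_anova_oracle(self):
        """theta from the closed-form matches the nested indicator ANOVA
        (pops / individuals / copies) with unequal sample sizes, to 1e-9."""
        rng = np.random.default_rng(8)
        ga = [
            [tuple(rng.choice([10, 12, 14], size=2, p=[0.6, 0.3, 0.1]))]
            for _ in range(10)
        ]
        gb = [
            [tuple(rng.choice([10, 12, 14], size=2, p=[0.2, 0.2, 0.6]))]
            for _ in range(7)
        ]
        g = make_genotypes({"A": ga, "B": gb})
        pairs = {"A": np.array([x[0] for x in ga], float),
                 "B": np.array([x[0] for x in gb], float)}
        suma = sumabc = 0.0
        ns = np.array([10.0, 7.0])
        r = 2.0
        nbar = ns.mean()
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        for allele in (10, 12, 14):
            x = {k: (v == allele).astype(float) for k, v in pairs.items()}
            # nested ANOVA mean squares
            ptot = np.concatenate([x["A"].ravel(), x["B"].ravel()]).mean()
            msg = sum(((xi[:, 0] - xi[:, 1]) ** 2 / 2.0).sum()
                      for xi in x.values()) / ns.sum()
            pbar_i = {k: v.mean(axis=1) for k, v in x.items()}
            pk = {k: v.mean() for k, v in x.items()}
            ssi = sum(
                (2.0 * (pbar_i[k] - pk[k]) ** 2).sum() for k in x
            )
            msi = ssi / (ns.sum() - r)
            ssp = sum(ns[j] * 2.0 * (pk[k] - (ns * [pk["A"], pk["B"]]).sum()
                                     / ns.sum()) ** 2
                      for j, k in enumerate(["A", "B"]))
            msp = ssp / (r - 1)
            a = (msp - msi) / (2.0 * nc)
            b = (msi - msg) / 2.0
            c = msg
            suma += a
            sumabc += a + b + c
        oracle = suma / sumabc
        assert abs(wc_theta(g) - oracle) < 1e-9

    def test_pairwise_matrix_symmetric(self, mink_dataset):
        pm = f_st_pairwise(mink_dataset.genotypes, permutations=30, rng=0)
        v = pm.values
        assert np.allclose(v, v.T, equal_nan=True)
        off = v[~np.isnan(v)]
        assert ((pm.pvalues[~np.isnan(pm.pvalues)] >= 1.0 / 31.0)).all()


class TestRst:
    def test_same_distribution_near_zero(self):
        block = [[(10, 14)]] * 20 + [[(12, 12)]] * 20
        g = make_genotypes({"A": block, "B": block})
        assert abs(slatkin_rst(g)) < 0.02

    def test_fixed_size_difference_is_one(self):
        g = make_genotypes({"A": [[(10, 10)]] * 10, "B": [[(20, 20)]] * 10})
        assert abs(slatkin_rst(g) - 1.0) < 1e-12

    def test_brute_force_pair_oracle(self):
        rng = np.random.default_rng(1)
        ga = [[tuple(rng.integers(8, 20, 2))] for _ in range(9)]
        gb = [[tuple(rng.integers(12, 25, 2))] for _ in range(6)]
        g = make_genotypes({"A": ga, "B": gb})
        xa = np.array([x[0] for x in ga], float).ravel()
        xb = np.array([x[0] for x in gb], float).ravel()
        allv = np.concatenate([xa, xb])

        def msd(v):
            return np.mean([(p - q) ** 2 for p, q in
                            itertools.combinations(v, 2)]) if len(v) > 1 else 0.0

        # mean squared difference over unordered pairs
        sbar = msd(allv)
        sw = 0.5 * (msd(xa) + msd(xb))
        oracle = (sbar - sw) / sbar
        assert abs(slatkin_rst(g) - oracle) < 1e-9

    def test_pairwise_runs(self, toy_genotypes):
        pm = r_st_pairwise(toy_genotypes, permutations=30, rng=0)
        assert pm.values.shape == (2, 2)


class TestPhiSt:
    def test_complete_sorting_is_one(self):
        seqs = ["AAAAA"] * 4 + ["TTTTT"] * 4
        pops = ["A"] * 4 + ["B"] * 4
        pm = phi_st_pairwise(aln_from(seqs, pops), permutations=30, rng=0)
        assert abs(pm.value("A", "B") - 1.0) < 1e-12

    def test_brute_force_ssd_oracle(self):
        seqs = ["AATT", "AATA", "TATA", "AACA", "TACA", "AATT"]
        pops = ["A", "A", "A", "B", "B", "B"]
        aln = aln_from(seqs, pops)
        pm = phi_st_pairwise(aln, permutations=0, rng=0)
        # brute-force two-level AMOVA on hand-computed distances
        d2 = np.array([[sum(a != b for a, b in zip(s, t)) for t in seqs]
                       for s in seqs], float)
        N, P = 6, 2
        ssd_t = d2.sum() / (2 * N)
        in_a, in_b = [0, 1, 2], [3, 4, 5]
        ssd_w = (d2[np.ix_(in_a, in_a)].sum() / (2 * 3)
                 + d2[np.ix_(in_b, in_b)].sum() / (2 * 3))
        ms_a = (ssd_t - ssd_w) / (P - 1)
        sigma_w = ssd_w / (N - P)
        n0 = (N - (9 + 9) / N) / (P - 1)
        sigma_a = (ms_a - sigma_w) / n0
        oracle = sigma_a / (sigma_a + sigma_w)
        assert abs(pm.value("A", "B") - oracle) < 1e-9

    def test_null_panmixia_phi_near_zero(self, mink_dataset):
        # split one simulated population in half arbitrarily: no structure
        aln = mink_dataset.alignment
        ids = [i for i in aln.ids if aln.pop_of[i] == "NE"]
        half = len(ids) // 2
        sub = aln.subset(ids)
        sub.pop_of = {
            i: ("X" if k < half else "Y") for k, i in enumerate(ids)
        }
        pm = phi_st_pairwise(sub, permutations=99, rng=4)
        assert pm.value("X", "Y") < 0.1
        assert pm.pvalues[0, 1] > 0.05


class TestAmova:
    def test_all_identical_flagged(self):
        seqs = ["ACGT"] * 9
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        d2 = sequence_distance_matrix(aln_from(seqs, labels))
        res = amova(d2, labels, {"A": "g1", "B": "g1", "C": "g2"},
                    permutations=0)
        assert res.sigma_c == 0.0 and math.isnan(res.phi_st)

    def test_one_pop_per_group_collapses(self, mink_dataset):
        aln = mink_dataset.alignment
        d2 = sequence_distance_matrix(aln)
        labels = [aln.pop_of[i] for i in aln.ids]
        nested = amova(d2, labels, {u: u for u in set(labels)},
                       permutations=0)
        flat = amova(d2, labels, None, permutations=0)
        assert abs(nested.phi_ct - flat.phi_st) < 1e-9

    def test_nested_scalar_anova_oracle(self):
        """AMOVA on squared scalar differences reproduces textbook nested
        random-effects ANOVA variance components."""
        rng = np.random.default_rng(3)
        data, labels, groups = [], [], {}
        layout = {"p1": ("g1", 5), "p2": ("g1", 7), "p3": ("g2", 4),
                  "p4": ("g2", 6)}
        shift = {"p1": 0.0, "p2": 1.0, "p3": 4.0, "p4": 6.0}
        for pop, (grp, size) in layout.items():
            groups[pop] = grp
            for _ in range(size):
                data.append(shift[pop] + rng.normal())
                labels.append(pop)
        x = np.array(data)
        d2 = (x[:, None] - x[None, :]) ** 2
        res = amova(d2, labels, groups, permutations=0)
        # independent nested ANOVA from group/pop means and sums of squares
        pops = list(layout)
        n_p = np.array([layout[p][1] for p in pops], float)
        N = n_p.sum()
        grand = x.mean()
        mean_p = {p: x[[i for i, l in enumerate(labels) if l == p]].mean()
                  for p in pops}
        by_group = {"g1": ["p1", "p2"], "g2": ["p3", "p4"]}
        N_g = {g: sum(layout[p][1] for p in ps) for g, ps in by_group.items()}
        mean_g = {
            g: sum(layout[p][1] * mean_p[p] for p in ps) / N_g[g]
            for g, ps in by_group.items()
        }
        ss_within = sum(
            ((x[[i for i, l in enumerate(labels) if l == p]] - mean_p[p]) ** 2).sum()
            for p in pops
        )
        ss_pop = sum(
            layout[p][1] * (mean_p[p] - mean_g[groups[p]]) ** 2 for p in pops
        )
        weighted_grand = sum(N_g[h] * mean_g[h] for h in N_g) / N
        ss_group = sum(
            N_g[g] * (mean_g[g] - weighted_grand) ** 2 for g in N_g
        )
        df_a, df_b, df_c = 1, 2, int(N - 4)
        sigma_c = ss_within / df_c
        sum_np2_over_ng = sum(
            sum(layout[p][1] ** 2 for p in ps) / N_g[g]
            for g, ps in by_group.items()
        )
        n1 = (N - sum_np2_over_ng) / df_b
        sigma_b = (ss_pop / df_b - sigma_c) / n1
        n2 = (sum_np2_over_ng - (n_p**2).sum() / N) / df_a
        n3 = (N - sum(v**2 for v in N_g.values()) / N) / df_a
        sigma_a = (ss_group / df_a - sigma_c - n2 * sigma_b) / n3
        assert abs(res.sigma_c - sigma_c) < 1e-9
        assert abs(res.sigma_b - sigma_b) < 1e-9
        assert abs(res.sigma_a - sigma_a) < 1e-9

    def test_permutation_pvalues_in_range(self, mink_dataset):
        aln = mink_dataset.alignment
        d2 = sequence_distance_matrix(aln)
        labels = [aln.pop_of[i] for i in aln.ids]
        res = amova(d2, labels, {"NE": "E", "SE": "E", "FR": "W", "SP": "W"},
                    permutations=99, rng=0)
        for p in (res.p_st, res.p_sc, res.p_ct):
            assert 0.0 < p <= 1.0


def planted_two_cluster_alignment(n_units=6, per_unit=6, divergence=20, L=60,
                                  seed=0):
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=L)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    other = base.copy()
    for site in rng.choice(L, size=divergence, replace=False):
        other[site] = flip[other[site]]
    seqs, pops = [], []
    coords = {}
    for u in range(n_units):
        hap = base if u < n_units // 2 else other
        lat = 40.0 + 2 * u + (0 if u < n_units // 2 else 10)
        coords[f"u{u}"] = (lat, 0.0 + u)
        for k in range(per_unit):
            s = hap.copy()
            site = rng.integers(L)
            s[site] = flip[s[site]]  # private noise mutation
            seqs.append("".join(s))
            pops.append(f"u{u}")
    return aln_from(seqs, pops), coords


class TestSamova:
    def test_k_equals_npops_matches_population_level(self, mink_dataset):
        aln = mink_dataset.alignment
        d2 = sequence_distance_matrix(aln)
        labels = [aln.pop_of[i] for i in aln.ids]
        units = list(dict.fromkeys(labels))
        coords = {"NE": (58, 38), "SE": (45, 29), "FR": (45, 0),
                  "SP": (43, -3)}
        res = samova(d2, labels, coords, k=len(units), steps=5, restarts=1,
                     permutations=0, rng=0)
        flat = amova(d2, labels, None, permutations=0)
        assert abs(res.f_ct - flat.phi_st) < 1e-9

    def test_recovers_planted_partition(self):
        aln, coords = planted_two_cluster_alignment(seed=2)
        d2 = sequence_distance_matrix(aln)
        labels = [aln.pop_of[i] for i in aln.ids]
        res = samova(d2, labels, coords, k=2, steps=60, restarts=3,
                     permutations=49, rng=1)
        g = res.assignment
        left = {u for u, gi in g.items() if gi == g["u0"]}
        assert left in ({"u0", "u1", "u2"}, {"u3", "u4", "u5"})
        assert res.f_ct > 0.8

    def test_trace_monotone(self):
        aln, coords = planted_two_cluster_alignment(seed=3)
        d2 = sequence_distance_matrix(aln)
        labels = [aln.pop_of[i] for i in aln.ids]
        res = samova(d2, labels, coords, k=2, steps=40, restarts=2,
                     permutations=0, rng=5)
        assert all(b >= a - 1e-12 for a, b in zip(res.trace, res.trace[1:]))

    def test_k_too_large_raises(self):
        aln, coords = planted_two_cluster_alignment(seed=4)
        d2 = sequence_distance_matrix(aln)
        labels = [aln.pop_of[i] for i in aln.ids]
        with pytest.raises(ValueError):
            samova(d2, labels, coords, k=7, rng=0)
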