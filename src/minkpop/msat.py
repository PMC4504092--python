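"""Per-population microsatellite summaries, HWE/LD testing, null-allele EM.

Summaries follow the conventions of the classic desktop tools: allele counts
and private alleles relative to the full dataset, allelic diversity as the
plain mean number of alleles per locus, Nei's unbiased expected
heterozygosity, and the Weir-Cockerham within-population inbreeding
coefficient f (F_IS).  Hardy-Weinberg and linkage-disequilibrium tests are
Monte-Carlo exact tests; null-allele frequencies are estimated with the
Dempster EM algorithm, optionally treating observed missing genotypes as
candidate null homozygotes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING, GenotypeMatrix

__all__ = [
    "MsatSummaryRow",
    "NullAlleleEstimate",
    "allele_frequencies",
    "summarize_msat",
    "f_is",
    "hwe_test",
    "ld_test",
    "null_allele_em",
    "bonferroni",
]


def _pop_rows(g: GenotypeMatrix, population: str | None) -> np.ndarray:
    if population is None:
        return np.arange(g.n)
    rows = np.array(
        [k for k, i in enumerate(g.individuals) if g.pop_of[i] == population]
    )
    if len(rows) == 0:
        raise ValueError(f"unknown or empty population {population!r}")
    return rows


def allele_frequencies(
    g: GenotypeMatrix, population: str | None = None, locus: int | str = 0
) -> dict[int, float]:
    """Allele relative frequencies at one locus (missing excluded)."""
    l = g.loci.index(locus) if isinstance(locus, str) else locus
    rows = _pop_rows(g, population)
    a = g.alleles[rows, l, :].ravel()
    a = a[a != MISSING]
    if len(a) == 0:
        return {}
    vals, counts = np.unique(a, return_counts=True)
    return {int(v): float(c) / len(a) for v, c in zip(vals, counts)}


@dataclass
class MsatSummaryRow:
    """One row of a per-population variability table."""

    label: str
    n: int
    n_alleles: int
    private_alleles: int
    private_pct: float
    allelic_diversity: float  # mean alleles per locus
    ho: float
    ho_sd: float
    he: float
    he_sd: float
    f_is: float


def _per_locus_stats(g: GenotypeMatrix, rows: np.ndarray):
    """Per-locus (allele set, Ho, unbiased He) over the given individuals."""
    allele_sets, ho, he = [], [], []
    for l in range(g.n_loci):
        pair = g.alleles[rows, l, :]
        typed = pair[:, 0] != MISSING
        pair = pair[typed]
        if len(pair) == 0:
            allele_sets.append(set())
            ho.append(math.nan)
            he.append(math.nan)
            continue
        allele_sets.append(set(pair.ravel().tolist()))
        ho.append(float((pair[:, 0] != pair[:, 1]).mean()))
        ncop = 2.0 * len(pair)
        _, counts = np.unique(pair.ravel(), return_counts=True)
        sp2 = float(((counts / ncop) ** 2).sum())
        he.append(
            (ncop / (ncop - 1.0)) * (1.0 - sp2) if ncop > 2 else math.nan
        )
    return allele_sets, np.array(ho), np.array(he)


def summarize_msat(g: GenotypeMatrix, min_n: int = 2) -> list[MsatSummaryRow]:
    """Variability table: one 'all' row plus one row per population.

    Private alleles are counted relative to the full dataset; populations
    with fewer than ``min_n`` individuals are reported with NaN statistics.
    """
    global_sets, _, _ = _per_locus_stats(g, np.arange(g.n))
    pop_sets: dict[str, list[set]] = {}
    for p in g.populations:
        pop_sets[p], _, _ = _per_locus_stats(g, _pop_rows(g, p))

    def make_row(label: str, rows: np.ndarray, private: int) -> MsatSummaryRow:
        sets, ho, he = _per_locus_stats(g, rows)
        na = sum(len(s) for s in sets)
        okh = ~np.isnan(ho)
        oke = ~np.isnan(he)
        return MsatSummaryRow(
            label=label, n=len(rows), n_alleles=na, private_alleles=private,
            private_pct=100.0 * private / na if na else math.nan,
            allelic_diversity=na / g.n_loci,
            ho=float(ho[okh].mean()) if okh.any() else math.nan,
            ho_sd=float(ho[okh].std(ddof=1)) if okh.sum() > 1 else math.nan,
            he=float(he[oke].mean()) if oke.any() else math.nan,
            he_sd=float(he[oke].std(ddof=1)) if oke.sum() > 1 else math.nan,
            f_is=f_is(g, None if label == "all" else label),
        )

    rows_out = [make_row("all", np.arange(g.n), 0)]
    for p in g.populations:
        rows = _pop_rows(g, p)
        priv = 0
        for l in range(g.n_loci):
            others = set().union(
                *(pop_sets[q][l] for q in g.populations if q != p)
            ) if len(g.populations) > 1 else set()
            priv += len(pop_sets[p][l] - others)
        if len(rows) < min_n:
            rows_out.append(
                MsatSummaryRow(p, len(rows), 0, priv, math.nan, math.nan,
                               math.nan, math.nan, math.nan, math.nan, math.nan)
            )
        else:
            rows_out.append(make_row(p, rows, priv))
    return rows_out


def f_is(g: GenotypeMatrix, population: str | None = None) -> float:
    """Weir-Cockerham within-population inbreeding coefficient f, multi-locus.

    f = 1 - sum(c) / sum(b + c) over loci and alleles, with the single-sample
    variance components b (among individuals) and c (within individuals).
    NaN when every locus is monomorphic.
    """
    rows = _pop_rows(g, population)
    sum_c = 0.0
    sum_bc = 0.0
    any_poly = False
    for l in range(g.n_loci):
        pair = g.alleles[rows, l, :]
        pair = pair[pair[:, 0] != MISSING]
        n = len(pair)
        if n < 2:
            continue
        vals, counts = np.unique(pair.ravel(), return_counts=True)
        if len(vals) < 2:
            continue
        any_poly = True
        for v, cnt in zip(vals, counts):
            p = cnt / (2.0 * n)
            h = float(((pair[:, 0] != pair[:, 1]) & ((pair == v).any(axis=1))).mean())
            b = (n / (n - 1.0)) * (
                p * (1.0 - p) - (2.0 * n - 1.0) / (4.0 * n) * h
            )
            c = 0.5 * h
            sum_c += c
            sum_bc += b + c
    if not any_poly or sum_bc == 0.0:
        return math.nan
    return 1.0 - sum_c / sum_bc


# -- exact tests -------------------------------------------------------------

def _genotype_log_prob_stat(pairs: np.ndarray) -> float:
    """log of the (conditional) genotype-array probability, up to terms fixed
    by the allele counts: h*log 2 - sum log(n_uv!)."""
    het = int((pairs[:, 0] != pairs[:, 1]).sum())
    cnt = Counter(map(tuple, np.sort(pairs, axis=1)))
    return het * math.log(2.0) - sum(math.lgamma(c + 1.0) for c in cnt.values())


def hwe_test(
    g: GenotypeMatrix,
    population: str | None,
    locus: int | str,
    reps: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte-Carlo exact Hardy-Weinberg test (probability-ordering criterion).

    Alleles are shuffled into genotypes conditional on the observed allele
    counts; the p-value is the fraction of arrays no more probable than the
    observed one (with the +1 correction).
    """
    l = g.loci.index(locus) if isinstance(locus, str) else locus
    rows = _pop_rows(g, population)
    pairs = g.alleles[rows, l, :]
    pairs = pairs[pairs[:, 0] != MISSING]
    if len(pairs) == 0:
        return math.nan
    if len(np.unique(pairs)) < 2:
        return 1.0
    rng = np.random.default_rng(rng)
    obs = _genotype_log_prob_stat(pairs)
    copies = pairs.ravel().copy()
    hits = 0
    for _ in range(reps):
        rng.shuffle(copies)
        sim = _genotype_log_prob_stat(copies.reshape(-1, 2))
        if sim <= obs + 1e-12:
            hits += 1
    return (hits + 1.0) / (reps + 1.0)


def ld_test(
    g: GenotypeMatrix,
    population: str | None,
    locus_a: int | str,
    locus_b: int | str,
    reps: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation test for genotypic linkage disequilibrium between two loci.

    The statistic is the G (log-likelihood ratio) statistic on the genotype x
    genotype contingency table; one locus's genotypes are permuted among
    individuals.  Monomorphic loci give p = 1.
    """
    la = g.loci.index(locus_a) if isinstance(locus_a, str) else locus_a
    lb = g.loci.index(locus_b) if isinstance(locus_b, str) else locus_b
    rows = _pop_rows(g, population)
    pa = g.alleles[rows, la, :]
    pb = g.alleles[rows, lb, :]
    typed = (pa[:, 0] != MISSING) & (pb[:, 0] != MISSING)
    pa, pb = np.sort(pa[typed], axis=1), np.sort(pb[typed], axis=1)
    if len(pa) == 0:
        return math.nan

    def codes(p):
        _, inv = np.unique(p, axis=0, return_inverse=True)
        return inv

    ca, cb = codes(pa), codes(pb)
    if ca.max() == 0 or cb.max() == 0:
        return 1.0

    def gstat(x, y):
        tab = np.zeros((ca.max() + 1, cb.max() + 1))
        np.add.at(tab, (x, y), 1.0)
        e = tab.sum(1, keepdims=True) * tab.sum(0, keepdims=True) / tab.sum()
        mask = tab > 0
        return 2.0 * float((tab[mask] * np.log(tab[mask] / e[mask])).sum())

    rng = np.random.default_rng(rng)
    obs = gstat(ca, cb)
    perm = cb.copy()
    hits = 0
    for _ in range(reps):
        rng.shuffle(perm)
        if gstat(ca, perm) >= obs - 1e-12:
            hits += 1
    return (hits + 1.0) / (reps + 1.0)


# -- null alleles ------------------------------------------------------------

@dataclass
class NullAlleleEstimate:
    """EM estimate of the null-allele frequency at one locus/population."""

    frequency: float
    iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)


def null_allele_em(
    g: GenotypeMatrix,
    population: str | None,
    locus: int | str,
    tol: float = 1e-8,
    max_iter: int = 10000,
    missing_as_null: bool = True,
) -> NullAlleleEstimate:
    """EM estimation of a null (non-amplifying) allele frequency.

    Apparent homozygotes are mixtures of true homozygotes and
    visible-x-null heterozygotes; with ``missing_as_null`` observed missing
    genotypes are treated as null homozygotes (the FreeNA-style convention).
    The log-likelihood is guaranteed non-decreasing across iterations.
    """
    l = g.loci.index(locus) if isinstance(locus, str) else locus
    rows = _pop_rows(g, population)
    pairs = g.alleles[rows, l, :]
    typed = pairs[:, 0] != MISSING
    n_missing = int((~typed).sum()) if missing_as_null else 0
    pairs = pairs[typed]
    het = pairs[pairs[:, 0] != pairs[:, 1]]
    hom = pairs[pairs[:, 0] == pairs[:, 1]][:, 0]
    alleles = sorted(set(pairs.ravel().tolist()))
    k = len(alleles)
    aidx = {a: i for i, a in enumerate(alleles)}
    hom_counts = np.zeros(k)
    for a in hom:
        hom_counts[aidx[int(a)]] += 1
    het_counts = np.zeros((k, k))
    for a, b in het:
        i, j = sorted((aidx[int(a)], aidx[int(b)]))
        het_counts[i, j] += 1
    N = len(pairs) + n_missing
    if N == 0:
        return NullAlleleEstimate(math.nan, 0, False)

    # init: uniform visible + small null
    p = np.full(k + 1, 1.0 / (k + 1))  # index k = null
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        pv, p0 = p[:k], p[k]
        # log-likelihood of observed classes
        ll = 0.0
        for i in range(k):
            for j in range(i + 1, k):
                if het_counts[i, j]:
                    ll += het_counts[i, j] * math.log(2 * pv[i] * pv[j])
            if hom_counts[i]:
                ll += hom_counts[i] * math.log(pv[i] ** 2 + 2 * pv[i] * p0)
        if n_missing and p0 > 0:
            ll += 2 * n_missing * math.log(p0)
        trace.append(ll)
        # E-step: split apparent homozygotes
        exp_copies = np.zeros(k + 1)
        for i in range(k):
            denom = pv[i] ** 2 + 2 * pv[i] * p0
            w_true = pv[i] ** 2 / denom if denom > 0 else 1.0
            exp_copies[i] += hom_counts[i] * (2 * w_true + (1 - w_true))
            exp_copies[k] += hom_counts[i] * (1 - w_true)
            exp_copies[i] += het_counts[i, :].sum() + het_counts[:, i].sum()
        exp_copies[k] += 2 * n_missing
        new = exp_copies / (2.0 * N)
        delta = float(np.abs(new - p).max())
        p = new
        if delta < tol:
            return NullAlleleEstimate(float(p[k]), it, True, trace)
    return NullAlleleEstimate(float(p[k]), it, False, trace)


def bonferroni(pvalues, alpha: float = 0.05) -> tuple[float, list[bool]]:
    """Bonferroni threshold alpha/m and per-test significance flags."""
    pvals = list(pvalues)
    m = len(pvals)
    if m < 1:
        raise ValueError("need at least one p-value")
    thr = alpha / m
    return thr, [p < thr for p in pvals]
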