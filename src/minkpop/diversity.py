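"""Sequence diversity indices and neutrality tests with simulated significance.

Implements Nei's haplotype diversity, per-site nucleotide diversity, Tajima's
D, Fu's Fs (via the Ewens sampling formula) and the Ramos-Onsins & Rozas R2
statistic.  Significance of the neutrality statistics is obtained by
simulating the constant-size neutral coalescent conditioned on the observed
number of segregating sites (mutations placed uniformly on branch length),
the convention of the classic desktop tools for these tests.

Columns containing ``N`` (or any gap that survived trimming) are excluded
from all site-based computations; ``L`` refers to the retained sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import _kernels
from .datamodel import HaplotypeAlignment, HaplotypeTable, collapse_haplotypes

__all__ = [
    "DiversityResult",
    "NeutralityResult",
    "haplotype_diversity",
    "nucleotide_diversity",
    "segregating_sites",
    "mean_pairwise_differences",
    "tajimas_d",
    "fus_fs",
    "r2_statistic",
    "ewens_khat_tail",
    "simulate_null_statistics",
    "neutrality_test",
    "diversity_summary",
]


# -- internal site machinery -------------------------------------------------

def clean_site_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    """(n, L') byte matrix keeping only columns free of '-' and 'N'."""
    mat = aln.to_matrix()
    keep = ~((mat == b"-") | (mat == b"N")).any(axis=0)
    return mat[:, keep]


@dataclass
class _SiteStats:
    n: int
    L: int
    S: int
    kbar: float  # mean pairwise differences (per sequence pair, not per site)
    U: np.ndarray  # singleton mutations carried by each sequence
    K: int  # number of distinct haplotypes

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "_SiteStats":
        """Compute from an (n, L) matrix of hashable states (bytes or ints)."""
        n, L = mat.shape
        npairs = max(n * (n - 1) / 2.0, 1.0)
        S = 0
        diff_pairs = 0.0
        U = np.zeros(n, dtype=int)
        for c in range(L):
            col = mat[:, c]
            states, counts = np.unique(col, return_counts=True)
            if len(states) > 1:
                S += 1
                diff_pairs += npairs - (counts * (counts - 1) / 2.0).sum()
                for st, ct in zip(states, counts):
                    if ct == 1:
                        U[np.flatnonzero(col == st)[0]] += 1
        K = np.unique(mat, axis=0).shape[0]
        return cls(n=n, L=L, S=S, kbar=diff_pairs / npairs, U=U, K=K)


def _stats(aln: HaplotypeAlignment) -> _SiteStats:
    return _SiteStats.from_matrix(clean_site_matrix(aln))


def segregating_sites(aln: HaplotypeAlignment) -> int:
    return _stats(aln).S


def mean_pairwise_differences(aln: HaplotypeAlignment) -> float:
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    return _stats(aln).kbar


# -- diversity indices -------------------------------------------------------

def haplotype_diversity(counts) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its sampling SD.

    ``counts`` are per-haplotype copy numbers; h = n(1 - sum p_i^2)/(n - 1).
    """
    c = np.asarray(list(counts), dtype=float)
    if (c <= 0).any():
        raise ValueError("haplotype counts must be positive")
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    p = c / n
    sp2 = float((p**2).sum())
    sp3 = float((p**3).sum())
    h = n * (1.0 - sp2) / (n - 1.0)
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (sp3 - sp2**2) + sp2 - sp2**2
    )
    return h, math.sqrt(max(var, 0.0))


def nucleotide_diversity(aln: HaplotypeAlignment) -> tuple[float, float]:
    """Per-site nucleotide diversity pi with its total (sampling +
    evolutionary) SD after Tajima/Nei."""
    if aln.n < 2:
        raise ValueError("nucleotide diversity undefined for n < 2")
    st = _stats(aln)
    n, L = st.n, st.L
    pi = st.kbar / L
    var = ((n + 1.0) / (3.0 * (n - 1.0) * L)) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, math.sqrt(max(var, 0.0))


# -- neutrality statistics ---------------------------------------------------

def _tajima_constants(n: int) -> tuple[float, ...]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def _tajimas_d_from(n: int, S: int, kbar: float) -> float:
    a1, e1, e2 = _tajima_constants(n)
    return (kbar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def tajimas_d(aln: HaplotypeAlignment) -> float:
    """Tajima's D; NaN when there is no segregating site."""
    st = _stats(aln)
    if st.S == 0:
        return math.nan
    return _tajimas_d_from(st.n, st.S, st.kbar)


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned first-kind Stirling numbers)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(n):  # s(m+1,k) = s(m,k-1) + m*s(m,k)
        new = np.full(n + 1, -np.inf)
        if m == 0:
            new[1:] = row[:-1]
        else:
            new[1:] = np.logaddexp(row[:-1], math.log(m) + row[1:])
        new[0] = -np.inf
        row = new
    return row


def ewens_khat_tail(n: int, k_obs: int, theta: float) -> float:
    """P(K >= k_obs) for the number of distinct alleles K under the Ewens
    sampling formula with scaled mutation rate ``theta``.

    Uses P(K=k) proportional to |s(n,k)| theta^k, evaluated in log space.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = _log_stirling_row(n)
    k = np.arange(n + 1)
    logw = ls + k * math.log(theta)
    logw[0] = -np.inf
    m = logw.max()
    w = np.exp(logw - m)
    return float(w[k_obs:].sum() / w.sum())


def _fus_fs_from(n: int, K: int, kbar: float) -> float:
    if K <= 1:
        return math.inf  # S' = P(K >= 1) = 1 exactly
    if kbar <= 0:
        return math.nan
    sprime = ewens_khat_tail(n, K, kbar)
    if sprime >= 1.0:
        return math.inf
    if sprime <= 0.0:
        return -math.inf
    return math.log(sprime / (1.0 - sprime))


def fus_fs(aln: HaplotypeAlignment) -> float:
    """Fu's Fs: ln(S'/(1-S')) with S' = P(K >= K_obs | theta = mean pairwise
    differences).  +inf when only one haplotype is observed (S' = 1)."""
    st = _stats(aln)
    return _fus_fs_from(st.n, st.K, st.kbar)


def _r2_from(n: int, S: int, U: np.ndarray) -> float:
    if S == 0:
        return math.nan
    return math.sqrt(float(((U - S / 2.0) ** 2).mean())) / S


def r2_statistic(aln: HaplotypeAlignment) -> float:
    """Ramos-Onsins & Rozas R2 from per-sequence singleton counts."""
    st = _stats(aln)
    return _r2_from(st.n, st.S, st.U)


# -- simulated significance --------------------------------------------------

def simulate_null_statistics(
    n: int, S: int, reps: int, rng: np.random.Generator | int | None = None
) -> dict[str, np.ndarray]:
    """Replicate (D, Fs, R2) under the fixed-S constant-size coalescent null."""
    rng = np.random.default_rng(rng)
    D = np.empty(reps)
    Fs = np.empty(reps)
    R2 = np.empty(reps)
    for r in range(reps):
        seed = int(rng.integers(0, 2**31 - 1))
        mat = _kernels.sim_fixed_s(seed, n, S)
        st = _SiteStats.from_matrix(mat)
        D[r] = _tajimas_d_from(n, S, st.kbar)
        Fs[r] = _fus_fs_from(n, st.K, st.kbar)
        R2[r] = _r2_from(n, S, st.U)
    return {"D": D, "Fs": Fs, "R2": R2}


def _empirical_p(sim: np.ndarray, obs: float, tail: str) -> float:
    sim = sim[np.isfinite(sim)]
    R = len(sim)
    if R == 0 or not math.isfinite(obs):
        return math.nan
    lo = (np.sum(sim <= obs) + 1.0) / (R + 1.0)
    hi = (np.sum(sim >= obs) + 1.0) / (R + 1.0)
    if tail == "lower":
        return float(lo)
    if tail == "upper":
        return float(hi)
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass
class NeutralityResult:
    """Observed neutrality statistics with simulated p-values."""

    n: int
    S: int
    tajimas_d: float
    fus_fs: float
    r2: float
    p_tajimas_d: float = math.nan
    p_fus_fs: float = math.nan
    p_r2: float = math.nan
    reps: int = 0
    undefined: dict[str, str] = field(default_factory=dict)


def neutrality_test(
    aln: HaplotypeAlignment,
    reps: int = 10000,
    rng: np.random.Generator | int | None = None,
    null_stats: dict[str, np.ndarray] | None = None,
) -> NeutralityResult:
    """All three neutrality statistics plus coalescent-simulated p-values.

    D and R2 are tested two-tailed, Fs one-tailed towards low (negative)
    values.  ``null_stats`` may supply precomputed replicates (e.g. cached by
    (n, S)) to avoid re-simulating.
    """
    if reps < 100:
        import warnings

        warnings.warn("fewer than 100 null replicates give coarse p-values")
    st = _stats(aln)
    res = NeutralityResult(
        n=st.n, S=st.S,
        tajimas_d=_tajimas_d_from(st.n, st.S, st.kbar) if st.S else math.nan,
        fus_fs=_fus_fs_from(st.n, st.K, st.kbar),
        r2=_r2_from(st.n, st.S, st.U),
    )
    if st.S == 0:
        res.undefined["D"] = res.undefined["R2"] = "no segregating sites"
        if st.kbar <= 0:
            res.undefined["Fs"] = "no sequence variation (theta = 0)"
        return res
    sims = null_stats or simulate_null_statistics(st.n, st.S, reps, rng)
    res.reps = len(sims["D"])
    res.p_tajimas_d = _empirical_p(sims["D"], res.tajimas_d, "two")
    res.p_fus_fs = _empirical_p(sims["Fs"], res.fus_fs, "lower")
    res.p_r2 = _empirical_p(sims["R2"], res.r2, "two")
    return res


# -- reporting ---------------------------------------------------------------

@dataclass
class DiversityResult:
    """One row of a diversity report (global or per population)."""

    label: str
    n: int
    n_haplotypes: int
    private_haplotypes: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float


def diversity_summary(
    aln: HaplotypeAlignment, table: HaplotypeTable | None = None
) -> list[DiversityResult]:
    """Per-population and overall diversity rows in the style of a marker
    variability table: N_h with private haplotypes, h +- SD and pi +- SD."""
    table = table or collapse_haplotypes(aln)
    rows = []
    pops = table.populations
    private_pop = {}
    for j, p in enumerate(pops):
        present = table.counts[:, j] > 0
        elsewhere = (table.counts[:, [k for k in range(len(pops)) if k != j]] > 0).any(
            axis=1
        ) if len(pops) > 1 else np.zeros(len(table.haplotypes), bool)
        private_pop[p] = int((present & ~elsewhere).sum())

    def row(label, sub_aln, private):
        t = collapse_haplotypes(sub_aln)
        counts = t.total_counts
        if sub_aln.n >= 2:
            h, hsd = haplotype_diversity(counts)
            pi, pisd = nucleotide_diversity(sub_aln)
        else:
            h = hsd = pi = pisd = math.nan
        return DiversityResult(
            label=label, n=sub_aln.n, n_haplotypes=len(t.haplotypes),
            private_haplotypes=private, h=h, h_sd=hsd, pi=pi, pi_sd=pisd,
        )

    rows.append(row("all", aln, sum(private_pop.values())))
    for p in pops:
        ids = [i for i in aln.ids if aln.pop_of[i] == p]
        if len(ids) >= 2:
            rows.append(row(p, aln.subset(ids), private_pop[p]))
    return rows
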