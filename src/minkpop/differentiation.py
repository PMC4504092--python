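"""Population differentiation: pairwise fixation indices, AMOVA, SAMOVA.

Three flavours of fixation index are provided, matching the marker classes:
Weir-Cockerham theta (F_ST, allele identity), Slatkin's R_ST (allele-size
variance under stepwise mutation) and Phi_ST (AMOVA on sequence distances).
Hierarchical AMOVA decomposes variance among groups / among populations
within groups / within populations, with the three permutation schemes of the
classic implementation.  SAMOVA searches, by simulated annealing over
geographically contiguous partitions, for the grouping of populations that
maximizes the among-group index F_CT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING, GenotypeMatrix, HaplotypeAlignment

__all__ = [
    "PairwiseMatrix",
    "AmovaResult",
    "PartitionResult",
    "sequence_distance_matrix",
    "genotype_distance_matrix",
    "wc_theta",
    "slatkin_rst",
    "phi_st_pairwise",
    "f_st_pairwise",
    "r_st_pairwise",
    "amova",
    "samova",
]


@dataclass
class PairwiseMatrix:
    """Symmetric pairwise statistic over populations with permutation p-values."""

    statistic: str
    populations: list[str]
    values: np.ndarray
    pvalues: np.ndarray
    permutations: int

    def value(self, a: str, b: str) -> float:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.values[i, j])


@dataclass
class AmovaResult:
    """Variance components and fixation indices of a (nested) AMOVA."""

    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    phi_st: float
    phi_sc: float
    phi_ct: float
    p_st: float = math.nan
    p_sc: float = math.nan
    p_ct: float = math.nan
    permutations: int = 0
    df: tuple[int, int, int] = (0, 0, 0)


@dataclass
class PartitionResult:
    """Best grouping found by the SAMOVA annealing search."""

    k: int
    assignment: dict[str, int]
    f_ct: float
    p_value: float
    trace: list[float] = field(default_factory=list)
    amova: AmovaResult | None = None


# -- distances ---------------------------------------------------------------

def sequence_distance_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    """Pairwise number of differing sites (gap/N-free columns only)."""
    from .diversity import clean_site_matrix

    mat = clean_site_matrix(aln).view(np.uint8)
    d = np.zeros((aln.n, aln.n))
    for i in range(aln.n):
        d[i, :] = (mat != mat[i]).sum(axis=1)
    return d


def genotype_distance_matrix(g: GenotypeMatrix, mode: str = "identity") -> np.ndarray:
    """Squared inter-individual distance summed over loci.

    ``identity``: number of non-shared alleles per locus (0, 1 or 2);
    ``size``: squared repeat-count differences under the best pairing of the
    two allele copies.  Loci missing in either individual are skipped.
    """
    if mode not in ("identity", "size"):
        raise ValueError("mode must be 'identity' or 'size'")
    a = np.sort(g.alleles, axis=2).astype(float)
    miss = g.missing_mask()
    n = g.n
    d = np.zeros((n, n))
    for i in range(n):
        ok = ~(miss[i] | miss)  # (n, n_loci)
        ai = a[i]
        if mode == "identity":
            # shared alleles between sorted pairs (ai0,ai1) and (aj0,aj1)
            x0, x1 = ai[:, 0], ai[:, 1]
            y0, y1 = a[..., 0], a[..., 1]
            both = (x0 == y0) & (x1 == y1)
            one = (
                (x0 == y0) | (x0 == y1) | (x1 == y0) | (x1 == y1)
            ) & ~both
            per_locus = np.where(both, 0.0, np.where(one, 1.0, 2.0))
        else:
            s1 = (ai[:, 0] - a[..., 0]) ** 2 + (ai[:, 1] - a[..., 1]) ** 2
            s2 = (ai[:, 0] - a[..., 1]) ** 2 + (ai[:, 1] - a[..., 0]) ** 2
            per_locus = np.minimum(s1, s2)
        d[i, :] = (per_locus * ok).sum(axis=1)
    np.fill_diagonal(d, 0.0)
    return d


# -- AMOVA machinery ---------------------------------------------------------

def _ssd(d2: np.ndarray, mask: np.ndarray) -> float:
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _amova2(d2: np.ndarray, unit: np.ndarray) -> tuple[float, float, float]:
    """Two-level AMOVA: returns (sigma_a, sigma_w, phi_st)."""
    N = len(unit)
    units = np.unique(unit)
    P = len(units)
    ssd_total = _ssd(d2, np.ones(N, bool))
    ssd_wp = sum(_ssd(d2, unit == u) for u in units)
    df_a, df_w = P - 1, N - P
    if df_w <= 0 or df_a <= 0:
        return math.nan, math.nan, math.nan
    sizes = np.array([(unit == u).sum() for u in units], float)
    n0 = (N - (sizes**2).sum() / N) / df_a
    ms_a = (ssd_total - ssd_wp) / df_a
    sigma_w = ssd_wp / df_w
    sigma_a = (ms_a - sigma_w) / n0
    tot = sigma_a + sigma_w
    return sigma_a, sigma_w, (sigma_a / tot if tot != 0 else math.nan)


def _amova3(
    d2: np.ndarray, unit: np.ndarray, group_of_unit: np.ndarray
) -> tuple[float, float, float, tuple[int, int, int]]:
    """Three-level variance components (sigma_a, sigma_b, sigma_c).

    ``unit`` codes populations per individual; ``group_of_unit[u]`` the group
    of population code u.
    """
    N = len(unit)
    group = group_of_unit[unit]
    units = np.unique(unit)
    groups = np.unique(group)
    P, G = len(units), len(groups)
    df = (G - 1, P - G, N - P)
    ssd_total = _ssd(d2, np.ones(N, bool))
    ssd_wp = sum(_ssd(d2, unit == u) for u in units)
    ssd_wg = sum(_ssd(d2, group == g) for g in groups)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg
    n_p = np.array([(unit == u).sum() for u in units], float)
    g_of = group_of_unit[units]
    N_g = np.array([n_p[g_of == g].sum() for g in groups], float)
    sum_np2_over_Ng = sum(
        (n_p[g_of == g] ** 2).sum() / N_g[i] for i, g in enumerate(groups)
    )
    sigma_c = ssd_wp / df[2] if df[2] > 0 else math.nan
    if df[1] > 0:
        n1 = (N - sum_np2_over_Ng) / df[1]
        sigma_b = ((ssd_ap / df[1]) - sigma_c) / n1
    else:
        sigma_b = 0.0
    if df[0] > 0:
        n2 = (sum_np2_over_Ng - (n_p**2).sum() / N) / df[0]
        n3 = (N - (N_g**2).sum() / N) / df[0]
        sigma_a = ((ssd_ag / df[0]) - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c, df


def _indices(sa: float, sb: float, sc: float) -> tuple[float, float, float]:
    tot = sa + sb + sc
    phi_st = (sa + sb) / tot if tot != 0 else math.nan
    phi_ct = sa / tot if tot != 0 else math.nan
    phi_sc = sb / (sb + sc) if (sb + sc) != 0 else math.nan
    return phi_st, phi_sc, phi_ct


def amova(
    d2: np.ndarray,
    unit_labels: list[str],
    group_of_unit: dict[str, str] | None = None,
    permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on a squared-distance matrix.

    ``unit_labels`` gives each individual's population; ``group_of_unit`` maps
    population -> group (one group per population collapses the among-group
    level onto the population level).  Permutation schemes: Phi_ST permutes
    individuals among all populations, Phi_SC individuals among populations
    within groups, Phi_CT whole populations among groups.
    """
    rng = np.random.default_rng(rng)
    units = list(dict.fromkeys(unit_labels))
    ucode = {u: i for i, u in enumerate(units)}
    unit = np.array([ucode[u] for u in unit_labels])
    if group_of_unit is None:
        group_of_unit = {u: "_all" for u in units}
    groups = list(dict.fromkeys(group_of_unit[u] for u in units))
    gcode = {g: i for i, g in enumerate(groups)}
    gofu = np.array([gcode[group_of_unit[u]] for u in units])

    single_group = len(groups) == 1
    if single_group:
        sa, sc, phi_st = _amova2(d2, unit)
        res = AmovaResult(
            sigma_a=0.0, sigma_b=sa, sigma_c=sc,
            phi_st=phi_st, phi_sc=phi_st, phi_ct=math.nan,
            df=(0, len(units) - 1, len(unit) - len(units)),
        )
    else:
        sa, sb, sc, df = _amova3(d2, unit, gofu)
        phi_st, phi_sc, phi_ct = _indices(sa, sb, sc)
        res = AmovaResult(
            sigma_a=sa, sigma_b=sb, sigma_c=sc,
            phi_st=phi_st, phi_sc=phi_sc, phi_ct=phi_ct, df=df,
        )
    if permutations <= 0:
        return res
    res.permutations = permutations

    hit_st = hit_sc = hit_ct = 0
    for _ in range(permutations):
        # ST: individuals among all populations
        perm_unit = rng.permutation(unit)
        if single_group:
            _, _, p_st = _amova2(d2, perm_unit)
        else:
            p_st = _indices(*_amova3(d2, perm_unit, gofu)[:3])[0]
        if not math.isnan(p_st) and p_st >= res.phi_st - 1e-12:
            hit_st += 1
        if not single_group:
            # SC: individuals among populations within their group
            perm_unit2 = unit.copy()
            for g in range(len(groups)):
                sel = np.flatnonzero(gofu[unit] == g)
                perm_unit2[sel] = unit[sel][rng.permutation(len(sel))]
            p_sc = _indices(*_amova3(d2, perm_unit2, gofu)[:3])[1]
            if not math.isnan(p_sc) and p_sc >= res.phi_sc - 1e-12:
                hit_sc += 1
            # CT: whole populations among groups
            perm_g = rng.permutation(gofu)
            p_ct = _indices(*_amova3(d2, unit, perm_g)[:3])[2]
            if not math.isnan(p_ct) and p_ct >= res.phi_ct - 1e-12:
                hit_ct += 1
    res.p_st = (hit_st + 1.0) / (permutations + 1.0)
    if not single_group:
        res.p_sc = (hit_sc + 1.0) / (permutations + 1.0)
        res.p_ct = (hit_ct + 1.0) / (permutations + 1.0)
    return res


# -- fixation indices --------------------------------------------------------

def wc_theta(g: GenotypeMatrix, populations: list[str] | None = None) -> float:
    """Multi-locus Weir-Cockerham theta (F_ST) over the given populations."""
    pops = populations or g.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    rows_by_pop = [
        np.array([k for k, i in enumerate(g.individuals) if g.pop_of[i] == p])
        for p in pops
    ]
    r = float(len(pops))
    suma = sumabc = 0.0
    for l in range(g.n_loci):
        pairs = [g.alleles[rows, l, :] for rows in rows_by_pop]
        pairs = [p_[p_[:, 0] != MISSING] for p_ in pairs]
        ns = np.array([len(p_) for p_ in pairs], float)
        if (ns < 1).any() or ns.sum() < 2:
            continue
        alleles = np.unique(np.concatenate([p_.ravel() for p_ in pairs]))
        if len(alleles) < 2:
            continue
        nbar = ns.mean()
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1.0)
        for v in alleles:
            p_i = np.array([(p_ == v).sum() / (2.0 * n) for p_, n in zip(pairs, ns)])
            h_i = np.array(
                [
                    ((p_[:, 0] != p_[:, 1]) & ((p_ == v).any(axis=1))).sum() / n
                    for p_, n in zip(pairs, ns)
                ]
            )
            pbar = (ns * p_i).sum() / (r * nbar)
            s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1.0) * nbar)
            hbar = (ns * h_i).sum() / (r * nbar)
            if nbar <= 1 or nc <= 0:
                continue
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2.0
            suma += a
            sumabc += a + b + c
    return suma / sumabc if sumabc != 0 else math.nan


def slatkin_rst(g: GenotypeMatrix, populations: list[str] | None = None) -> float:
    """Slatkin's R_ST = (Sbar - Sw)/Sbar from allele-size variance, multi-locus.

    Sbar is the average squared size difference between allele copies drawn
    from the pooled sample, Sw the within-population average; numerators and
    denominators are summed over loci.
    """
    pops = populations or g.populations
    rows_by_pop = [
        np.array([k for k, i in enumerate(g.individuals) if g.pop_of[i] == p])
        for p in pops
    ]
    num = den = 0.0
    for l in range(g.n_loci):
        sizes = [
            g.alleles[rows, l, :][g.alleles[rows, l, 0] != MISSING].ravel().astype(float)
            for rows in rows_by_pop
        ]
        sizes = [s for s in sizes if len(s) >= 2]
        if len(sizes) < 2:
            continue
        allv = np.concatenate(sizes)
        # mean squared difference over pairs = 2 * biased variance * n/(n-1)
        def msd(x):
            n = len(x)
            return 2.0 * x.var(ddof=0) * n / (n - 1.0)

        sbar = msd(allv)
        sw = float(np.mean([msd(s) for s in sizes]))
        num += sbar - sw
        den += sbar
    return num / den if den != 0 else math.nan


def _pairwise(
    labels: list[str],
    stat_fn,
    permute_fn,
    permutations: int,
    rng: np.random.Generator,
    statistic: str,
) -> PairwiseMatrix:
    P = len(labels)
    vals = np.full((P, P), math.nan)
    pvals = np.full((P, P), math.nan)
    for i in range(P):
        for j in range(i + 1, P):
            obs = stat_fn(labels[i], labels[j])
            hits = 0
            for _ in range(permutations):
                if permute_fn(labels[i], labels[j], rng) >= obs - 1e-12:
                    hits += 1
            vals[i, j] = vals[j, i] = obs
            pvals[i, j] = pvals[j, i] = (hits + 1.0) / (permutations + 1.0)
    return PairwiseMatrix(statistic, list(labels), vals, pvals, permutations)


def phi_st_pairwise(
    aln: HaplotypeAlignment,
    permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> PairwiseMatrix:
    """Pairwise Phi_ST (two-population AMOVA on sequence distances) with
    permutation p-values (individuals permuted between the two populations)."""
    rng = np.random.default_rng(rng)
    d2 = sequence_distance_matrix(aln)
    pops = aln.populations
    codes = np.array([pops.index(aln.pop_of[i]) for i in aln.ids])

    def subset(a, b):
        ia, ib = pops.index(a), pops.index(b)
        sel = np.flatnonzero((codes == ia) | (codes == ib))
        return sel, (codes[sel] == ib).astype(int)

    def stat(a, b):
        sel, u = subset(a, b)
        return _amova2(d2[np.ix_(sel, sel)], u)[2]

    def perm(a, b, r):
        sel, u = subset(a, b)
        return _amova2(d2[np.ix_(sel, sel)], r.permutation(u))[2]

    return _pairwise(pops, stat, perm, permutations, rng, "phi_st")


def _genotype_pairwise(
    g: GenotypeMatrix,
    fn,
    statistic: str,
    permutations: int,
    rng: np.random.Generator | int | None,
) -> PairwiseMatrix:
    rng = np.random.default_rng(rng)
    pops = g.populations

    def stat(a, b):
        sub = g.subset([i for i in g.individuals if g.pop_of[i] in (a, b)])
        return fn(sub)

    def perm(a, b, r):
        ids = [i for i in g.individuals if g.pop_of[i] in (a, b)]
        sub = g.subset(ids)
        labels = [sub.pop_of[i] for i in ids]
        shuffled = [labels[k] for k in r.permutation(len(labels))]
        sub.pop_of = dict(zip(ids, shuffled))
        return fn(sub)

    return _pairwise(pops, stat, perm, permutations, rng, statistic)


def f_st_pairwise(
    g: GenotypeMatrix,
    permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> PairwiseMatrix:
    """Pairwise Weir-Cockerham theta with permutation p-values."""
    return _genotype_pairwise(g, wc_theta, "f_st", permutations, rng)


def r_st_pairwise(
    g: GenotypeMatrix,
    permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> PairwiseMatrix:
    """Pairwise Slatkin R_ST with permutation p-values."""
    return _genotype_pairwise(g, slatkin_rst, "r_st", permutations, rng)


# -- SAMOVA ------------------------------------------------------------------

def _great_circle(c1, c2) -> float:
    lat1, lon1, lat2, lon2 = map(math.radians, (*c1, *c2))
    return math.acos(
        min(1.0, max(-1.0,
            math.sin(lat1) * math.sin(lat2)
            + math.cos(lat1) * math.cos(lat2) * math.cos(lon1 - lon2)))
    )


def _knn_graph(units: list[str], coords: dict[str, tuple[float, float]], k: int):
    """Symmetrized k-nearest-neighbour adjacency on great-circle distance."""
    P = len(units)
    adj = [set() for _ in range(P)]
    for i in range(P):
        d = sorted(
            (j for j in range(P) if j != i),
            key=lambda j: _great_circle(coords[units[i]], coords[units[j]]),
        )
        for j in d[: min(k, P - 1)]:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def samova(
    d2: np.ndarray,
    unit_labels: list[str],
    coords: dict[str, tuple[float, float]],
    k: int,
    steps: int = 100,
    restarts: int = 10,
    neighbours: int = 3,
    permutations: int = 199,
    rng: np.random.Generator | int | None = None,
) -> PartitionResult:
    """Simulated-annealing search for the k-group partition maximizing F_CT.

    Candidate moves reassign a population to a group containing one of its
    geographic neighbours (3-nearest-neighbour graph on great-circle
    distances), keeping all k groups non-empty.  The best partition over all
    restarts is returned; significance permutes populations among groups.
    """
    rng = np.random.default_rng(rng)
    units = list(dict.fromkeys(unit_labels))
    P = len(units)
    if not 2 <= k <= P:
        raise ValueError(f"k={k} outside 2..{P}")
    ucode = {u: i for i, u in enumerate(units)}
    unit = np.array([ucode[u] for u in unit_labels])
    adj = _knn_graph(units, coords, neighbours)

    def fct(gofu: np.ndarray) -> float:
        if len(np.unique(gofu)) < 2:
            return -math.inf
        v = _indices(*_amova3(d2, unit, gofu)[:3])[2]
        return v if not math.isnan(v) else -math.inf

    def initial() -> np.ndarray:
        seeds = rng.choice(P, size=k, replace=False)
        gofu = np.full(P, -1)
        for gi, s in enumerate(seeds):
            gofu[s] = gi
        todo = [p for p in range(P) if gofu[p] < 0]
        rng.shuffle(todo)
        while todo:
            progressed = False
            for p in list(todo):
                labelled = [q for q in adj[p] if gofu[q] >= 0]
                if labelled:
                    gofu[p] = gofu[labelled[int(rng.integers(len(labelled)))]]
                    todo.remove(p)
                    progressed = True
            if not progressed:  # disconnected graph: attach arbitrarily
                p = todo.pop()
                gofu[p] = int(rng.integers(k))
        return gofu

    best_g, best_f = None, -math.inf
    trace: list[float] = []
    for _ in range(max(1, restarts)):
        gofu = initial()
        cur_f = fct(gofu)
        loc_best_g, loc_best_f = gofu.copy(), cur_f
        T0 = 0.1
        for s in range(steps):
            T = T0 * (0.95**s)
            p = int(rng.integers(P))
            neigh_groups = {int(gofu[q]) for q in adj[p]} - {int(gofu[p])}
            if not neigh_groups:
                trace.append(max(loc_best_f, best_f))
                continue
            if (gofu == gofu[p]).sum() == 1:  # would empty its group
                trace.append(max(loc_best_f, best_f))
                continue
            new_g = gofu.copy()
            new_g[p] = rng.choice(sorted(neigh_groups))
            new_f = fct(new_g)
            if new_f >= cur_f or rng.random() < math.exp((new_f - cur_f) / max(T, 1e-9)):
                gofu, cur_f = new_g, new_f
                if cur_f > loc_best_f:
                    loc_best_g, loc_best_f = gofu.copy(), cur_f
            trace.append(max(loc_best_f, best_f))
        if loc_best_f > best_f:
            best_g, best_f = loc_best_g, loc_best_f
    # monotone best-so-far trace
    run_max = -math.inf
    mono = []
    for v in trace:
        run_max = max(run_max, v)
        mono.append(run_max)

    # significance: permute populations among groups (CT scheme)
    hits = 0
    for _ in range(permutations):
        perm_g = rng.permutation(best_g)
        v = fct(perm_g)
        if v >= best_f - 1e-12:
            hits += 1
    pval = (hits + 1.0) / (permutations + 1.0)
    group_map = {u: int(best_g[ucode[u]]) for u in units}
    amova_res = amova(
        d2, unit_labels,
        {u: f"g{group_map[u]}" for u in units},
        permutations=0,
    )
    return PartitionResult(
        k=k, assignment=group_map, f_ct=best_f, p_value=pval,
        trace=mono, amova=amova_res,
    )
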