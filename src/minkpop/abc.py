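"""ABC model choice over demographic scenarios.

The likelihood-free workflow: simulate a reference table of (scenario,
parameter draw, summary statistics) rows; retain the small fraction of rows
closest to the observed statistics (Euclidean distance on SD-normalized
statistics); estimate per-scenario posterior probabilities with a
multinomial logistic regression on linear-discriminant projections of the
retained statistics, evaluated at the observation.  Confidence intervals come
from a nonparametric bootstrap over retained rows; a scenario is only
"selected" when its CI does not overlap the runner-up's.

The summary-statistic panel follows the microsatellite conventions of
DIYABC-style analyses: per population mean alleles/locus, mean expected
heterozygosity and mean allele-size variance; per population pair
Weir-Cockerham theta, the (delta mu)^2 mean-size distance and an
allele-sharing distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression

from ._kernels import summarize_msat_kernel
from .datamodel import GenotypeMatrix
from .simulate import (
    DemographicScenario,
    MutationModel,
    PriorSpec,
    SampleConfig,
    sample_priors,
    simulate_msat_alleles,
)

__all__ = [
    "summary_stat_names",
    "summarize",
    "ReferenceTable",
    "build_reference_table",
    "rejection",
    "AbcModelChoice",
    "scenario_posterior",
    "confusion_matrix",
]


def summary_stat_names(populations: list[str]) -> list[str]:
    """Fixed ordering of the summary-statistic panel for these populations."""
    names = [f"mean_alleles_{p}" for p in populations]
    names += [f"mean_he_{p}" for p in populations]
    names += [f"size_var_{p}" for p in populations]
    pairs = [
        (populations[i], populations[j])
        for i in range(len(populations))
        for j in range(i + 1, len(populations))
    ]
    names += [f"fst_{a}_{b}" for a, b in pairs]
    names += [f"dmu2_{a}_{b}" for a, b in pairs]
    names += [f"das_{a}_{b}" for a, b in pairs]
    return names


def _summarize_arrays(
    alleles: np.ndarray, ind_pop: np.ndarray, npops: int, amin: int, amax: int
) -> np.ndarray:
    return summarize_msat_kernel(
        np.ascontiguousarray(alleles), ind_pop.astype(np.int64), npops, amin, amax
    )


def summarize(
    g: GenotypeMatrix, mut: MutationModel | None = None
) -> tuple[np.ndarray, list[str]]:
    """Summary-statistic vector of an observed genotype matrix.

    Returns (vector, names); entries that would be degenerate (e.g. a
    population with an all-missing locus) are computed as 0 by convention.
    """
    mut = mut or MutationModel()
    codes, pops = g.pop_codes()
    amin = min(mut.allele_min, int(g.alleles[g.alleles > 0].min()))
    amax = max(mut.allele_max, int(g.alleles.max()))
    vec = _summarize_arrays(g.alleles, codes, len(pops), amin, amax)
    return vec, summary_stat_names(pops)


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, statistics) rows plus normalization."""

    scenario_ids: np.ndarray  # (rows,) int: index into `scenarios`
    scenarios: list[str]
    params: list[dict[str, float]]
    stats: np.ndarray  # (rows, n_stats)
    stat_names: list[str]
    col_mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    col_sd: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.col_mean.size == 0:
            self.col_mean = self.stats.mean(axis=0)
            sd = self.stats.std(axis=0)
            sd[sd == 0] = 1.0
            self.col_sd = sd

    @property
    def n_rows(self) -> int:
        return len(self.scenario_ids)

    def normalized(self, x: np.ndarray | None = None) -> np.ndarray:
        x = self.stats if x is None else x
        return (x - self.col_mean) / self.col_sd


def build_reference_table(
    scenarios: list[DemographicScenario],
    priors: PriorSpec,
    n_per_scenario: int,
    sample: SampleConfig,
    seed: int = 0,
    mut: MutationModel | None = None,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario and summarize each."""
    if not scenarios:
        raise ValueError("scenario list is empty")
    mut = mut or MutationModel()
    rng = np.random.default_rng(seed)
    pops = [p for p in scenarios[0].populations if sample.genotypes.get(p, 0) > 0]
    names = summary_stat_names(pops)
    rows = len(scenarios) * n_per_scenario
    stats = np.empty((rows, len(names)))
    ids = np.empty(rows, dtype=np.int64)
    params_list: list[dict[str, float]] = []
    r = 0
    for s_ix, scen in enumerate(scenarios):
        for _ in range(n_per_scenario):
            params = sample_priors(scen, priors, rng)
            alleles, ind_pop, _ = simulate_msat_alleles(scen, params, sample, mut, rng)
            stats[r] = _summarize_arrays(
                alleles, ind_pop, len(pops), mut.allele_min, mut.allele_max
            )
            ids[r] = s_ix
            params_list.append(params)
            r += 1
    return ReferenceTable(
        scenario_ids=ids, scenarios=[s.name for s in scenarios],
        params=params_list, stats=stats, stat_names=names,
    )


def rejection(
    obs: np.ndarray, table: ReferenceTable, tolerance: float = 0.01
) -> np.ndarray:
    """Indices of the ceil(tolerance * rows) rows closest to ``obs``.

    Euclidean distance on SD-normalized statistics; ties broken by row index
    (stable sort).
    """
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance must be in (0, 1]")
    dist = np.linalg.norm(table.normalized() - table.normalized(obs), axis=1)
    keep = math.ceil(tolerance * table.n_rows)
    order = np.argsort(dist, kind="stable")
    return order[:keep]


@dataclass
class AbcModelChoice:
    """Posterior probabilities of the candidate scenarios at the observation."""

    scenarios: list[str]
    posterior: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_retained: int
    selected: str  # winning scenario name, or "ambiguous"
    retained_fractions: np.ndarray | None = None


def _fit_predict(
    X: np.ndarray, y: np.ndarray, x_obs: np.ndarray, n_classes: int
) -> np.ndarray:
    """LDA projection + multinomial logit, evaluated at the observation."""
    present = np.unique(y)
    pp = np.zeros(n_classes)
    if len(present) == 1:
        pp[present[0]] = 1.0
        return pp
    n_axes = min(len(present) - 1, X.shape[1])
    lda = LinearDiscriminantAnalysis(n_components=n_axes)
    try:
        Xp = lda.fit_transform(X, y)
        xo = lda.transform(x_obs.reshape(1, -1))
    except np.linalg.LinAlgError:  # degenerate covariance: fall back to raw
        Xp, xo = X, x_obs.reshape(1, -1)
    # standardize the projections: keeps the regularized logit well
    # conditioned even when classes are nearly separable
    mu, sd = Xp.mean(axis=0), Xp.std(axis=0)
    sd[sd == 0] = 1.0
    Xp = (Xp - mu) / sd
    xo = (xo - mu) / sd
    clf = LogisticRegression(max_iter=500, C=1.0)
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xp, y)
    probs = clf.predict_proba(xo)[0]
    for cls, p in zip(clf.classes_, probs):
        pp[int(cls)] = p
    return pp


def scenario_posterior(
    obs: np.ndarray,
    table: ReferenceTable,
    tolerance: float = 0.01,
    n_bootstrap: int = 200,
    rng: np.random.Generator | int | None = None,
) -> AbcModelChoice:
    """Polychotomous-logistic posterior probabilities of each scenario.

    LDA axes are fitted on the retained rows (labels = scenario) as a
    preprocessing step; the CI is a nonparametric bootstrap over retained
    rows.  The selected scenario must beat the runner-up with non-overlapping
    95 % CIs, otherwise "ambiguous".
    """
    rng = np.random.default_rng(rng)
    keep = rejection(obs, table, tolerance)
    X = table.normalized()[keep]
    y = table.scenario_ids[keep]
    xo = table.normalized(obs)
    S = len(table.scenarios)
    pp = _fit_predict(X, y, xo, S)
    pp = pp / pp.sum()

    boots = np.empty((max(n_bootstrap, 0), S))
    for b in range(n_bootstrap):
        ix = rng.integers(0, len(keep), size=len(keep))
        boots[b] = _fit_predict(X[ix], y[ix], xo, S)
    if n_bootstrap:
        lo = np.quantile(boots, 0.025, axis=0)
        hi = np.quantile(boots, 0.975, axis=0)
    else:
        lo = hi = np.full(S, math.nan)
    order = np.argsort(-pp)
    selected = table.scenarios[order[0]]
    if n_bootstrap and len(order) > 1 and lo[order[0]] <= hi[order[1]]:
        selected = "ambiguous"
    fracs = np.bincount(y, minlength=S) / len(y)
    return AbcModelChoice(
        scenarios=list(table.scenarios), posterior=pp, ci_low=lo, ci_high=hi,
        n_retained=len(keep), selected=selected, retained_fractions=fracs,
    )


def confusion_matrix(
    scenarios: list[DemographicScenario],
    priors: PriorSpec,
    table: ReferenceTable,
    sample: SampleConfig,
    n_pods: int = 20,
    tolerance: float = 0.01,
    seed: int = 0,
    mut: MutationModel | None = None,
) -> np.ndarray:
    """Mean posterior probability matrix over pseudo-observed datasets.

    Row i: datasets simulated under scenario i; column j: mean posterior
    probability assigned to scenario j.  Rows sum to 1.
    """
    mut = mut or MutationModel()
    rng = np.random.default_rng(seed)
    S = len(scenarios)
    out = np.zeros((S, S))
    pops = [p for p in scenarios[0].populations if sample.genotypes.get(p, 0) > 0]
    for i, scen in enumerate(scenarios):
        for _ in range(n_pods):
            params = sample_priors(scen, priors, rng)
            alleles, ind_pop, _ = simulate_msat_alleles(scen, params, sample, mut, rng)
            obs = _summarize_arrays(
                alleles, ind_pop, len(pops), mut.allele_min, mut.allele_max
            )
            mc = scenario_posterior(obs, table, tolerance, n_bootstrap=0, rng=rng)
            out[i] += mc.posterior
        out[i] /= n_pods
    return out
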