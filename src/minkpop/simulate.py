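"""Backward-time coalescent simulation under parameterised demographic scenarios.

A :class:`DemographicScenario` is an ordered schedule of backward-time events
over a set of sampled populations: population splits (lineage movement into an
ancestral deme), admixture (probabilistic movement into two source demes) and
effective-size changes.  Microsatellites mutate under a generalized stepwise
model (geometric step sizes, reflecting allele-range boundaries) and mtDNA
under infinite sites.  The same machinery is both the reference simulator for
ABC model choice and the package's synthetic-data generator.

Times are in generations (one generation = one year for this species);
effective sizes N are diploid individuals.  mtDNA lineages coalesce with the
female effective size N_f = N/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .datamodel import GenotypeMatrix, GroupingScheme, HaplotypeAlignment

__all__ = [
    "Split",
    "Admixture",
    "SizeChange",
    "DemographicScenario",
    "Prior",
    "PriorSpec",
    "MutationModel",
    "SampleConfig",
    "SyntheticDataset",
    "default_priors",
    "sample_priors",
    "simulate_coalescent",
    "mink_scenarios",
    "generate_mink_like",
    "MINK_SAMPLE_CONFIG",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class Split:
    """Backward in time at ``t``, all lineages of ``derived`` join ``ancestor``."""

    t: str
    derived: str
    ancestor: str


@dataclass(frozen=True)
class Admixture:
    """At ``t`` each lineage of ``derived`` joins ``source_a`` with probability
    ``r`` (a parameter name), else ``source_b``."""

    t: str
    derived: str
    source_a: str
    source_b: str
    r: str = "r"


@dataclass(frozen=True)
class SizeChange:
    """At ``t`` population ``pop`` takes (diploid) size parameter ``size``."""

    t: str
    pop: str
    size: str


Event = Split | Admixture | SizeChange


@dataclass
class DemographicScenario:
    """Named event schedule over sampled populations.

    ``events`` must be ordered by (non-strictly) increasing backward time once
    parameters are drawn; after the last split exactly one population carries
    all remaining lineages.
    """

    name: str
    populations: list[str]
    events: list[Event]
    size_params: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.size_params:
            self.size_params = {p: f"N_{p}" for p in self.populations}
        self._validate_collapse()

    def _validate_collapse(self) -> None:
        alive = set(self.populations)
        for ev in self.events:
            if isinstance(ev, Split):
                if ev.derived not in alive:
                    raise ValueError(
                        f"{self.name}: split of inactive population {ev.derived}"
                    )
                alive.discard(ev.derived)
            elif isinstance(ev, Admixture):
                if ev.derived not in alive:
                    raise ValueError(
                        f"{self.name}: admixture of inactive population {ev.derived}"
                    )
                alive.discard(ev.derived)
                alive.update((ev.source_a, ev.source_b))
        if len(alive) != 1:
            raise ValueError(
                f"{self.name}: {len(alive)} populations remain after final event; "
                "exactly one ancestral population required"
            )

    @property
    def free_parameters(self) -> list[str]:
        names: dict[str, None] = {}
        for p in self.size_params.values():
            names.setdefault(p)
        for ev in self.events:
            names.setdefault(ev.t)
            if isinstance(ev, Admixture):
                names.setdefault(ev.r)
            if isinstance(ev, SizeChange):
                names.setdefault(ev.size)
        return [n for n in names if not _is_number(n)]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


@dataclass(frozen=True)
class Prior:
    """Marginal prior: 'uniform' or 'loguniform' on finite (low, high)."""

    dist: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior family {self.dist!r}")
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("prior bounds must be finite")
        if not self.low < self.high:
            raise ValueError("prior needs low < high")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError("log-uniform needs positive bounds")

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))


@dataclass
class PriorSpec:
    """Per-parameter priors plus '<=' order constraints between parameters."""

    priors: dict[str, Prior]
    order: list[tuple[str, str]] = field(default_factory=list)

    def __getitem__(self, name: str) -> Prior:
        return self.priors[name]


def default_priors(order_times: tuple[str, ...] = ("T1", "T2", "T3")) -> PriorSpec:
    """DIYABC-conventional default priors used throughout the package.

    N ~ U[100, 30000] diploids; event times U[10, 1e5] generations with
    T1 <= T2 <= T3; admixture proportion r ~ U[0.1, 0.9]; microsatellite
    mutation rate log-U[1e-4, 1e-3] per locus per generation and geometric
    GSM parameter U[0, 0.3].
    """
    priors: dict[str, Prior] = {
        "r": Prior("uniform", 0.1, 0.9),
        "mu": Prior("loguniform", 1e-4, 1e-3),
        "p_gsm": Prior("uniform", 0.0, 0.3),
    }
    for p in ("NE", "SE", "FR", "SP", "ANC"):
        priors[f"N_{p}"] = Prior("uniform", 100.0, 30000.0)
    for t in order_times:
        priors[t] = Prior("uniform", 10.0, 1e5)
    order = [
        (order_times[i], order_times[i + 1]) for i in range(len(order_times) - 1)
    ]
    return PriorSpec(priors=priors, order=order)


def sample_priors(
    scenario: DemographicScenario,
    priors: PriorSpec,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> dict[str, float]:
    """Draw one fully instantiated parameter set honouring order constraints.

    Draws are rejected and redrawn until every declared '<=' constraint holds.
    Mutation parameters ('mu', 'p_gsm') are drawn too when the prior
    specification covers them, so that a reference table integrates over
    mutation-rate uncertainty.
    """
    needed = scenario.free_parameters + [
        p for p in ("mu", "p_gsm") if p in priors.priors
    ]
    missing = [p for p in needed if p not in priors.priors]
    if missing:
        raise ValueError(f"no prior for parameters {missing}")
    relevant = [(a, b) for a, b in priors.order if a in needed and b in needed]
    for _ in range(max_tries):
        draw = {p: priors[p].draw(rng) for p in needed}
        if all(draw[a] <= draw[b] for a, b in relevant):
            return draw
    raise RuntimeError("order constraints unsatisfiable within max_tries")


@dataclass(frozen=True)
class MutationModel:
    """Mutation parameters for both marker classes.

    ``mtdna_rate`` defaults to half the 14.5 %/Myr *divergence* rate, i.e.
    7.25e-8 substitutions/site/year per lineage, at one generation per year.
    """

    msat_mu: float = 5e-4
    p_gsm: float = 0.0
    allele_min: int = 5
    allele_max: int = 60
    ancestral_allele: int = 30
    mtdna_rate: float = 7.25e-8

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_gsm < 1.0):
            raise ValueError("p_gsm must be in [0, 1)")
        if self.msat_mu <= 0 or self.mtdna_rate <= 0:
            raise ValueError("mutation rates must be positive")
        if not (self.allele_min < self.ancestral_allele < self.allele_max):
            raise ValueError("ancestral allele outside the declared range")


@dataclass(frozen=True)
class SampleConfig:
    """How many diploid genotypes / mtDNA sequences to draw per population."""

    genotypes: dict[str, int]
    sequences: dict[str, int]
    n_loci: int = 11
    seq_length: int = 476

    def __post_init__(self) -> None:
        if all(v == 0 for v in self.genotypes.values()) and all(
            v == 0 for v in self.sequences.values()
        ):
            raise ValueError("no samples requested")
        if any(v < 0 for v in {**self.genotypes, **self.sequences}.values()):
            raise ValueError("negative sample count")


def _proportional_split(total: int, weights: list[int]) -> list[int]:
    """Largest-remainder apportionment of ``total`` over ``weights``."""
    w = np.asarray(weights, dtype=float)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base.tolist()


#: Regional sample sizes of the mink study conditions: genotyped individuals
#: NE=107 (Russia 88 + Belarus/Estonia 19), SE=44, FR=73, SP=89 (313 total)
#: and 157 mtDNA sequences apportioned proportionally.
MINK_SAMPLE_CONFIG = SampleConfig(
    genotypes={"NE": 107, "SE": 44, "FR": 73, "SP": 89},
    sequences=dict(
        zip(["NE", "SE", "FR", "SP"], _proportional_split(157, [107, 44, 73, 89]))
    ),
    n_loci=11,
    seq_length=476,
)


@dataclass
class SyntheticDataset:
    """A simulated dataset with its generating ground truth attached."""

    genotypes: GenotypeMatrix
    alignment: HaplotypeAlignment
    grouping: GroupingScheme
    scenario: str
    params: dict[str, float]


# -- scenario catalogue ------------------------------------------------------

def _admix_scenario(
    k: int, west: str, other: str, ne_se_split_time: str, fr_sp_split: bool
) -> DemographicScenario:
    """Admixture scenarios: the western founder deme ``west`` arises from an
    NE x SE admixture pulse at T2; ``other`` splits from it at T1 (or is the
    same deme when ``fr_sp_split`` is false, encoded as a split at 1 gen)."""
    events: list[Event] = []
    if fr_sp_split:
        events.append(Split("T1", other, west))
    else:
        events.append(Split("1", other, west))
    events.append(Admixture("T2", west, "NE", "SE", "r"))
    events.append(Split(ne_se_split_time, "SE", "NE"))
    events.append(SizeChange(ne_se_split_time, "NE", "N_ANC"))
    return DemographicScenario(
        name=f"scenario_{k}", populations=["NE", "SE", "FR", "SP"], events=events
    )


def _bifurcation_scenario(k: int, mid: tuple[str, str], late: tuple[str, str]):
    """Pure-divergence scenarios: NE/SE split at T3, then ``mid`` = (derived,
    source) at T2 and ``late`` at T1."""
    events: list[Event] = [
        Split("T1", late[0], late[1]),
        Split("T2", mid[0], mid[1]),
        Split("T3", "SE", "NE"),
        SizeChange("T3", "NE", "N_ANC"),
    ]
    return DemographicScenario(
        name=f"scenario_{k}", populations=["NE", "SE", "FR", "SP"], events=events
    )


def mink_scenarios() -> list[DemographicScenario]:
    """The fourteen candidate colonization histories for the four sampled
    populations (NE, SE, FR, SP) descending from a single ancestral deme.

    Scenarios 1-6 contain an admixture pulse founding the western lineage:
    1/3/5 without prior NE-SE differentiation (NE and SE separate only at the
    admixture time), 2/4/6 with differentiation at the older T3; in 1-2 the
    pulse founds the FR lineage (SP splits from it later), in 3-4 the SP
    lineage, and in 5-6 FR and SP are effectively one western deme.
    Scenarios 7-14 are pure three-step divergence histories: the four chain
    topologies (the second western deme splitting from the first) and the
    four independent derivations of FR and SP from NE/SE.  The 7-14
    enumeration is this package's interpretation of "all ordered
    bifurcation orders"; the admixture scenarios follow the published
    descriptions exactly.
    """
    out = [
        _admix_scenario(1, "FR", "SP", "T2", True),
        _admix_scenario(2, "FR", "SP", "T3", True),
        _admix_scenario(3, "SP", "FR", "T2", True),
        _admix_scenario(4, "SP", "FR", "T3", True),
        _admix_scenario(5, "FR", "SP", "T2", False),
        _admix_scenario(6, "FR", "SP", "T3", False),
        # chains
        _bifurcation_scenario(7, ("FR", "NE"), ("SP", "FR")),
        _bifurcation_scenario(8, ("FR", "SE"), ("SP", "FR")),
        _bifurcation_scenario(9, ("SP", "NE"), ("FR", "SP")),
        _bifurcation_scenario(10, ("SP", "SE"), ("FR", "SP")),
        # independent derivations
        _bifurcation_scenario(11, ("FR", "NE"), ("SP", "NE")),
        _bifurcation_scenario(12, ("FR", "NE"), ("SP", "SE")),
        _bifurcation_scenario(13, ("FR", "SE"), ("SP", "NE")),
        _bifurcation_scenario(14, ("FR", "SE"), ("SP", "SE")),
    ]
    assert len(out) == 14
    return out


# -- event compilation and simulation ----------------------------------------

def _compile_events(
    scenario: DemographicScenario,
    params: dict[str, float],
    size_scale: float,
):
    """Turn the symbolic schedule into the kernel's parallel arrays.

    ``size_scale`` converts diploid N to coalescent units (2.0 for autosomal
    loci, 0.5 for mtDNA).  Event order: by time, ties kept in schedule order.
    """
    pops = list(scenario.populations)
    pop_ix = {p: i for i, p in enumerate(pops)}

    def val(tok: str) -> float:
        return float(tok) if _is_number(tok) else float(params[tok])

    rows = []
    for k, ev in enumerate(scenario.events):
        t = val(ev.t)
        if t <= 0:
            raise ValueError(f"event time {ev.t}={t} must be positive")
        if isinstance(ev, Split):
            for q in (ev.derived, ev.ancestor):
                if q not in pop_ix:
                    pop_ix[q] = len(pops)
                    pops.append(q)
            rows.append((t, k, 0, pop_ix[ev.derived], pop_ix[ev.ancestor], 0, 0.0))
        elif isinstance(ev, Admixture):
            for q in (ev.derived, ev.source_a, ev.source_b):
                if q not in pop_ix:
                    pop_ix[q] = len(pops)
                    pops.append(q)
            rows.append(
                (t, k, 1, pop_ix[ev.derived], pop_ix[ev.source_a],
                 pop_ix[ev.source_b], val(ev.r))
            )
        else:
            rows.append((t, k, 2, pop_ix[ev.pop], 0, 0, val(ev.size) * size_scale))
    rows.sort(key=lambda r: (r[0], r[1]))
    ev_time = np.array([r[0] for r in rows], dtype=np.float64)
    ev_type = np.array([r[2] for r in rows], dtype=np.int64)
    ev_a = np.array([r[3] for r in rows], dtype=np.int64)
    ev_b = np.array([r[4] for r in rows], dtype=np.int64)
    ev_c = np.array([r[5] for r in rows], dtype=np.int64)
    ev_x = np.array([r[6] for r in rows], dtype=np.float64)
    sizes = np.array(
        [val(scenario.size_params.get(p, f"N_{p}")) * size_scale for p in pops],
        dtype=np.float64,
    )
    return sizes, ev_time, ev_type, ev_a, ev_b, ev_c, ev_x, pop_ix


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_msat_alleles(
    scenario: DemographicScenario,
    params: dict[str, float],
    sample: SampleConfig,
    mut: MutationModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Simulate raw repeat counts: returns (alleles (n, n_loci, 2), pop codes,
    pop order)."""
    pop_order = [p for p in scenario.populations if sample.genotypes.get(p, 0) > 0]
    n_ind = sum(sample.genotypes[p] for p in pop_order)
    sizes, *ev, pop_ix = _compile_events(scenario, params, size_scale=2.0)
    lin_pop = np.concatenate(
        [np.full(2 * sample.genotypes[p], pop_ix[p], dtype=np.int64) for p in pop_order]
    )
    copies = _kernels.sim_msat_dataset(
        _child_seed(rng), lin_pop, sizes, *ev,
        sample.n_loci, params.get("mu", mut.msat_mu),
        params.get("p_gsm", mut.p_gsm), mut.ancestral_allele,
        mut.allele_min, mut.allele_max,
    )
    alleles = copies.reshape(n_ind, 2, sample.n_loci).transpose(0, 2, 1)
    ind_pop = np.concatenate(
        [np.full(sample.genotypes[p], k, dtype=np.int64) for k, p in enumerate(pop_order)]
    )
    return np.ascontiguousarray(alleles), ind_pop, pop_order


def simulate_sequences(
    scenario: DemographicScenario,
    params: dict[str, float],
    sample: SampleConfig,
    mut: MutationModel,
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray, list[str]]:
    """Simulate mtDNA sequences; returns (seqs, pop codes, pop order)."""
    pop_order = [p for p in scenario.populations if sample.sequences.get(p, 0) > 0]
    sizes, *ev, pop_ix = _compile_events(scenario, params, size_scale=0.5)
    lin_pop = np.concatenate(
        [np.full(sample.sequences[p], pop_ix[p], dtype=np.int64) for p in pop_order]
    )
    states, sites = _kernels.sim_mtdna(
        _child_seed(rng), lin_pop, sizes, *ev, mut.mtdna_rate, sample.seq_length
    )
    ancestral = _BASES[rng.integers(0, 4, size=sample.seq_length)].copy()
    derived = ancestral[sites].copy()
    for j in range(len(sites)):
        choices = [b for b in _BASES if b != derived[j]]
        derived[j] = choices[int(rng.integers(0, 3))]
    seqs = []
    for row in states:
        s = ancestral.copy()
        s[sites[row.astype(bool)]] = derived[row.astype(bool)]
        seqs.append(b"".join(s).decode())
    ind_pop = np.concatenate(
        [np.full(sample.sequences[p], k, dtype=np.int64) for k, p in enumerate(pop_order)]
    )
    return seqs, ind_pop, pop_order


def simulate_coalescent(
    scenario: DemographicScenario,
    params: dict[str, float],
    sample: SampleConfig,
    mut: MutationModel | None = None,
    rng: np.random.Generator | int | None = None,
    groups: dict[str, str] | None = None,
) -> SyntheticDataset:
    """Simulate one full dataset (genotypes + sequences) under a scenario.

    ``groups`` optionally maps population -> region label for the returned
    grouping scheme (defaults to one group per population).
    """
    mut = mut or MutationModel()
    rng = np.random.default_rng(rng)
    geno = None
    if any(sample.genotypes.get(p, 0) > 0 for p in scenario.populations):
        alleles, ind_pop, pops_g = simulate_msat_alleles(
            scenario, params, sample, mut, rng
        )
        ids = [f"{pops_g[ind_pop[i]]}_g{i:04d}" for i in range(len(ind_pop))]
        geno = GenotypeMatrix(
            individuals=ids,
            loci=[f"L{k + 1:02d}" for k in range(sample.n_loci)],
            alleles=alleles,
            pop_of={i: pops_g[p] for i, p in zip(ids, ind_pop)},
        )
    aln = None
    if any(sample.sequences.get(p, 0) > 0 for p in scenario.populations):
        seqs, seq_pop, pops_s = simulate_sequences(scenario, params, sample, mut, rng)
        sids = [f"{pops_s[seq_pop[i]]}_m{i:04d}" for i in range(len(seq_pop))]
        aln = HaplotypeAlignment(
            ids=sids,
            seqs=seqs,
            pop_of={i: pops_s[p] for i, p in zip(sids, seq_pop)},
        )
    unit_of: dict[str, str] = {}
    if geno is not None:
        unit_of.update(geno.pop_of)
    if aln is not None:
        unit_of.update(aln.pop_of)
    grouping = GroupingScheme.from_labels("regions", unit_of, groups)
    return SyntheticDataset(
        genotypes=geno, alignment=aln, grouping=grouping,
        scenario=scenario.name, params=dict(params),
    )


def generate_mink_like(
    scenario_id: int = 2,
    seed: int | np.random.Generator = 0,
    priors: PriorSpec | None = None,
    params: dict[str, float] | None = None,
) -> SyntheticDataset:
    """A full mink-like dataset: 313 genotyped individuals at 11 loci in four
    regional populations (NE=107, SE=44, FR=73, SP=89) plus 157 mtDNA
    sequences, generated under one of the fourteen scenarios.

    Ground truth (scenario name and the drawn parameters) is embedded in the
    returned dataset.
    """
    if not 1 <= scenario_id <= 14:
        raise ValueError("scenario_id must be in 1..14")
    rng = np.random.default_rng(seed)
    scenario = mink_scenarios()[scenario_id - 1]
    priors = priors or default_priors()
    if params is None:
        params = sample_priors(scenario, priors, rng)
    ds = simulate_coalescent(
        scenario, params, MINK_SAMPLE_CONFIG, MutationModel(), rng,
        groups={"NE": "East", "SE": "East", "FR": "West", "SP": "West"},
    )
    return replace(ds, scenario=scenario.name)
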