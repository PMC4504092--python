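"""Config-driven orchestration of the full analysis flow.

``run_study`` executes the stages (diversity/neutrality, microsatellite
variability, differentiation + AMOVA/SAMOVA, haplotype network, ABC scenario
choice) in dependency order on real files or on a synthetic dataset, and
returns a JSON-serializable report whose blocks mirror the classic paper
tables.  A single global seed fans out deterministically into per-stage
child seeds, so toggling one stage never changes another stage's results.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import abc as abc_mod
from . import io as io_mod
from .datamodel import GenotypeMatrix, HaplotypeAlignment, collapse_haplotypes, trim_gapped_columns
from .differentiation import (
    amova,
    f_st_pairwise,
    genotype_distance_matrix,
    phi_st_pairwise,
    r_st_pairwise,
    samova,
    sequence_distance_matrix,
)
from .diversity import diversity_summary, neutrality_test
from .msat import bonferroni, f_is, hwe_test, null_allele_em, summarize_msat
from .network import median_joining
from .simulate import (
    MINK_SAMPLE_CONFIG,
    default_priors,
    generate_mink_like,
    mink_scenarios,
)

__all__ = ["RunConfig", "run_study", "make_fixtures", "REGION_COORDS"]

#: rough regional centroids (lat, lon) of the four sampled regions, used as
#: SAMOVA coordinates when none are supplied
REGION_COORDS = {
    "NE": (58.0, 38.0),
    "SE": (45.2, 28.8),
    "FR": (44.6, 0.0),
    "SP": (42.6, -2.8),
    "East": (52.0, 33.0),
    "West": (43.6, -1.4),
}


@dataclass
class RunConfig:
    """Inputs, stage toggles and sampling settings for one study run."""

    # either real files ...
    fasta: str | None = None
    genepop: str | None = None
    sidecar: str | None = None
    # ... or a synthetic scenario
    synthetic_scenario: int | None = 2
    seed: int = 0
    outdir: str | None = None
    stages: tuple[str, ...] = ("diversity", "msat", "differentiation", "network", "abc")
    permutations: int = 999
    neutrality_reps: int = 2000
    hwe_reps: int = 1000
    abc_n_per_scenario: int = 2000
    abc_scenarios: int = 6
    abc_tolerance: float = 0.01
    samova_k: tuple[int, ...] = (2, 3, 4)
    coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        for k in ("stages", "samova_k"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)


def _jsonable(x: Any) -> Any:
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return _jsonable(dataclasses.asdict(x))
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return _jsonable(x.tolist())
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        xf = float(x)
        return xf if math.isfinite(xf) else repr(xf)
    return x


def _load_inputs(cfg: RunConfig):
    if cfg.fasta or cfg.genepop:
        meta = io_mod.read_sidecar(cfg.sidecar) if cfg.sidecar else None
        aln = io_mod.read_fasta(cfg.fasta, meta) if cfg.fasta else None
        geno = io_mod.read_genepop(cfg.genepop) if cfg.genepop else None
        if geno is not None and meta is not None:
            pop_of = {
                i: str(meta.loc[i, "population"]) if i in meta.index else geno.pop_of[i]
                for i in geno.individuals
            }
            geno = GenotypeMatrix(
                geno.individuals, geno.loci, geno.alleles, pop_of
            )
        truth = None
    else:
        ds = generate_mink_like(cfg.synthetic_scenario or 2, seed=cfg.seed)
        aln, geno = ds.alignment, ds.genotypes
        truth = {"scenario": ds.scenario, "params": ds.params}
    if geno is not None:
        geno = geno.drop_poorly_typed(min_loci=min(9, geno.n_loci))
    return aln, geno, truth


def run_study(cfg: RunConfig) -> dict[str, Any]:
    """Run the configured stages and return the structured report."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(8)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(
            ("diversity", "msat", "differentiation", "samova", "network", "abc",
             "abc_obs", "spare"),
            seeds,
        )
    }
    aln, geno, truth = _load_inputs(cfg)
    report: dict[str, Any] = {
        "config": _jsonable(dataclasses.asdict(cfg)),
        "seeds": stage_seed,
        "stages": {},
    }
    if truth:
        report["ground_truth"] = _jsonable(truth)

    def run_stage(name, fn):
        if name not in cfg.stages:
            return
        try:
            report["stages"][name] = _jsonable(fn())
        except Exception as exc:  # stage isolation: others proceed
            report["stages"][name] = {"failed": True, "error": str(exc)}

    run_stage("diversity", lambda: _stage_diversity(cfg, aln, stage_seed))
    run_stage("msat", lambda: _stage_msat(cfg, geno, stage_seed))
    run_stage("differentiation", lambda: _stage_diff(cfg, aln, geno, stage_seed))
    run_stage("network", lambda: _stage_network(aln))
    run_stage("abc", lambda: _stage_abc(cfg, geno, stage_seed))

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report


def _stage_diversity(cfg, aln, seeds):
    if aln is None:
        raise ValueError("no sequence data")
    aln = trim_gapped_columns(aln)
    rows = diversity_summary(aln)
    rng = np.random.default_rng(seeds["diversity"])
    neut = {}
    neut["all"] = neutrality_test(aln, reps=cfg.neutrality_reps, rng=rng)
    for p in aln.populations:
        ids = [i for i in aln.ids if aln.pop_of[i] == p]
        if len(ids) >= 4:
            sub = aln.subset(ids)
            neut[p] = neutrality_test(sub, reps=cfg.neutrality_reps, rng=rng)
    return {"diversity": rows, "neutrality": neut}


def _stage_msat(cfg, geno, seeds):
    if geno is None:
        raise ValueError("no genotype data")
    rng = np.random.default_rng(seeds["msat"])
    rows = summarize_msat(geno)
    hwe = {}
    nulls = {}
    for p in geno.populations:
        hp = [
            hwe_test(geno, p, l, reps=cfg.hwe_reps, rng=rng)
            for l in range(geno.n_loci)
        ]
        thr, flags = bonferroni([x for x in hp if not math.isnan(x)])
        hwe[p] = {"pvalues": hp, "bonferroni_threshold": thr,
                  "significant": flags}
        nulls[p] = [
            null_allele_em(geno, p, l).frequency for l in range(geno.n_loci)
        ]
    return {"summary": rows, "hwe": hwe, "null_alleles": nulls,
            "f_is_overall": f_is(geno)}


def _stage_diff(cfg, aln, geno, seeds):
    rng = np.random.default_rng(seeds["differentiation"])
    out: dict[str, Any] = {}
    if aln is not None:
        aln_t = trim_gapped_columns(aln)
        out["phi_st"] = phi_st_pairwise(aln_t, cfg.permutations, rng)
        d2 = sequence_distance_matrix(aln_t)
        labels = [aln_t.pop_of[i] for i in aln_t.ids]
        groups = {"NE": "East", "SE": "East", "FR": "West", "SP": "West"}
        gmap = {u: groups.get(u, u) for u in set(labels)}
        out["amova_mtdna"] = amova(d2, labels, gmap, cfg.permutations, rng)
        coords = {**REGION_COORDS, **cfg.coords}
        units = list(dict.fromkeys(labels))
        if all(u in coords for u in units):
            sam_rng = np.random.default_rng(seeds["samova"])
            best = None
            per_k = {}
            for k in cfg.samova_k:
                if k > len(units):
                    continue
                r = samova(d2, labels, coords, k, rng=sam_rng,
                           permutations=min(cfg.permutations, 199))
                per_k[k] = r
                if best is None or r.f_ct > best.f_ct:
                    best = r
            out["samova"] = {"per_k": per_k,
                             "best_k": best.k if best else None}
    if geno is not None:
        out["f_st"] = f_st_pairwise(geno, cfg.permutations, rng)
        out["r_st"] = r_st_pairwise(geno, cfg.permutations, rng)
        labels = [geno.pop_of[i] for i in geno.individuals]
        groups = {"NE": "East", "SE": "East", "FR": "West", "SP": "West"}
        gmap = {u: groups.get(u, u) for u in set(labels)}
        d2 = genotype_distance_matrix(geno)
        out["amova_msat"] = amova(d2, labels, gmap, cfg.permutations, rng)
    return out


def _stage_network(aln):
    if aln is None:
        raise ValueError("no sequence data")
    table = collapse_haplotypes(trim_gapped_columns(aln))
    net = median_joining(table, epsilon=0)
    return {
        "n_haplotypes": len(table.haplotypes),
        "n_medians": len(net.medians),
        "total_length": net.total_length,
        "edges": [
            (f"H{table.haplotypes.index(u) + 1}" if u in table.haplotypes else "median",
             f"H{table.haplotypes.index(v) + 1}" if v in table.haplotypes else "median",
             w)
            for u, v, w in net.export_edgelist()
        ],
    }


def _stage_abc(cfg, geno, seeds):
    if geno is None:
        raise ValueError("no genotype data")
    scens = mink_scenarios()[: cfg.abc_scenarios]
    priors = default_priors()
    sample = MINK_SAMPLE_CONFIG
    table = abc_mod.build_reference_table(
        scens, priors, cfg.abc_n_per_scenario, sample, seed=seeds["abc"]
    )
    obs, _names = abc_mod.summarize(geno)
    mc = abc_mod.scenario_posterior(
        obs, table, cfg.abc_tolerance, n_bootstrap=200, rng=seeds["abc_obs"]
    )
    return {
        "scenarios": mc.scenarios,
        "posterior": mc.posterior,
        "ci_low": mc.ci_low,
        "ci_high": mc.ci_high,
        "selected": mc.selected,
        "n_retained": mc.n_retained,
        "n_per_scenario": cfg.abc_n_per_scenario,
    }


# -- canonical fixtures ------------------------------------------------------

def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write small canonical datasets used by the tests and the examples.

    ``star``: a star-like mtDNA alignment (central haplotype plus one-step
    derivatives); ``two_cluster``: genotypes from two strongly diverged pairs
    of populations; ``mink_like``: a full synthetic scenario-2 dataset.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    # star-like mtDNA: center (x10) + 5 singleton one-step derivatives
    L = 60
    center = "".join(rng.choice(list("ACGT"), size=L))
    seqs, ids, pop = [], [], {}
    for i in range(10):
        ids.append(f"c{i:02d}")
        seqs.append(center)
    var_sites = rng.choice(L, size=5, replace=False)
    for k, site in enumerate(var_sites):
        s = list(center)
        s[site] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[site]]
        ids.append(f"d{k:02d}")
        seqs.append("".join(s))
    for i in ids:
        pop[i] = "NE"
    aln = HaplotypeAlignment(ids=ids, seqs=seqs, pop_of=pop)
    io_mod.write_fasta(aln, out / "star.fasta")
    io_mod.write_sidecar(
        _sidecar_frame(ids, pop), out / "star.tsv"
    )
    paths["star_fasta"] = out / "star.fasta"

    # two planted clusters: 6 pops, two groups fixed for distant haplotypes
    ds = generate_mink_like(2, seed=int(rng.integers(2**31 - 1)))
    io_mod.write_genepop(ds.genotypes, out / "mink_like.gen")
    io_mod.write_fasta(ds.alignment, out / "mink_like.fasta")
    ids_all = ds.genotypes.individuals + ds.alignment.ids
    pops_all = {**ds.genotypes.pop_of, **ds.alignment.pop_of}
    io_mod.write_sidecar(_sidecar_frame(ids_all, pops_all), out / "mink_like.tsv")
    paths["mink_genepop"] = out / "mink_like.gen"
    paths["mink_fasta"] = out / "mink_like.fasta"
    paths["mink_sidecar"] = out / "mink_like.tsv"
    return paths


def _sidecar_frame(ids, pop_of):
    import pandas as pd

    return pd.DataFrame(
        {"id": list(ids), "population": [pop_of[i] for i in ids]}
    )
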