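"""Shared fixtures: toy datasets, a session-scoped synthetic mink-like
dataset, and a synthetic stand-in for the deposited haplotype set."""

from __future__ import annotations

import numpy as np
import pytest

from minkpop.datamodel import GenotypeMatrix, HaplotypeAlignment
from minkpop.simulate import generate_mink_like


@pytest.fixture(scope="session")
def mink_dataset():
    """One full synthetic admixture-origin (scenario 2) dataset."""
    return generate_mink_like(2, seed=20240917)


@pytest.fixture()
def toy_alignment():
    seqs = ["ACGTACGTAC", "ACGTACGTAT", "ACGAACGTAT", "ACGTACGTAC"]
    ids = [f"s{i}" for i in range(4)]
    pops = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
    return HaplotypeAlignment(ids=ids, seqs=seqs, pop_of=pops)


def make_genotypes(geno_by_pop: dict[str, list[list[tuple[int, int]]]],
                   loci: list[str] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {pop: [per-individual list of (a,b)]}."""
    individuals, rows, pop_of = [], [], {}
    for pop, inds in geno_by_pop.items():
        for k, geno in enumerate(inds):
            name = f"{pop}_{k}"
            individuals.append(name)
            pop_of[name] = pop
            rows.append([list(pair) for pair in geno])
    alleles = np.array(rows)
    n_loci = alleles.shape[1]
    return GenotypeMatrix(
        individuals=individuals,
        loci=loci or [f"L{i}" for i in range(n_loci)],
        alleles=alleles,
        pop_of=pop_of,
    )


@pytest.fixture()
def toy_genotypes():
    """Two populations x 5 individuals x 2 loci, some missing data."""
    return make_genotypes(
        {
            "A": [
                [(10, 12), (20, 20)],
                [(10, 10), (20, 22)],
                [(12, 12), (20, 20)],
                [(10, 12), (22, 22)],
                [(12, 14), (-1, -1)],
            ],
            "B": [
                [(14, 14), (24, 24)],
                [(14, 16), (24, 26)],
                [(16, 16), (26, 26)],
                [(14, 14), (24, 26)],
                [(16, 14), (26, 26)],
            ],
        }
    )


def synthetic_deposited_haplotypes(seed: int = 1234) -> HaplotypeAlignment:
    """Synthetic stand-in for the deposited mtDNA control-region data.

    The real deposited sequences are not redistributable here, so this
    builds an alignment with the published dimensions: 157 sequences of a
    614-bp amplicon whose indel-containing columns reduce it to 476 sites,
    collapsing to 17 distinct haplotypes defined by 17 variable sites --
    a star-like northeastern core around a central haplotype shared with
    the southeast, three southeastern derivatives, and a single divergent
    western haplotype.
    """
    rng = np.random.default_rng(seed)
    L_full, L_trim, n_var = 614, 476, 17
    gap_cols = rng.choice(L_full, size=L_full - L_trim, replace=False)
    keep_cols = np.setdiff1d(np.arange(L_full), gap_cols)
    var_sites = rng.choice(keep_cols, size=n_var, replace=False)

    base = rng.choice(list("ACGT"), size=L_full)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}

    def mutate(seq, sites):
        s = seq.copy()
        for site in sites:
            s[site] = flip[s[site]]
        return s

    center = base
    haps = [center]
    for k in range(12):  # NE star: one private mutation each
        haps.append(mutate(center, [var_sites[k]]))
    se1 = mutate(center, [var_sites[12]])
    haps.append(se1)
    haps.append(mutate(se1, [var_sites[13]]))
    haps.append(mutate(se1, [var_sites[14]]))
    haps.append(mutate(center, var_sites[15:17]))  # W: two steps away
    assert len(haps) == 17

    # counts: NE n=84 (center 25 + 12 derivatives), SE n=30 (center shared
    # + 3 private), W n=43 (single haplotype)
    ne_counts = [25] + [5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 4]
    plan = [("NE", 0, ne_counts[0])]
    plan += [("NE", k, ne_counts[k]) for k in range(1, 13)]
    plan += [("SE", 0, 6), ("SE", 13, 9), ("SE", 14, 8), ("SE", 15, 7)]
    plan += [("W", 16, 43)]
    ids, seqs, pop_of = [], [], {}
    i = 0
    for pop, hap_ix, count in plan:
        hap = haps[hap_ix].copy()
        for _ in range(count):
            seq = hap.copy()
            # one random sequence per gap column carries the deletion
            ids.append(f"{pop}_{i:03d}")
            seqs.append(seq)
            pop_of[ids[-1]] = pop
            i += 1
    # distribute gaps: each gap column gets a '-' in one random sequence
    arr = np.array(seqs)
    for col in gap_cols:
        arr[rng.integers(0, len(ids)), col] = "-"
    seq_strs = ["".join(row) for row in arr]
    return HaplotypeAlignment(ids=ids, seqs=seq_strs, pop_of=pop_of)
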