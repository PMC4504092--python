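"""Core containers shared by every analysis stage.

Two kinds of marker data move through the package: aligned mitochondrial
control-region sequences (maternally inherited, effectively haploid) and
diploid microsatellite genotypes scored as integer repeat counts.  Both carry
sample -> population labels, and optionally sample -> river-drainage labels,
so that the same individuals can be analysed under a regional grouping or a
drainage grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGTN-")

#: sentinel for a missing allele in a genotype matrix
MISSING = -1


class AlignmentError(ValueError):
    """Raised when sequences cannot form a valid alignment."""


@dataclass
class HaplotypeAlignment:
    """Aligned equal-length sequences with per-sample population labels.

    Sequences are stored uppercase over the alphabet ``{A,C,G,T,N,-}``.
    """

    ids: list[str]
    seqs: list[str]
    pop_of: dict[str, str]
    drainage_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("empty alignment")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sample ids")
        self.seqs = [s.upper() for s in self.seqs]
        L = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"ragged alignment: {sid!r} has length {len(s)}, expected {L}"
                )
            bad = set(s) - VALID_BASES
            if bad:
                raise AlignmentError(f"invalid characters {bad} in {sid!r}")
        if L == 0:
            raise AlignmentError("zero-length alignment")
        missing = [i for i in self.ids if i not in self.pop_of]
        if missing:
            raise AlignmentError(f"samples without population label: {missing[:5]}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for i in self.ids:
            seen.setdefault(self.pop_of[i], None)
        return list(seen)

    def to_matrix(self) -> np.ndarray:
        """Alignment as an (n, L) array of single-byte characters."""
        return np.frombuffer(
            "".join(self.seqs).encode(), dtype="S1"
        ).reshape(self.n, self.length)

    def subset(self, ids: list[str]) -> "HaplotypeAlignment":
        idx = {i: k for k, i in enumerate(self.ids)}
        return HaplotypeAlignment(
            ids=list(ids),
            seqs=[self.seqs[idx[i]] for i in ids],
            pop_of={i: self.pop_of[i] for i in ids},
            drainage_of={i: self.drainage_of[i] for i in ids if i in self.drainage_of},
        )


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population copy counts.

    ``counts`` has one row per haplotype in first-occurrence order and one
    column per population; rows sum to the haplotype's total frequency.
    """

    haplotypes: list[str]
    populations: list[str]
    counts: np.ndarray  # (n_haplotypes, n_populations) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.haplotypes), len(self.populations)):
            raise ValueError("counts shape mismatch")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("haplotypes not distinct")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def expand(self) -> list[str]:
        """Reconstruct the multiset of sequences (total order: haplotype-major)."""
        out: list[str] = []
        for h, c in zip(self.haplotypes, self.total_counts):
            out.extend([h] * int(c))
        return out


@dataclass
class GenotypeMatrix:
    """Diploid microsatellite genotypes: individuals x loci pairs of repeat counts.

    ``alleles`` is an (n, n_loci, 2) integer array; :data:`MISSING` marks both
    entries of an untyped genotype (never only one).
    """

    individuals: list[str]
    loci: list[str]
    alleles: np.ndarray
    pop_of: dict[str, str]
    drainage_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, nl = len(self.individuals), len(self.loci)
        if self.alleles.shape != (n, nl, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {nl}, 2)"
            )
        a, b = self.alleles[..., 0], self.alleles[..., 1]
        half = (a == MISSING) ^ (b == MISSING)
        if half.any():
            raise ValueError("half-missing genotype (one allele present)")
        present = a != MISSING
        if (self.alleles[present.nonzero()] <= 0).any():
            raise ValueError("non-positive allele value")
        missing = [i for i in self.individuals if i not in self.pop_of]
        if missing:
            raise ValueError(f"individuals without population label: {missing[:5]}")

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.individuals:
            seen.setdefault(self.pop_of[i], None)
        return list(seen)

    def pop_codes(self, order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Integer population code per individual plus the label order used."""
        pops = order if order is not None else self.populations
        code = {p: k for k, p in enumerate(pops)}
        return np.array([code[self.pop_of[i]] for i in self.individuals]), pops

    def missing_mask(self) -> np.ndarray:
        """(n, n_loci) boolean, True where the genotype is missing."""
        return self.alleles[..., 0] == MISSING

    def subset(self, individuals: list[str]) -> "GenotypeMatrix":
        idx = {i: k for k, i in enumerate(self.individuals)}
        rows = [idx[i] for i in individuals]
        return GenotypeMatrix(
            individuals=list(individuals),
            loci=list(self.loci),
            alleles=self.alleles[rows],
            pop_of={i: self.pop_of[i] for i in individuals},
            drainage_of={
                i: self.drainage_of[i] for i in individuals if i in self.drainage_of
            },
        )

    def drop_poorly_typed(self, min_loci: int = 9) -> "GenotypeMatrix":
        """Drop individuals genotyped at fewer than ``min_loci`` loci."""
        ok = (~self.missing_mask()).sum(axis=1) >= min_loci
        keep = [i for i, k in zip(self.individuals, ok) if k]
        return self.subset(keep)


@dataclass
class GroupingScheme:
    """Two-level nesting: groups (regions) -> units (populations) -> individuals.

    Every individual belongs to exactly one unit and every unit to exactly one
    group; both properties are validated on construction.
    """

    name: str
    groups: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        seen_units: set[str] = set()
        seen_ind: set[str] = set()
        for g, units in self.groups.items():
            for u, members in units.items():
                if u in seen_units:
                    raise ValueError(f"unit {u!r} appears in more than one group")
                seen_units.add(u)
                for m in members:
                    if m in seen_ind:
                        raise ValueError(f"individual {m!r} in more than one unit")
                    seen_ind.add(m)

    @property
    def units(self) -> list[str]:
        return [u for units in self.groups.values() for u in units]

    @property
    def individuals(self) -> list[str]:
        return [m for units in self.groups.values() for mem in units.values() for m in mem]

    def unit_of(self) -> dict[str, str]:
        return {
            m: u
            for units in self.groups.values()
            for u, mem in units.items()
            for m in mem
        }

    def group_of_unit(self) -> dict[str, str]:
        return {u: g for g, units in self.groups.items() for u in units}

    @classmethod
    def from_labels(
        cls,
        name: str,
        unit_of: dict[str, str],
        group_of_unit: dict[str, str] | None = None,
    ) -> "GroupingScheme":
        """Build a scheme from flat label maps (one group per unit if none given)."""
        groups: dict[str, dict[str, list[str]]] = {}
        for ind, u in unit_of.items():
            g = (group_of_unit or {}).get(u, u)
            groups.setdefault(g, {}).setdefault(u, []).append(ind)
        return cls(name=name, groups=groups)


def collapse_haplotypes(aln: HaplotypeAlignment) -> HaplotypeTable:
    """Collapse an alignment into distinct haplotypes with per-population counts.

    Haplotype order is deterministic (first occurrence in the alignment).
    """
    pops = aln.populations
    pop_idx = {p: k for k, p in enumerate(pops)}
    order: dict[str, int] = {}
    rows: list[np.ndarray] = []
    for sid, seq in zip(aln.ids, aln.seqs):
        if seq not in order:
            order[seq] = len(rows)
            rows.append(np.zeros(len(pops), dtype=int))
        rows[order[seq]][pop_idx[aln.pop_of[sid]]] += 1
    return HaplotypeTable(
        haplotypes=list(order), populations=pops, counts=np.array(rows, dtype=int)
    )


def trim_gapped_columns(
    aln: HaplotypeAlignment, drop_ambiguous: bool = False
) -> HaplotypeAlignment:
    """Remove every column containing a gap (optionally also any ``N``).

    Columns with an indel in *any* sequence are excluded so that downstream
    site counts refer to positions scored in all samples.
    """
    mat = aln.to_matrix()
    bad = (mat == b"-").any(axis=0)
    if drop_ambiguous:
        bad |= (mat == b"N").any(axis=0)
    keep = ~bad
    if not keep.any():
        raise AlignmentError("all columns gapped; nothing left after trimming")
    seqs = [bytes(row[keep]).decode() for row in mat]
    return HaplotypeAlignment(
        ids=list(aln.ids),
        seqs=seqs,
        pop_of=dict(aln.pop_of),
        drainage_of=dict(aln.drainage_of),
    )
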