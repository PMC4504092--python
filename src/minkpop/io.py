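"""Readers and writers for the exchange formats used by the package.

Sequences travel as FASTA, diploid microsatellite genotypes as Genepop text
(2- or 3-digit allele codes), and sample metadata (population, drainage,
coordinates) as a sidecar TSV keyed by sample id.  Population labels are never
parsed out of FASTA headers: deposited sequence records carry no reliable
population information, so the sidecar is authoritative.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import MISSING, AlignmentError, GenotypeMatrix, HaplotypeAlignment

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_sidecar",
    "write_sidecar",
    "read_genepop",
    "write_genepop",
]


def read_sidecar(path: str | Path) -> pd.DataFrame:
    """Read the metadata TSV (columns: id, population[, drainage, lat, lon])."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns or "population" not in df.columns:
        raise ValueError("sidecar TSV needs at least 'id' and 'population' columns")
    return df.set_index("id", drop=False)


def write_sidecar(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fasta(
    path: str | Path,
    sidecar: str | Path | pd.DataFrame | None = None,
    default_population: str = "pop1",
) -> HaplotypeAlignment:
    """Read an aligned FASTA into a :class:`HaplotypeAlignment`.

    Population labels come from ``sidecar`` (path or DataFrame); samples absent
    from the sidecar fall back to ``default_population``.
    """
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(f"ragged FASTA: record lengths {sorted(lengths)}")
    meta = None
    if sidecar is not None:
        meta = sidecar if isinstance(sidecar, pd.DataFrame) else read_sidecar(sidecar)
    pop_of, drainage_of = {}, {}
    for sid in ids:
        if meta is not None and sid in meta.index:
            row = meta.loc[sid]
            pop_of[sid] = str(row["population"])
            if "drainage" in meta.columns and not pd.isna(row.get("drainage")):
                drainage_of[sid] = str(row["drainage"])
        else:
            pop_of[sid] = default_population
    return HaplotypeAlignment(ids=ids, seqs=seqs, pop_of=pop_of, drainage_of=drainage_of)


def write_fasta(aln: HaplotypeAlignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- Genepop ----------------------------------------------------------------

def _parse_genepop_code(tok: str, n_loci_hint: int | None = None) -> tuple[int, int]:
    """Split a Genepop diploid code ('092100' or '0911') into two alleles."""
    if len(tok) % 2 != 0 or len(tok) not in (4, 6):
        raise ValueError(f"bad genotype code {tok!r} (need 4 or 6 digits)")
    w = len(tok) // 2
    a, b = int(tok[:w]), int(tok[w:])
    return (MISSING if a == 0 else a, MISSING if b == 0 else b)


def read_genepop(path: str | Path, pop_names: list[str] | None = None) -> GenotypeMatrix:
    """Read a Genepop 2- or 3-digit file into a :class:`GenotypeMatrix`.

    Populations appear in file order and are named ``pop1..popK`` unless
    ``pop_names`` overrides them.  ``000``/``00`` codes mean a missing allele;
    a half-missing genotype is rejected by the container invariant.
    """
    text = Path(path).read_text()
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ValueError("truncated Genepop file")
    # line 0: title. Locus names: one per line, or one comma-separated line.
    i = 1
    loci: list[str] = []
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend([t.strip() for t in lines[i].split(",") if t.strip()])
        i += 1
    if not loci:
        raise ValueError("no locus names before first 'Pop'")
    individuals: list[str] = []
    rows: list[list[int]] = []
    pop_of: dict[str, str] = {}
    pop_idx = -1
    counter = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        if pop_idx < 0:
            raise ValueError("genotype line before first 'Pop'")
        if "," not in lines[i]:
            raise ValueError(f"genotype line without comma: {lines[i]!r}")
        name, geno = lines[i].split(",", 1)
        name = name.strip()
        if not name or name in pop_of:
            counter += 1
            name = f"{name or 'ind'}_{counter}"
        toks = geno.split()
        if len(toks) != len(loci):
            raise ValueError(
                f"{name!r}: {len(toks)} genotypes for {len(loci)} loci"
            )
        pair_row: list[int] = []
        for tok in toks:
            a, b = _parse_genepop_code(tok)
            # one missing allele makes the whole genotype missing
            if a == MISSING or b == MISSING:
                a = b = MISSING
            pair_row.extend((a, b))
        individuals.append(name)
        rows.append(pair_row)
        label = (
            pop_names[pop_idx]
            if pop_names is not None and pop_idx < len(pop_names)
            else f"pop{pop_idx + 1}"
        )
        pop_of[name] = label
        i += 1
    alleles = np.array(rows, dtype=np.int64).reshape(len(individuals), len(loci), 2)
    return GenotypeMatrix(
        individuals=individuals, loci=loci, alleles=alleles, pop_of=pop_of
    )


def write_genepop(
    g: GenotypeMatrix, path: str | Path, title: str = "minkpop export", digits: int = 3
) -> None:
    """Write a GenotypeMatrix as Genepop text (3-digit codes by default)."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    buf = _io.StringIO()
    buf.write(title + "\n")
    for loc in g.loci:
        buf.write(loc + "\n")
    codes, pops = g.pop_codes()
    for k, _pop in enumerate(pops):
        buf.write("Pop\n")
        for i in np.flatnonzero(codes == k):
            parts = []
            for l in range(g.n_loci):
                a, b = g.alleles[i, l]
                a = 0 if a == MISSING else int(a)
                b = 0 if b == MISSING else int(b)
                parts.append(f"{a:0{digits}d}{b:0{digits}d}")
            buf.write(f"{g.individuals[i]}, " + " ".join(parts) + "\n")
    Path(path).write_text(buf.getvalue())
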