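"""Genome assembly and taxonomy input.

Reads FASTA assemblies (plain or gzip), applies the plasmid-exclusion rule,
and loads the accession -> species/genus/phylum/domain taxonomy table that
drives ambiguity screening. Total assembly length S is the denominator of
the homologous coverage ratio, so everything downstream depends on the
lengths established here.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import EmptyAssemblyError, FormatError, InputError

__all__ = [
    "Contig",
    "GenomeAssembly",
    "TaxonomyRecord",
    "read_fasta",
    "write_fasta",
    "filter_plasmids",
    "load_taxonomy",
    "write_taxonomy",
]

#: Minimum fraction of A/C/G/T/N for a record to pass without a warning.
_NUCLEOTIDE_DOMINANCE = 0.9


@dataclass(frozen=True)
class Contig:
    """A single contig: identifier, free-text description, uppercase sequence."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeAssembly:
    """One accession's contig set.

    ``total_length`` (the S term of the coverage ratio) is always the sum of
    contig lengths, recomputed rather than stored so it can never drift from
    the contigs.
    """

    accession: str
    contigs: tuple[Contig, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.accession:
            raise InputError("assembly accession must be non-empty")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def contig_lengths(self) -> dict[str, int]:
        return {c.id: len(c) for c in self.contigs}


@dataclass(frozen=True)
class TaxonomyRecord:
    accession: str
    species: str
    genus: str
    phylum: str
    domain: str

    def taxon(self, level: str) -> str:
        if level not in ("species", "genus", "phylum", "domain"):
            raise InputError(f"unknown taxonomic level: {level!r}")
        return getattr(self, level)


def _open_text(path: Path):
    # Sniff gzip by magic bytes rather than extension.
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, accession: str | None = None) -> GenomeAssembly:
    """Read a (possibly gzip-compressed) FASTA file into a :class:`GenomeAssembly`.

    The accession defaults to the filename stem (with ``.fa.gz``-style double
    suffixes stripped), matching the convention of naming assembly files after
    their accession.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    if accession is None:
        accession = path.name
        for suffix in (".gz", ".fasta", ".fa", ".fna"):
            if accession.endswith(suffix):
                accession = accession[: -len(suffix)]
    contigs = []
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq).upper()
            nuc = sum(seq.count(b) for b in "ACGTN")
            if seq and nuc / len(seq) < _NUCLEOTIDE_DOMINANCE:
                warnings.warn(
                    f"record {record.id} in {path.name} does not look like "
                    "nucleotide sequence; retained",
                    stacklevel=2,
                )
            contigs.append(Contig(record.id, seq, record.description))
    if not contigs:
        raise InputError(f"no FASTA records in {path}")
    return GenomeAssembly(accession, tuple(contigs))


def write_fasta(genome: GenomeAssembly, path: str | Path, width: int = 80) -> Path:
    """Write an assembly to plain FASTA (round-trips through :func:`read_fasta`)."""
    path = Path(path)
    with open(path, "w") as fh:
        for contig in genome.contigs:
            header = contig.description if contig.description else contig.id
            fh.write(f">{header}\n")
            for i in range(0, len(contig.sequence), width):
                fh.write(contig.sequence[i : i + width] + "\n")
    return path


def filter_plasmids(genome: GenomeAssembly) -> GenomeAssembly:
    """Drop contigs whose header mentions "plasmid" (case-insensitive).

    Plasmid replicons are excluded from coverage-ratio scoring; keyword
    matching on the FASTA description follows RefSeq header conventions.
    Idempotent. Raises :class:`EmptyAssemblyError` if nothing remains.
    """
    kept = tuple(
        c
        for c in genome.contigs
        if "plasmid" not in f"{c.id} {c.description}".lower()
    )
    if not kept:
        raise EmptyAssemblyError(
            f"{genome.accession}: all contigs are plasmids; nothing to score"
        )
    if len(kept) == len(genome.contigs):
        return genome
    return GenomeAssembly(genome.accession, kept)


_TAXONOMY_COLUMNS = ("accession", "species", "genus", "phylum", "domain")


def load_taxonomy(path: str | Path) -> dict[str, TaxonomyRecord]:
    """Load the taxonomy TSV (header: accession species genus phylum domain).

    Returns a mapping accession -> :class:`TaxonomyRecord`. Duplicate
    accessions and missing columns are format errors.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"taxonomy file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _TAXONOMY_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"taxonomy table {path} lacks column(s): {', '.join(missing)}")
    dupes = table["accession"][table["accession"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"duplicate accession(s) in {path}: {', '.join(sorted(set(dupes)))}")
    return {
        row.accession: TaxonomyRecord(
            row.accession, row.species, row.genus, row.phylum, row.domain
        )
        for row in table.itertuples()
    }


def write_taxonomy(
    records: Iterable[TaxonomyRecord] | Mapping[str, TaxonomyRecord],
    path: str | Path,
) -> Path:
    if isinstance(records, Mapping):
        records = records.values()
    frame = pd.DataFrame(
        [[r.accession, r.species, r.genus, r.phylum, r.domain] for r in records],
        columns=list(_TAXONOMY_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False)
    return Path(path)
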