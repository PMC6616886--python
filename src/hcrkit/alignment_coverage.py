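"""Precise homologous coverage ratio from pairwise local alignments.

Alignment blocks (from LAST or any BLAST-like aligner) are filtered at an
E-value threshold (strictly below 1e-10 by default), projected onto both
genomes, and merged into per-contig interval unions, giving covered lengths
H_A and H_B. The homologous coverage ratio is then

    HCR(A, B) = (H_A + H_B) / (S_A + S_B)

with S_A, S_B the total assembly lengths. Merging overlapping blocks keeps
H_X <= S_X, so the ratio is always in [0, 1]; distinct repeat loci still
each contribute coverage because they occupy distinct coordinates.

All coordinates are 0-based half-open internally. The MAF reader converts
start+length (flipping reverse-strand coordinates to the forward strand);
the tabular reader accepts 12-column BLAST outfmt-6 rows, converting
1-based inclusive coordinates and swapping reversed subject intervals.
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import (
    AlignerUnavailableError,
    ConfigurationError,
    FormatError,
    InputError,
)
from .genome_io import GenomeAssembly, write_fasta
from .kmer_profile import PairScore

__all__ = [
    "AlignmentBlock",
    "CoverageResult",
    "parse_alignments",
    "filter_by_evalue",
    "union_length",
    "hcr_alignment",
    "run_external_aligner",
    "write_coverage_results",
]

DEFAULT_EVALUE_THRESHOLD = 1e-10


@dataclass(frozen=True)
class AlignmentBlock:
    """One local alignment between contig_a of genome A and contig_b of B.

    Both intervals are 0-based half-open on the forward strand of their
    contig; ``strand_b`` records whether B aligned reverse-complemented.
    """

    accession_a: str
    accession_b: str
    contig_a: str
    contig_b: str
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    strand_b: Literal["+", "-"]
    evalue: float

    def __post_init__(self) -> None:
        for name, (start, end) in (("a", self.interval_a), ("b", self.interval_b)):
            if start >= end:
                raise InputError(
                    f"interval_{name} must satisfy start < end, got ({start}, {end})"
                )
        if self.evalue < 0:
            raise InputError(f"negative E-value: {self.evalue}")


@dataclass(frozen=True)
class CoverageResult:
    """Coverage terms and final ratio for one genome pair."""

    accession_a: str
    accession_b: str
    h_a: int
    h_b: int
    s_a: int
    s_b: int
    hcr: float
    n_blocks_used: int
    n_blocks_filtered: int

    def as_pair_score(self) -> PairScore:
        return PairScore(self.accession_a, self.accession_b, "alignment", self.hcr)


def parse_alignments(
    path: str | Path,
    dialect: str,
    accession_a: str = "A",
    accession_b: str = "B",
) -> list[AlignmentBlock]:
    """Parse an alignment file in the ``maf`` or ``tabular`` dialect.

    Contig names come from the file; the genome accessions are supplied by
    the caller (pairwise alignment files carry contig, not assembly, ids).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    if dialect == "maf":
        return _parse_maf(path, accession_a, accession_b)
    if dialect == "tabular":
        return _parse_tabular(path, accession_a, accession_b)
    raise ConfigurationError(f"unknown alignment dialect: {dialect!r}")


def _maf_forward_interval(start: int, size: int, strand: str, src_size: int) -> tuple[int, int]:
    # MAF gives start on the aligned strand; flip to forward-strand coords.
    if strand == "+":
        return (start, start + size)
    return (src_size - start - size, src_size - start)


def _parse_maf(path: Path, accession_a: str, accession_b: str) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    a_line: tuple[int, str] | None = None  # (line number, text)
    s_lines: list[tuple[int, list[str]]] = []

    def flush() -> None:
        nonlocal a_line, s_lines
        if a_line is None:
            return
        lineno, text = a_line
        if len(s_lines) != 2:
            raise FormatError(
                f"{path}:{lineno}: alignment block has {len(s_lines)} sequence "
                "lines, expected 2"
            )
        evalue = None
        for token in text.split()[1:]:
            key, _, value = token.partition("=")
            if key in ("E", "e", "expect"):
                try:
                    evalue = float(value)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad E-value {value!r}") from exc
        if evalue is None:
            raise FormatError(
                f"{path}:{lineno}: alignment block lacks an E= attribute; "
                "an E-value is required for homology filtering"
            )
        parsed = []
        for s_lineno, fields in s_lines:
            if len(fields) < 7:
                raise FormatError(f"{path}:{s_lineno}: malformed s-line")
            try:
                name = fields[1]
                start, size = int(fields[2]), int(fields[3])
                strand = fields[4]
                src_size = int(fields[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{s_lineno}: malformed s-line") from exc
            if strand not in "+-" or size <= 0:
                raise FormatError(f"{path}:{s_lineno}: malformed s-line")
            parsed.append((name, _maf_forward_interval(start, size, strand, src_size), strand))
        (name_a, ival_a, strand_a), (name_b, ival_b, strand_b) = parsed
        blocks.append(
            AlignmentBlock(
                accession_a,
                accession_b,
                name_a,
                name_b,
                ival_a,
                ival_b,
                "+" if strand_a == strand_b else "-",
                evalue,
            )
        )
        a_line = None
        s_lines = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if line.startswith("a"):
                flush()
                a_line = (lineno, line)
            elif line.startswith("s"):
                if a_line is None:
                    raise FormatError(f"{path}:{lineno}: s-line outside an alignment block")
                s_lines.append((lineno, line.split()))
            # other line types (#, q, i, p, blank) are ignored
    flush()
    return blocks


def _parse_tabular(path: Path, accession_a: str, accession_b: str) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns "
                    f"(BLAST outfmt 6), got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed record") from exc
            if qstart > qend:
                raise FormatError(f"{path}:{lineno}: reversed query coordinates")
            strand_b = "+"
            if sstart > send:
                sstart, send = send, sstart
                strand_b = "-"
            blocks.append(
                AlignmentBlock(
                    accession_a,
                    accession_b,
                    qseqid,
                    sseqid,
                    (qstart - 1, qend),
                    (sstart - 1, send),
                    strand_b,
                    evalue,
                )
            )
    return blocks


def filter_by_evalue(
    blocks: Iterable[AlignmentBlock], threshold: float = DEFAULT_EVALUE_THRESHOLD
) -> list[AlignmentBlock]:
    """Keep blocks with E-value strictly below ``threshold``."""
    return [b for b in blocks if b.evalue < threshold]


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Number of distinct bases covered by half-open intervals on one contig."""
    ivals = sorted(intervals)
    total = 0
    cur_start = cur_end = None
    for start, end in ivals:
        if start >= end:
            raise InputError(f"invalid interval ({start}, {end}): start must be < end")
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        elif end > cur_end:
            cur_end = end
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def _covered_per_genome(
    blocks: Sequence[AlignmentBlock],
    side: str,
    lengths: dict[str, int],
    accession: str,
) -> int:
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for block in blocks:
        contig = getattr(block, f"contig_{side}")
        interval = getattr(block, f"interval_{side}")
        if contig not in lengths:
            raise InputError(
                f"block {block.contig_a}:{block.interval_a}/"
                f"{block.contig_b}:{block.interval_b} references unknown "
                f"contig {contig!r} of {accession}"
            )
        if interval[1] > lengths[contig]:
            raise InputError(
                f"block {block.contig_a}:{block.interval_a}/"
                f"{block.contig_b}:{block.interval_b} exceeds length "
                f"{lengths[contig]} of contig {contig!r} ({accession})"
            )
        per_contig.setdefault(contig, []).append(interval)
    return sum(union_length(ivals) for ivals in per_contig.values())


def hcr_alignment(
    blocks: Iterable[AlignmentBlock],
    genome_a: GenomeAssembly,
    genome_b: GenomeAssembly,
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> CoverageResult:
    """E-value-filter blocks, merge coverage on both genomes, take the ratio."""
    blocks = list(blocks)
    used = filter_by_evalue(blocks, threshold)
    h_a = _covered_per_genome(used, "a", genome_a.contig_lengths(), genome_a.accession)
    h_b = _covered_per_genome(used, "b", genome_b.contig_lengths(), genome_b.accession)
    s_a, s_b = genome_a.total_length, genome_b.total_length
    if s_a + s_b == 0:
        raise InputError("both assemblies are empty")
    return CoverageResult(
        genome_a.accession,
        genome_b.accession,
        h_a,
        h_b,
        s_a,
        s_b,
        (h_a + h_b) / (s_a + s_b),
        len(used),
        len(blocks) - len(used),
    )


def run_external_aligner(
    genome_a: GenomeAssembly,
    genome_b: GenomeAssembly,
    command_template: str,
    workdir: str | Path | None = None,
) -> Path:
    """Run a user-configured pairwise aligner and return its output path.

    ``command_template`` must contain the placeholders ``{query}``,
    ``{target}`` and ``{output}``; the genomes are written as FASTA and the
    filled command is executed. This is a convenience only — alignment files
    can always be produced out-of-band and fed to :func:`parse_alignments`.
    """
    for placeholder in ("{query}", "{target}", "{output}"):
        if placeholder not in command_template:
            raise ConfigurationError(
                f"aligner command template lacks the {placeholder} placeholder"
            )
    executable = shlex.split(command_template)[0]
    if shutil.which(executable) is None:
        raise AlignerUnavailableError(
            f"aligner executable {executable!r} not found on PATH; align the "
            "genomes externally and pass the file to parse_alignments instead"
        )
    workdir = Path(workdir) if workdir is not None else Path(tempfile.mkdtemp(prefix="hcr_aln_"))
    workdir.mkdir(parents=True, exist_ok=True)
    query = write_fasta(genome_a, workdir / f"{genome_a.accession}.fasta")
    target = write_fasta(genome_b, workdir / f"{genome_b.accession}.fasta")
    output = workdir / f"{genome_a.accession}__{genome_b.accession}.aln"
    command = command_template.format(query=query, target=target, output=output)
    proc = subprocess.run(shlex.split(command), capture_output=True, text=True)
    if proc.returncode != 0:
        raise AlignerUnavailableError(
            f"aligner exited with code {proc.returncode}: {proc.stderr.strip()[:500]}"
        )
    return output


def write_coverage_results(results: Iterable[CoverageResult], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "accession_a\taccession_b\tS_a\tS_b\tH_a\tH_b\thcr\t"
            "n_blocks_used\tn_blocks_filtered\n"
        )
        for r in results:
            fh.write(
                f"{r.accession_a}\t{r.accession_b}\t{r.s_a}\t{r.s_b}\t"
                f"{r.h_a}\t{r.h_b}\t{r.hcr:.9f}\t{r.n_blocks_used}\t{r.n_blocks_filtered}\n"
            )
    return path
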