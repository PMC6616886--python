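"""Fast approximate coverage ratio from distinct k-mer containment.

A genome's profile is the set of its distinct k-mers (membership only —
multiplicity is deliberately ignored). For two genomes A and B the
approximate homologous coverage ratio is

    HCR_kmer(A, B) = (Hit_A + Hit_B) / (HS_A + HS_B)

where HS_X is the number of distinct k-mers of X and Hit_X the number of
X's k-mers also present in the other genome's set. This cross-containment
reading makes the ratio symmetric, 1 on identical genomes and bounded by 1,
and is cheap enough for all-vs-all screening of thousands of assemblies;
the alignment-based ratio (:mod:`hcrkit.alignment_coverage`) then refines
candidate pairs.

k defaults to 12 (4^12 ~ 1.7e7 possible keys: selective for bacterial-size
genomes, light in memory). K-mers are strand-canonicalized by default since
assembly orientation is arbitrary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import ConfigurationError, EmptyProfileError, InputError
from .genome_io import GenomeAssembly

__all__ = [
    "KmerProfile",
    "PairScore",
    "build_profile",
    "hcr_kmer",
    "all_vs_all",
    "write_scores",
    "read_scores",
]

DEFAULT_K = 12

_RC = str.maketrans("ACGT", "TGCA")
_VALID_RUN = re.compile(r"[ACGT]+")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class KmerProfile:
    """Distinct-k-mer membership set of one genome (size = the HS term)."""

    accession: str
    k: int
    canonical: bool
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PairScore:
    """An HCR value for one unordered genome pair."""

    accession_a: str
    accession_b: str
    method: Literal["kmer", "alignment"]
    hcr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.hcr <= 1.0:
            raise InputError(
                f"hcr out of [0,1] for {self.accession_a}/{self.accession_b}: {self.hcr}"
            )

    @property
    def key(self) -> tuple[str, str]:
        """Order-independent pair key: PairScore(a,b) and (b,a) share it."""
        return tuple(sorted((self.accession_a, self.accession_b)))


def build_profile(
    genome: GenomeAssembly, k: int = DEFAULT_K, canonical: bool = True
) -> KmerProfile:
    """Collect all distinct length-k windows of a genome.

    Windows containing any non-ACGT symbol are skipped, and windows never
    span contig boundaries. With ``canonical`` each k-mer is collapsed with
    its reverse complement (lexicographic minimum kept).
    """
    if k < 3:
        raise ConfigurationError(f"k must be >= 3, got {k}")
    if not genome.contigs:
        raise EmptyProfileError(f"{genome.accession}: empty assembly")
    members: set[str] = set()
    add = members.add
    for contig in genome.contigs:
        for run in _VALID_RUN.findall(contig.sequence):
            if canonical:
                rc = run.translate(_RC)[::-1]
                n = len(run)
                for i in range(n - k + 1):
                    kmer = run[i : i + k]
                    kmer_rc = rc[n - k - i : n - i]
                    add(kmer if kmer <= kmer_rc else kmer_rc)
            else:
                for i in range(len(run) - k + 1):
                    add(run[i : i + k])
    if not members:
        raise EmptyProfileError(
            f"{genome.accession}: no valid window of length {k} "
            "(contigs shorter than k or interrupted by ambiguous bases)"
        )
    return KmerProfile(genome.accession, k, canonical, frozenset(members))


def _check_compatible(a: KmerProfile, b: KmerProfile) -> None:
    if a.k != b.k:
        raise ConfigurationError(f"profiles built with different k: {a.k} vs {b.k}")
    if a.canonical != b.canonical:
        raise ConfigurationError("profiles differ in strand canonicalization")


def hcr_kmer(profile_a: KmerProfile, profile_b: KmerProfile) -> PairScore:
    """Approximate coverage ratio (Hit_A + Hit_B) / (HS_A + HS_B)."""
    _check_compatible(profile_a, profile_b)
    shared = len(profile_a.members & profile_b.members)
    # Hit_A and Hit_B both equal the intersection cardinality under the
    # symmetric cross-containment reading.
    hcr = (shared + shared) / (profile_a.size + profile_b.size)
    return PairScore(profile_a.accession, profile_b.accession, "kmer", hcr)


def all_vs_all(profiles: Sequence[KmerProfile]) -> list[PairScore]:
    """Score every unordered pair, in lexicographic accession order."""
    if len(profiles) < 2:
        raise InputError("all-vs-all needs at least 2 profiles")
    ordered = sorted(profiles, key=lambda p: p.accession)
    for other in ordered[1:]:
        _check_compatible(ordered[0], other)
    return [hcr_kmer(a, b) for a, b in combinations(ordered, 2)]


def write_scores(scores: Iterable[PairScore], path: str | Path) -> Path:
    """Write pair scores as TSV with hcr printed to 9 decimal places."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("accession_a\taccession_b\tmethod\thcr\n")
        for s in scores:
            fh.write(f"{s.accession_a}\t{s.accession_b}\t{s.method}\t{s.hcr:.9f}\n")
    return path


def read_scores(path: str | Path) -> list[PairScore]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"scores file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype={"accession_a": str, "accession_b": str})
    required = {"accession_a", "accession_b", "method", "hcr"}
    if not required.issubset(table.columns):
        raise InputError(
            f"scores file {path} lacks column(s): {', '.join(sorted(required - set(table.columns)))}"
        )
    return [
        PairScore(row.accession_a, row.accession_b, row.method, float(row.hcr))
        for row in table.itertuples()
    ]
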