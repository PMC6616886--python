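"""Synthetic genomes with planted homology for end-to-end testing.

The generator emulates the one property the coverage-ratio statistics
measure — what fraction of two genomes is shared — while keeping every
planted quantity exact and closed-form:

* backgrounds are i.i.d. uniform A/C/G/T (spurious k-mer sharing between
  unrelated 100 kb genomes at k=12 is ~L²/4^k, well under a percent);
* shared material is copied in non-overlapping segments, optionally with
  point substitutions but never indels, so planted coordinates stay exact
  and double as a ready-made alignment fixture;
* a planted taxonomy gives every genome of a genus a common genus backbone
  (within-genus sharing), every genome a common global backbone
  (between-genus sharing), and optionally one cross-genus genome pair an
  extra private shared segment — the planted classification ambiguity.

Everything is driven by numpy's PCG64 generator, so a seed fixes the
output bit-for-bit across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GenerationError, InputError
from .genome_io import Contig, GenomeAssembly, TaxonomyRecord

__all__ = [
    "SyntheticPairSpec",
    "PlantedSegment",
    "SyntheticPair",
    "TaxonomyFixture",
    "random_genome",
    "make_pair",
    "make_taxonomy_fixture",
    "emit_alignment_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _indices_to_seq(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode("ascii")


def _random_indices(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def random_genome(
    length: int,
    seed: int,
    accession: str = "synthetic",
    contig_id: str | None = None,
) -> GenomeAssembly:
    """A single-contig genome of i.i.d. uniform bases, reproducible by seed."""
    if length <= 0:
        raise InputError(f"genome length must be positive, got {length}")
    rng = np.random.default_rng(seed)
    contig_id = contig_id or f"{accession}_ctg1"
    seq = _indices_to_seq(_random_indices(rng, length))
    return GenomeAssembly(accession, (Contig(contig_id, seq, contig_id),))


@dataclass(frozen=True)
class SyntheticPairSpec:
    """Parameters for one planted-homology genome pair."""

    length_a: int = 100_000
    length_b: int = 100_000
    shared_fraction: float = 0.5
    substitution_rate: float = 0.0
    segment_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_a <= 0 or self.length_b <= 0:
            raise InputError("genome lengths must be positive")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise InputError("shared_fraction must be in [0, 1]")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise InputError("substitution_rate must be in [0, 1)")
        if self.segment_count < 1:
            raise InputError("segment_count must be >= 1")
        if self.shared_fraction * self.length_a > self.length_b:
            raise InputError(
                "shared_fraction * length_a exceeds length_b; the copied "
                "material cannot fit in genome B"
            )


@dataclass(frozen=True)
class PlantedSegment:
    """One copied segment: source in A, destination in B, substitution count."""

    start_a: int
    start_b: int
    length: int
    n_substitutions: int = 0

    @property
    def interval_a(self) -> tuple[int, int]:
        return (self.start_a, self.start_a + self.length)

    @property
    def interval_b(self) -> tuple[int, int]:
        return (self.start_b, self.start_b + self.length)


@dataclass(frozen=True)
class SyntheticPair:
    genome_a: GenomeAssembly
    genome_b: GenomeAssembly
    planted_fraction_a: float
    planted_fraction_b: float
    segments: tuple[PlantedSegment, ...] = field(default_factory=tuple)


def _segment_lengths(total: int, count: int) -> list[int]:
    base, extra = divmod(total, count)
    lengths = [base + (1 if i < extra else 0) for i in range(count)]
    return [l for l in lengths if l > 0]


def _place_segments(
    rng: np.random.Generator, genome_length: int, lengths: Sequence[int]
) -> list[int]:
    # one segment per equal-width slot keeps placements non-overlapping
    slot = genome_length // len(lengths)
    starts = []
    for i, seg_len in enumerate(lengths):
        if seg_len > slot:
            raise GenerationError(
                f"cannot place a {seg_len} bp segment in a {slot} bp slot; "
                "use fewer or shorter segments"
            )
        starts.append(i * slot + int(rng.integers(0, slot - seg_len + 1)))
    return starts


def _mutate(
    rng: np.random.Generator, idx: np.ndarray, rate: float
) -> tuple[np.ndarray, int]:
    if rate == 0.0:
        return idx, 0
    hit = rng.random(idx.size) < rate
    if not hit.any():
        return idx, 0
    out = idx.copy()
    # shift by 1..3 mod 4: always a *different* base
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out, int(hit.sum())


def make_pair(spec: SyntheticPairSpec) -> SyntheticPair:
    """Generate a genome pair with an exactly known shared fraction.

    Genome A is random; genome B is a random background into which
    ``segment_count`` non-overlapping segments of A (totalling
    ``shared_fraction * length_a`` bases) are copied, each independently
    mutated at ``substitution_rate``. The returned planted fractions are
    exact (copied bases over genome length, per genome).
    """
    rng = np.random.default_rng(spec.seed)
    idx_a = _random_indices(rng, spec.length_a)
    idx_b = _random_indices(rng, spec.length_b)

    total = round(spec.shared_fraction * spec.length_a)
    segments: list[PlantedSegment] = []
    if total > 0:
        lengths = _segment_lengths(total, spec.segment_count)
        starts_a = _place_segments(rng, spec.length_a, lengths)
        starts_b = _place_segments(rng, spec.length_b, lengths)
        for seg_len, sa, sb in zip(lengths, starts_a, starts_b):
            copied, n_sub = _mutate(rng, idx_a[sa : sa + seg_len], spec.substitution_rate)
            idx_b[sb : sb + seg_len] = copied
            segments.append(PlantedSegment(sa, sb, seg_len, n_sub))

    genome_a = GenomeAssembly("synthA", (Contig("synthA_ctg1", _indices_to_seq(idx_a)),))
    genome_b = GenomeAssembly("synthB", (Contig("synthB_ctg1", _indices_to_seq(idx_b)),))
    return SyntheticPair(
        genome_a,
        genome_b,
        total / spec.length_a,
        total / spec.length_b,
        tuple(segments),
    )


@dataclass(frozen=True)
class TaxonomyFixture:
    genomes: tuple[GenomeAssembly, ...]
    taxonomy: dict[str, TaxonomyRecord]
    ambiguous_accessions: tuple[str, str] | None


def make_taxonomy_fixture(
    n_genera: int = 3,
    genomes_per_genus: int = 3,
    intra_fraction: float = 0.3,
    inter_fraction: float = 0.05,
    ambiguous_pair: tuple[int, int] | None = None,
    ambiguous_fraction: float = 0.5,
    genome_length: int = 20_000,
    seed: int = 0,
) -> TaxonomyFixture:
    """A planted taxonomy: genus backbones, a global backbone, one anomaly.

    Every genome of genus g carries a copy of genus g's backbone
    (``intra_fraction − inter_fraction`` of its length) plus a copy of the
    global backbone (``inter_fraction``), so within-genus pairs share
    ``intra_fraction`` of their genomes and cross-genus pairs
    ``inter_fraction``. With ``ambiguous_pair=(i, j)`` the first genome of
    genus i and the first genome of genus j additionally share a private
    segment raising their pairwise sharing to ``ambiguous_fraction`` —
    a cross-genus pair more similar than any within-genus pair, which the
    anchored screen must flag.
    """
    if n_genera < 1 or genomes_per_genus < 1:
        raise InputError("need at least one genus and one genome per genus")
    if not 0.0 <= inter_fraction <= intra_fraction <= 1.0:
        raise InputError(
            "fractions must satisfy 0 <= inter_fraction <= intra_fraction <= 1"
        )
    genus_len = round((intra_fraction - inter_fraction) * genome_length)
    global_len = round(inter_fraction * genome_length)
    amb_len = 0
    if ambiguous_pair is not None:
        i, j = ambiguous_pair
        if i == j or not (0 <= i < n_genera and 0 <= j < n_genera):
            raise InputError(f"invalid ambiguous genus pair: {ambiguous_pair}")
        if ambiguous_fraction <= intra_fraction:
            raise InputError(
                "ambiguous_fraction must exceed intra_fraction to plant an anomaly"
            )
        amb_len = round((ambiguous_fraction - inter_fraction) * genome_length)
    if genus_len + global_len + amb_len > genome_length:
        raise InputError(
            "fractions are infeasible: genus backbone + global backbone + "
            "ambiguous segment exceed the genome length"
        )

    rng = np.random.default_rng(seed)
    global_backbone = _random_indices(rng, global_len)
    genus_backbones = [_random_indices(rng, genus_len) for _ in range(n_genera)]
    amb_segment = _random_indices(rng, amb_len)

    n_phyla = max(1, (n_genera + 1) // 2)
    genomes: list[GenomeAssembly] = []
    taxonomy: dict[str, TaxonomyRecord] = {}
    ambiguous_accessions = None
    for g in range(n_genera):
        genus = f"Genus_{g + 1:02d}"
        phylum = f"Phylum_{(g % n_phyla) + 1:02d}"
        for m in range(genomes_per_genus):
            accession = f"SYN_{g + 1:02d}_{m + 1:02d}"
            is_amb = (
                ambiguous_pair is not None and m == 0 and g in ambiguous_pair
            )
            parts = [genus_backbones[g], global_backbone]
            if is_amb:
                parts.append(amb_segment)
            fixed = int(sum(p.size for p in parts))
            parts.append(_random_indices(rng, genome_length - fixed))
            idx = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
            genomes.append(
                GenomeAssembly(accession, (Contig(f"{accession}_ctg1", _indices_to_seq(idx)),))
            )
            taxonomy[accession] = TaxonomyRecord(
                accession, f"{genus} sp{m + 1:03d}", genus, phylum, "Bacteria"
            )
            if is_amb:
                if ambiguous_accessions is None:
                    ambiguous_accessions = (accession,)
                else:
                    ambiguous_accessions = (*ambiguous_accessions, accession)
    if ambiguous_accessions is not None and len(ambiguous_accessions) != 2:
        raise GenerationError("failed to plant the ambiguous genome pair")
    return TaxonomyFixture(tuple(genomes), taxonomy, ambiguous_accessions)


def emit_alignment_fixture(
    pair: SyntheticPair,
    path: str | Path,
    evalues: float | Sequence[float] = 1e-30,
) -> Path:
    """Write the planted segments of a pair as a tabular alignment file.

    One 12-column BLAST-outfmt-6-like row per planted segment, with the
    supplied E-value(s) (a scalar applies to every segment). Because the
    segments are non-overlapping by construction, the coverage ratio of the
    emitted file is closed-form: the summed lengths of below-threshold
    segments, counted on both genomes, over the summed genome lengths.
    """
    path = Path(path)
    segments = pair.segments
    if isinstance(evalues, (int, float)):
        evalues = [float(evalues)] * len(segments)
    if len(evalues) != len(segments):
        raise InputError(
            f"need one E-value per segment: {len(evalues)} given, "
            f"{len(segments)} segments"
        )
    contig_a = pair.genome_a.contigs[0].id
    contig_b = pair.genome_b.contigs[0].id
    with open(path, "w") as fh:
        for seg, evalue in zip(segments, evalues):
            pident = 100.0 * (1 - seg.n_substitutions / seg.length)
            fh.write(
                f"{contig_a}\t{contig_b}\t{pident:.2f}\t{seg.length}\t"
                f"{seg.n_substitutions}\t0\t{seg.start_a + 1}\t{seg.start_a + seg.length}\t"
                f"{seg.start_b + 1}\t{seg.start_b + seg.length}\t{evalue:g}\t"
                f"{2 * seg.length}\n"
            )
    return path
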