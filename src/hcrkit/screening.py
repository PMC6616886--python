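"""Taxonomy ambiguity screening from pairwise HCR scores.

For every pair of taxa (genera or phyla) the screen compares the best
cross-taxon score against within-taxon scores. Two criteria are offered:

``anchored_max``
    Flag the pair when the maximum cross-taxon HCR exceeds the *anchored*
    maximum within-taxon HCR — the largest within-taxon score involving one
    of the two genomes that achieve the cross-taxon maximum. Anchoring asks
    the sharp question "is this genome closer to a foreign genus than to
    any genome of its own?"; ties are not flagged.

``min_intra_ratio``
    Flag the pair when max cross-taxon HCR / min within-taxon HCR exceeds a
    threshold (2 and 4 are the conventional cutoffs at the phylum level).
    A taxon whose own members barely overlap each other while overlapping a
    foreign taxon heavily is a strong inconsistency signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .errors import ConfigurationError, InputError
from .genome_io import TaxonomyRecord
from .kmer_profile import PairScore

__all__ = [
    "AmbiguityRecord",
    "taxon_pair_stats",
    "flag_ambiguous",
    "candidate_screen",
    "write_ambiguity_report",
]

logger = logging.getLogger(__name__)

Criterion = Literal["anchored_max", "min_intra_ratio"]


@dataclass(frozen=True)
class AmbiguityRecord:
    """Screening statistics for one unordered taxon pair."""

    level: str
    taxon_a: str
    taxon_b: str
    max_inter_hcr: float
    inter_pair: tuple[str, str]
    max_intra_hcr: float | None = None  # anchored by default; see taxon_pair_stats
    intra_pair: tuple[str, str] | None = None
    min_intra_hcr: float | None = None
    min_intra_pair: tuple[str, str] | None = None
    flagged: bool = False

    @property
    def ratio(self) -> float:
        """max_inter / min_intra; inf when min_intra is 0, nan when undefined."""
        if self.min_intra_hcr is None:
            return math.nan
        if self.min_intra_hcr == 0:
            return math.inf if self.max_inter_hcr > 0 else math.nan
        return self.max_inter_hcr / self.min_intra_hcr

    @property
    def excess(self) -> float:
        """max_inter − anchored max_intra (positive ⇒ ambiguous)."""
        if self.max_intra_hcr is None:
            return math.nan
        return self.max_inter_hcr - self.max_intra_hcr


def _resolve_taxa(
    scores: Sequence[PairScore],
    taxonomy: Mapping[str, TaxonomyRecord],
    level: str,
) -> dict[str, str]:
    accessions = {a for s in scores for a in (s.accession_a, s.accession_b)}
    missing = sorted(a for a in accessions if a not in taxonomy)
    if missing:
        raise InputError(
            "accession(s) absent from the taxonomy table: " + ", ".join(missing)
        )
    taxa = {a: taxonomy[a].taxon(level) for a in accessions}
    empty = sorted(a for a, t in taxa.items() if not t)
    if empty:
        raise InputError(
            f"empty {level} for accession(s): " + ", ".join(empty)
        )
    return taxa


def taxon_pair_stats(
    scores: Sequence[PairScore],
    taxonomy: Mapping[str, TaxonomyRecord],
    level: str = "genus",
    min_intra_scope: Literal["both", "first"] = "both",
    anchored: bool = True,
) -> list[AmbiguityRecord]:
    """Aggregate pair scores into per-taxon-pair screening records.

    For each unordered taxon pair with at least one cross-taxon score:
    the maximum cross score, the anchored maximum within-taxon score
    (``anchored=False`` takes the global within-taxon maximum over both
    taxa instead), and the minimum within-taxon score over both taxa
    (``min_intra_scope="first"`` restricts it to the lexicographically
    first taxon). Pairs in which either taxon has no within-taxon score
    (single-genome taxa) are skipped with a log note.
    """
    taxa = _resolve_taxa(scores, taxonomy, level)

    intra: dict[str, list[PairScore]] = {}
    cross: dict[tuple[str, str], list[PairScore]] = {}
    for score in scores:
        ta, tb = taxa[score.accession_a], taxa[score.accession_b]
        if ta == tb:
            if score.accession_a != score.accession_b:
                intra.setdefault(ta, []).append(score)
        else:
            cross.setdefault(tuple(sorted((ta, tb))), []).append(score)

    records = []
    for (taxon_a, taxon_b), pair_scores in sorted(cross.items()):
        if taxon_a not in intra or taxon_b not in intra:
            lonely = [t for t in (taxon_a, taxon_b) if t not in intra]
            logger.info(
                "skipping %s pair %s–%s: no within-taxon score for %s",
                level, taxon_a, taxon_b, ", ".join(lonely),
            )
            continue
        best = max(pair_scores, key=lambda s: s.hcr)
        inter_pair = (best.accession_a, best.accession_b)

        candidates = []
        if anchored:
            # within-taxon scores involving either endpoint of the best
            # cross pair, each endpoint searched within its own taxon
            for anchor in inter_pair:
                for s in intra[taxa[anchor]]:
                    if anchor in (s.accession_a, s.accession_b):
                        candidates.append(s)
        if not candidates:
            candidates = intra[taxon_a] + intra[taxon_b]
        best_intra = max(candidates, key=lambda s: s.hcr)

        min_pool = (
            intra[taxon_a]
            if min_intra_scope == "first"
            else intra[taxon_a] + intra[taxon_b]
        )
        worst_intra = min(min_pool, key=lambda s: s.hcr)
        records.append(
            AmbiguityRecord(
                level=level,
                taxon_a=taxon_a,
                taxon_b=taxon_b,
                max_inter_hcr=best.hcr,
                inter_pair=inter_pair,
                max_intra_hcr=best_intra.hcr,
                intra_pair=(best_intra.accession_a, best_intra.accession_b),
                min_intra_hcr=worst_intra.hcr,
                min_intra_pair=(worst_intra.accession_a, worst_intra.accession_b),
            )
        )
    return records


def flag_ambiguous(
    records: Iterable[AmbiguityRecord],
    criterion: Criterion = "anchored_max",
    threshold: float = 2.0,
) -> list[AmbiguityRecord]:
    """Apply a flagging criterion, returning records with ``flagged`` set.

    ``anchored_max``: flagged iff max_inter > max_intra (strict, so exact
    ties are not flagged). ``min_intra_ratio``: flagged iff
    max_inter / min_intra > threshold.
    """
    if criterion not in ("anchored_max", "min_intra_ratio"):
        raise ConfigurationError(f"unknown criterion: {criterion!r}")
    out = []
    for rec in records:
        if criterion == "anchored_max":
            if rec.max_intra_hcr is None:
                raise InputError(
                    f"{rec.taxon_a}–{rec.taxon_b}: max_intra_hcr required "
                    "for the anchored_max criterion"
                )
            flagged = rec.max_inter_hcr > rec.max_intra_hcr
        else:
            if rec.min_intra_hcr is None:
                raise InputError(
                    f"{rec.taxon_a}–{rec.taxon_b}: min_intra_hcr required "
                    "for the min_intra_ratio criterion"
                )
            flagged = rec.ratio > threshold
        out.append(replace(rec, flagged=flagged))
    return out


def candidate_screen(
    kmer_scores: Sequence[PairScore],
    taxonomy: Mapping[str, TaxonomyRecord],
    top_n: int,
    level: str = "genus",
) -> list[AmbiguityRecord]:
    """Rank taxon pairs by anchored excess for alignment-stage refinement.

    Returns the ``top_n`` pairs whose best cross-taxon score strictly
    exceeds the anchored within-taxon maximum, most excessive first.
    """
    records = taxon_pair_stats(kmer_scores, taxonomy, level=level)
    positive = [r for r in records if r.excess > 0]
    positive.sort(key=lambda r: (-r.excess, r.taxon_a, r.taxon_b))
    return positive[: max(top_n, 0)]


def _fmt_pair(pair: tuple[str, str] | None) -> str:
    return "&".join(pair) if pair else ""


def _fmt_opt(value: float | None) -> str:
    return "" if value is None else f"{value:.9f}"


def write_ambiguity_report(
    records: Iterable[AmbiguityRecord], path: str | Path
) -> Path:
    """Write the screening report TSV, sorted by descending ratio."""
    def sort_key(r: AmbiguityRecord):
        ratio = r.ratio
        return -ratio if not math.isnan(ratio) else math.inf

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "level\ttaxon_a\ttaxon_b\tmax_inter_hcr\tinter_pair\t"
            "max_intra_hcr\tintra_pair\tmin_intra_hcr\tmin_intra_pair\t"
            "ratio\tflagged\n"
        )
        for r in sorted(records, key=sort_key):
            ratio = "" if math.isnan(r.ratio) else f"{r.ratio:.6f}"
            fh.write(
                f"{r.level}\t{r.taxon_a}\t{r.taxon_b}\t{r.max_inter_hcr:.9f}\t"
                f"{_fmt_pair(r.inter_pair)}\t{_fmt_opt(r.max_intra_hcr)}\t"
                f"{_fmt_pair(r.intra_pair)}\t{_fmt_opt(r.min_intra_hcr)}\t"
                f"{_fmt_pair(r.min_intra_pair)}\t{ratio}\t"
                f"{'yes' if r.flagged else 'no'}\n"
            )
    return path
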