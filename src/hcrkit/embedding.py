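"""Ordination of pairwise HCR scores by classical multidimensional scaling.

Similarity is turned into distance by d = 1 − HCR (identical genomes at
distance 0, genomes with no detectable homology at 1), and the distance
matrix is embedded with classical (Torgerson) MDS: double-center the
squared distances, B = −½ J D² J, and take coordinates from the leading
non-negative eigenpairs. Classical MDS is deterministic and seed-free;
a fixed sign convention (the largest-magnitude coordinate of each axis is
made positive) makes outputs byte-reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError
from .genome_io import TaxonomyRecord
from .kmer_profile import PairScore

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "distance_from_scores",
    "classical_mds",
    "write_coordinates",
    "plot_ordination",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric zero-diagonal matrix of 1 − HCR distances."""

    accessions: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.accessions)
        if self.d.shape != (n, n):
            raise InputError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise InputError("distance matrix diagonal must be zero")


@dataclass(frozen=True)
class Ordination:
    accessions: tuple[str, ...]
    coords: np.ndarray
    eigenvalues: np.ndarray


def distance_from_scores(scores: Sequence[PairScore]) -> DistanceMatrix:
    """Build the 1 − HCR distance matrix from a complete set of pair scores."""
    by_key = {}
    accessions = set()
    for s in scores:
        accessions.update((s.accession_a, s.accession_b))
        if s.accession_a != s.accession_b:
            by_key[s.key] = s.hcr
    order = tuple(sorted(accessions))
    missing = [
        (a, b) for a, b in combinations(order, 2) if (a, b) not in by_key
    ]
    if missing:
        listed = ", ".join(f"{a}/{b}" for a, b in missing[:20])
        suffix = "" if len(missing) <= 20 else f" (+{len(missing) - 20} more)"
        raise InputError(f"missing pair score(s): {listed}{suffix}")
    n = len(order)
    d = np.zeros((n, n))
    for (i, a), (j, b) in combinations(enumerate(order), 2):
        d[i, j] = d[j, i] = 1.0 - by_key[(a, b)]
    return DistanceMatrix(order, d)


def classical_mds(dm: DistanceMatrix, dims: int = 2) -> Ordination:
    """Torgerson scaling of a distance matrix into ``dims`` coordinates.

    Negative eigenvalues (non-Euclidean distances) contribute nothing; if
    fewer than ``dims`` positive eigenpairs exist the trailing coordinate
    columns are zero.
    """
    n = len(dm.accessions)
    if n <= dims:
        raise InputError(f"need more than {dims} points, got {n}")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (dm.d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1][:dims]
    lam = eigvals[order]
    vec = eigvecs[:, order]
    coords = vec * np.sqrt(np.clip(lam, 0.0, None))
    # sign convention: largest-|coordinate| entry of each axis is positive
    for axis in range(coords.shape[1]):
        pivot = int(np.argmax(np.abs(coords[:, axis])))
        if coords[pivot, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    return Ordination(dm.accessions, coords, lam)


def write_coordinates(
    ordination: Ordination,
    path: str | Path,
    taxonomy: Mapping[str, TaxonomyRecord] | None = None,
    level: str = "genus",
) -> Path:
    """Write the coordinates TSV (accession, x, y, taxon_label)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("accession\tx\ty\ttaxon_label\n")
        for accession, row in zip(ordination.accessions, ordination.coords):
            label = taxonomy[accession].taxon(level) if taxonomy else ""
            y = row[1] if ordination.coords.shape[1] > 1 else 0.0
            fh.write(f"{accession}\t{row[0]:.9f}\t{y:.9f}\t{label}\n")
    return path


def plot_ordination(
    ordination: Ordination,
    path: str | Path,
    taxonomy: Mapping[str, TaxonomyRecord] | None = None,
    level: str = "genus",
    title: str | None = None,
) -> Path:
    """Scatter the 2-D ordination colored by taxon; thin plotting layer only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [
        taxonomy[a].taxon(level) if taxonomy else "" for a in ordination.accessions
    ]
    fig, ax = plt.subplots(figsize=(7, 6))
    for label in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == label]
        ax.scatter(
            ordination.coords[idx, 0],
            ordination.coords[idx, 1],
            s=24,
            label=label or None,
        )
    ax.set_xlabel("MDS1")
    ax.set_ylabel("MDS2")
    if title:
        ax.set_title(title)
    if any(labels):
        ax.legend(fontsize="small", markerscale=1.2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
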