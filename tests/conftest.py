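import pytest

from hcrkit.genome_io import Contig, GenomeAssembly
from hcrkit.kmer_profile import all_vs_all, build_profile
from hcrkit.synthetic import make_taxonomy_fixture


def assembly(accession: str, *sequences: str) -> GenomeAssembly:
    """Build a small in-memory assembly; contigs named <accession>_c1, ..."""
    contigs = tuple(
        Contig(f"{accession}_c{i + 1}", seq, f"{accession}_c{i + 1}")
        for i, seq in enumerate(sequences)
    )
    return GenomeAssembly(accession, contigs)


@pytest.fixture(scope="session")
def planted_taxonomy():
    """3 genera x 3 genomes with an ambiguity planted between genera 0 and 1."""
    return make_taxonomy_fixture(
        n_genera=3,
        genomes_per_genus=3,
        intra_fraction=0.3,
        inter_fraction=0.05,
        ambiguous_pair=(0, 1),
        ambiguous_fraction=0.5,
        genome_length=20_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_taxonomy_scores(planted_taxonomy):
    profiles = [build_profile(g) for g in planted_taxonomy.genomes]
    return all_vs_all(profiles)
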