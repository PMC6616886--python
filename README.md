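# hcrkit

Genome-to-genome comparison with the **homologous coverage ratio (HCR)**,
an overall genome relatedness index (OGRI) for large-scale screening of
microbial taxonomy.

Microbial classification is strained by sequencing-era diversity: marker-gene
methods (16S rRNA, concatenated single-copy protein sets) depend on which
genes are chosen, and the incumbent whole-genome index, average nucleotide
identity (ANI), is too expensive for all-vs-all surveys of thousands of
genomes. The HCR instead asks how much of two genomes is homologous at all:

```
HCR(A, B) = (H_A + H_B) / (S_A + S_B)
```

where `S_A`, `S_B` are the total assembly lengths (plasmids excluded) and
`H_A`, `H_B` the number of bases of each genome covered by homologous
alignment (E-value < 1e-10, overlapping blocks merged). Identical genomes
score 1, unrelated genomes ~0.

Because pairwise alignment at survey scale is infeasible (7,862 genomes is
~3.1e7 pairs; at ~20 s per alignment, years of compute), hcrkit uses a
two-stage design:

1. **scan** — a fast approximation from distinct-k-mer cross-containment,
   `HCR_kmer = (Hit_A + Hit_B) / (HS_A + HS_B)`, with `HS_X` the distinct
   k-mer count of genome X and `Hit_X` how many of its k-mers occur in the
   other genome (k = 12, strand-canonicalized, by default);
2. **refine** — the precise alignment-coverage HCR on the candidate pairs,
   consuming MAF or 12-column BLAST-tabular files from any local aligner
   (e.g. LAST).

On top of the two scores sit **screen** — per genus-pair (or phylum-pair)
comparison of cross-taxon vs within-taxon HCR, flagging pairs whose best
cross-taxon score rivals or exceeds within-taxon scores (the signature of an
ambiguous classification boundary) — and **mds**, classical multidimensional
scaling of `1 − HCR` distances for ordination plots. A seeded synthetic
generator (`hcrkit.synthetic`) produces genome pairs with exactly known
planted homology and planted taxonomies for end-to-end testing.

## Worked example

Generate a 3-genus × 3-genome planted dataset in which one cross-genus
genome pair shares half its genome (while within-genus sharing is 0.3),
then screen for it:

```sh
hcr synth --outdir dataset --n-genera 3 --genomes-per-genus 3 \
    --ambiguous-pair 0 1 --length 20000 --seed 11
hcr scan dataset -o scores.tsv
hcr screen --scores scores.tsv --taxonomy dataset/taxonomy.tsv \
    --level genus --criterion anchored_max -o report.tsv
hcr mds --scores scores.tsv --taxonomy dataset/taxonomy.tsv -o coords.tsv
```

`scores.tsv` holds the 36 all-vs-all k-mer HCR values:

```
accession_a	accession_b	method	hcr
SYN_01_01	SYN_01_02	kmer	0.300708936
SYN_01_01	SYN_01_03	kmer	0.300821561
SYN_01_01	SYN_02_01	kmer	0.500601202
```

Within-genus pairs score ≈ 0.30 (their planted shared fraction) and the
planted anomaly SYN_01_01/SYN_02_01 scores ≈ 0.50. The screening report:

```
level	taxon_a	taxon_b	max_inter_hcr	inter_pair	max_intra_hcr	intra_pair	min_intra_hcr	min_intra_pair	ratio	flagged
genus	Genus_01	Genus_02	0.500601202	SYN_01_01&SYN_02_01	0.301041875	SYN_02_01&SYN_02_03	0.300618567	SYN_02_02&SYN_02_03	1.665237	yes
genus	Genus_02	Genus_03	0.052232266	SYN_02_02&SYN_03_01	0.301039189	SYN_03_01&SYN_03_03	0.300618567	SYN_02_02&SYN_02_03	0.173749	no
genus	Genus_01	Genus_03	0.052110735	SYN_01_01&SYN_03_02	0.301282694	SYN_03_02&SYN_03_03	0.300708936	SYN_01_01&SYN_01_02	0.173293	no
```

Exactly the planted genus pair is flagged: its best cross-genus HCR (0.5006)
exceeds the best within-genus HCR anchored on the same genomes (0.3010).
The `mds` coordinates put the three genera in separate clusters, with the
two anomalous genomes pulled toward each other.

The library mirrors the CLI one-to-one
(`build_profile`/`hcr_kmer`/`all_vs_all`, `parse_alignments`/`hcr_alignment`,
`taxon_pair_stats`/`flag_ambiguous`, `distance_from_scores`/`classical_mds`);
see `docs/methods.md` for the model, parameter choices and limitations.

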