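"""Frozen reference values from a published large-scale HCR survey of
RefSeq microbial assemblies (7,861 genomes). These printed genus- and
phylum-level statistics are used as fixed inputs to screening-criterion
tests; nothing here is computed by hcrkit."""

# Genus-level survey: 15 genus pairs with blurred classification
# boundaries. Columns: genus_a, genus_b, max cross-genus HCR, achieving
# accession pair, anchored max within-genus HCR, achieving accession pair.
# Note the anchor construction: the same assembly appears in both pairs.
GENUS_PAIR_ROWS = [
    ("Alicycliphilus", "Acidovorax", 0.521, ("GCF_000175235.1", "GCF_000204645.1"),
     0.6, ("GCF_000175235.1", "GCF_002157165.1")),
    ("Chlorobium", "Chlorobaculum", 0.324, ("GCF_000012585.1", "GCF_000006985.1"),
     0.37, ("GCF_000012585.1", "GCF_000020645.1")),
    ("Clostridium", "Ruminiclostridium", 0.192, ("GCF_000620945.1", "GCF_002161175.1"),
     0.121, ("GCF_000620945.1", "GCF_000953215.1")),
    ("Corynebacterium", "Brevibacterium", 0.228, ("GCF_000720035.1", "GCF_900184225.1"),
     0.19, ("GCF_000720035.1", "GCF_001941505.1")),
    ("Diaphorobacter", "Acidovorax", 0.515, ("GCF_000175235.1", "GCF_000015545.1"),
     0.6, ("GCF_000175235.1", "GCF_002157165.1")),
    ("Erythrobacter", "Altererythrobacter", 0.479, ("GCF_000013005.1", "GCF_900177715.1"),
     0.493, ("GCF_000013005.1", "GCF_900115585.1")),
    ("Histophilus", "Haemophilus", 0.481, ("GCF_002015075.1", "GCF_000027305.1"),
     0.557, ("GCF_002015075.1", "GCF_000011785.1")),
    ("Kluyvera", "Enterobacter", 0.598, ("GCF_000321045.1", "GCF_900168315.1"),
     0.578, ("GCF_000321045.1", "GCF_001888805.2")),
    ("Kluyvera", "Escherichia", 0.549, ("GCF_000759795.1", "GCF_900112785.1"),
     0.506, ("GCF_000759795.1", "GCF_000350705.1")),
    ("Lelliottia", "Enterobacter", 0.709, ("GCF_001652505.2", "GCF_001729725.1"),
     0.702, ("GCF_001652505.2", "GCF_002811785.1")),
    ("Pseudodesulfovibrio", "Desulfovibrio", 0.397, ("GCF_000422565.1", "GCF_000189295.2"),
     0.397, ("GCF_000422565.1", "GCF_900188225.1")),
    ("Roseburia", "Clostridium", 0.194, ("GCF_900111235.1", "GCF_001940165.1"),
     0.2, ("GCF_900111235.1", "GCF_900112775.1")),
    ("Serratia", "Chania", 0.575, ("GCF_001976145.1", "GCF_002588845.1"),
     0.697, ("GCF_001976145.1", "GCF_000743365.1")),
    ("Sphingomonas", "Rhizorhabdus", 0.33, ("GCF_000512205.2", "GCF_000715175.2"),
     0.362, ("GCF_000512205.2", "GCF_001717955.1")),
    ("Vibrio", "Aliivibrio", 0.312, ("GCF_002100145.1", "GCF_001691025.1"),
     0.364, ("GCF_002100145.1", "GCF_000280885.2")),
]

# The five genus pairs whose cross-genus HCR strictly exceeds the anchored
# within-genus HCR (note Pseudodesulfovibrio–Desulfovibrio ties and is not
# among them).
EXPECTED_FLAGGED_GENUS_PAIRS = {
    ("Clostridium", "Ruminiclostridium"),
    ("Corynebacterium", "Brevibacterium"),
    ("Kluyvera", "Enterobacter"),
    ("Kluyvera", "Escherichia"),
    ("Lelliottia", "Enterobacter"),
}

# Phylum-level survey: 13 phylum pairs with the highest cross-phylum HCR.
# Columns: phylum_a, phylum_b, min within-genus HCR inside phylum_a,
# max cross-phylum HCR, achieving accession pair.
PHYLUM_PAIR_ROWS = [
    ("Proteobacteria", "Bacteroidetes", 0.015999617, 0.151368772,
     ("GCA_002355135.1", "GCA_000090965.1")),
    ("Proteobacteria", "Deferribacteres", 0.015999617, 0.112992155,
     ("GCA_000284355.1", "GCA_000010985.1")),
    ("Proteobacteria", "Aquificae", 0.015999617, 0.112416204,
     ("GCA_000284355.1", "GCA_000021545.1")),
    ("Firmicutes", "Dictyoglomi", 0.026170854, 0.170361824,
     ("GCA_000092965.1", "GCA_000020965.1")),
    ("Proteobacteria", "Tenericutes", 0.015999617, 0.101309783,
     ("GCA_001262715.1", "GCA_900016775.1")),
    ("Proteobacteria", "Firmicutes", 0.015999617, 0.096263109,
     ("GCA_000284355.1", "GCA_000014125.1")),
    ("Proteobacteria", "Fusobacteria", 0.015999617, 0.093542786,
     ("GCA_000816185.1", "GCA_001296125.1")),
    ("Firmicutes", "Deferribacteres", 0.026170854, 0.13067773,
     ("GCA_000165465.1", "GCA_000010985.1")),
    ("Proteobacteria", "Cyanobacteria", 0.015999617, 0.077366777,
     ("GCA_000011465.1", "GCA_000008885.1")),
    ("Proteobacteria", "Dictyoglomi", 0.015999617, 0.074348485,
     ("GCA_002220775.1", "GCA_000021645.1")),
    ("Firmicutes", "Aquificae", 0.026170854, 0.119079275,
     ("GCA_000025645.1", "GCA_000191045.1")),
    ("Tenericutes", "Firmicutes", 0.024333677, 0.106030272,
     ("GCA_001702115.1", "GCA_002441935.1")),
    ("Tenericutes", "Fusobacteria", 0.024333677, 0.104966983,
     ("GCA_000439435.1", "GCA_000024565.1")),
]

# Minimum within-genus HCR per phylum (top 10 lowest).
PHYLUM_MIN_INTRA = {
    "Proteobacteria": 0.015999617,
    "Tenericutes": 0.024333677,
    "Firmicutes": 0.026170854,
    "Spirochaetes": 0.048420481,
    "Fusobacteria": 0.140362380,
    "Bacteroidetes": 0.166804691,
    "Cyanobacteria": 0.216424948,
    "Thermotogae": 0.220607538,
    "Aquificae": 0.221942947,
    "Dictyoglomi": 0.749914757,
}

# Headline single-pair figures quoted alongside the tables.
MESOPLASMA_MYCOPLASMA_MAX_INTER = 0.393
MYCOPLASMA_MIN_INTRA = 0.025
MYCOPLASMA_SNEATHIA_MAX_INTER = 0.106
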