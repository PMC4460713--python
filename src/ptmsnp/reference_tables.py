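"""Published summary count tables of the human PTM-SNP survey.

These are the count columns of the PTM-SNP database release built on dbSNP
Build 135, dbPTM3 and the NHGRI/GAD/dbGaP catalogs: per-PTM-type site
counts, per-functional-class SNP counts against the NHGRI disease-SNP
universe, per-PTM-type disease-associated PTM-SNP counts, and per-trait SNP
counts.  They serve as inputs for recomputing the release's coverage ratios
and Fisher-exact enrichment statistics; the absolute counts themselves are
release-dependent and are not reproduced by this package.
"""

# (ptm_type, n_sites, n_sites_with_ptm_snp) — top-10 ratio types plus the rest
PTM_SITE_COUNTS = [
    ("Disulfide bond", 1750, 1230),
    ("Ubiquitination", 34507, 21824),
    ("Proteolytic Cleavage", 1569, 987),
    ("Acetylation", 11612, 6760),
    ("Phosphorylation", 355203, 203830),
    ("Sumorylation", 1180, 673),
    ("S-nitrosylation", 1286, 695),
    ("N-linked Glycosylation", 65121, 21215),
    ("Methylation", 6166, 1761),
    ("Sulfation", 8614, 2433),
    ("O-linked Glycosylation", 91678, 21335),
    ("Other PTMs", 20696, 7670),
]
PTM_SITE_TOTAL = (599382, 290413)

# (functional class, n_snps, n_disease_associated) against the full universe
FUNCTIONAL_CLASS_COUNTS = [
    ("Missense & Stop-gain (PTM-SNP)", 179325, 186),
    ("NearGene-5", 744086, 251),
    ("UTR-3: MirSNP", 414510, 151),
    ("UTR-3", 513249, 170),
    ("NearGene-3", 189105, 71),
    ("UTR-5", 80250, 35),
    ("Cds-synon", 312479, 100),
    ("Missense & Stop-gain (Non PTM-SNP)", 361401, 95),
    ("Intergenic", 20492263, 4357),
    ("Frameshift", 30578, 5),
    ("Intron", 19248959, 3678),
]
SNP_UNIVERSE = (41740143, 8771)  # (all SNPs, all disease-associated SNPs)

# (ptm_type, n_disease_associated_ptm_snps, n_ptm_snps) within the PTM-SNP set
PTM_TYPE_DISEASE_COUNTS = [
    ("Phosphorylation", 179, 165489),
    ("Proteolytic Cleavage", 2, 1145),
    ("Disulfide bond", 2, 1253),
    ("S-palmitoyl Cysteine", 1, 1797),
    ("N-linked Glycosylation", 7, 9400),
    ("O-linked Glycosylation", 3, 5925),
    ("Acetylation", 1, 5579),
    ("Ubiquitination", 4, 15862),
]
PTM_SNP_UNIVERSE = (179325, 186)  # (distinct PTM-SNPs, disease-associated ones)

# (trait, n_disease_snps, n_ptm_snps) — top-ranked traits
TRAIT_COUNTS = [
    ("Coronary heart disease", 122, 7),
    ("Diabetes Mellitus, Type 1", 293, 11),
    ("Lupus Erythematosus, Systemic", 345, 11),
    ("Diabetes Mellitus, Type 2", 279, 6),
    ("Macular Degeneration", 661, 11),
    ("Stroke", 1490, 17),
    ("Coronary Artery Disease", 700, 7),
    ("Heart Failure", 1127, 10),
    ("Cholesterol, LDL", 831, 7),
    ("Iron deficiency", 961, 7),
]
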