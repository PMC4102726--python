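"""Published reference inputs for the human eQTL regulatory-feature analysis.

These constants are *inputs*, not results: the hg18 per-track unique base
coverages and observed overlap counts of 62,872 unique best-eQTL positions
against 22 regulatory feature tracks, the human genome length used for the
per-base null, and the headline GWAS-catalog / location-class counts of the
53-dataset synthesis.  They let the binomial-enrichment and summary
machinery be re-run against the published study without redistributing the
underlying tracks.
"""

HUMAN_GENOME_LEN = 3_080_436_451
N_UNIQUE_BEST_EQTLS = 62_872

# (track name, unique covered bases, observed overlaps, targeted_fraction).
# The 5C track is a targeted assay interrogating ~1% of the genome.
REGULATORY_TRACKS = [
    ("ORegAnno", 11_265_267, 744, 1.0),
    ("Functional RNAs", 107_202, 7, 1.0),
    ("Gm12892V2.narrowPeak", 80_820_229, 4_610, 1.0),
    ("Gm12891V2.narrowPeak", 84_650_075, 4_680, 1.0),
    ("ENCODE H3k4me3", 120_458_965, 6_500, 1.0),
    ("Gm12878V3.narrowPeak", 43_937_796, 2_260, 1.0),
    ("ENCODE H3k27ac", 125_879_335, 6_540, 1.0),
    ("ENCODE H3k4me1", 242_340_600, 11_300, 1.0),
    ("Patrocles", 3_375_454, 153, 1.0),
    ("ENCODE H3k36me3", 631_024_019, 28_200, 1.0),
    ("ENCODE CTCF", 44_516_245, 1_900, 1.0),
    ("ENCODE 5C interactions", 10_484_463, 510, 0.01),
    ("CpG islands", 21_575_631, 817, 1.0),
    ("Conserved TFBS", 1_602_974, 54, 1.0),
    ("miRbase", 63_451, 2, 1.0),
    ("TargetScan", 354_030, 11, 1.0),
    ("ENCODE H3k27me3", 1_136_357_520, 24_700, 1.0),
    ("Vista Enhancers", 1_052_004, 16, 1.0),
    ("lincRNAs", 127_119_148, 1_541, 1.0),
    ("IHS sites", 2_275_923, 24, 1.0),
    ("FST sites", 4_088_207, 41, 1.0),
    ("PolymiRTS", 11_265_267, 1, 1.0),
]

# GWAS-catalog comparison counts (unique rsids)
GWAS_CATALOG_UNIQUE_SNPS = 8_845
GWAS_CATALOG_DIRECT_OVERLAP = 926

# best-association location split under the uniform 500 kb convention
BEST_ASSOC_CIS_SUMMARY = 106_083
BEST_ASSOC_TRANS_SUMMARY = 10_480
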