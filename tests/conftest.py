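import pandas as pd
import pytest

from eqtlatlas import GeneModel, SynthConfig, generate_study, harmonize


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across the suite."""
    return generate_study(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def harmonized(study):
    best, mapped, drops = harmonize(study.assoc, study.genome.genes, study.genome.snp_map)
    return best, mapped, drops


@pytest.fixture
def toy_genes():
    return [
        GeneModel("gA", "GENEA", frozenset({"ALIASA"}), "chr1", 1000, 2000, "+"),
        GeneModel("gB", "GENEB", frozenset({"ALIASB", "SHARED"}), "chr1", 600_000, 610_000, "-"),
        GeneModel("gC", "GENEC", frozenset({"SHARED"}), "chr2", 5000, 9000, "+"),
    ]


@pytest.fixture
def toy_snp_map():
    rows = [
        # rsid, chrom, pos(1-based), aliases, pseudo_autosomal
        ("rs1", "chr1", 900, "", 0),
        ("rs2", "chr1", 1500, "", 0),
        ("rs3", "chr1", 502_001, "ssOld3", 0),
        ("rs4", "chr2", 6000, "", 0),
        ("rs5", "chr1", 100, "", 0),
        ("rs5", "chr2", 100, "", 0),  # multi-mapped
        ("rs6", "chrX", 5, "", 1),  # pseudo-autosomal
        ("rs7", "chr1", 2101, "", 0),
    ]
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "aliases", "pseudo_autosomal"])


def make_assoc(rows):
    return pd.DataFrame(rows, columns=["dataset_id", "snp_id", "gene_id", "pvalue"])
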