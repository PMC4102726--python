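"""Positional, chromosomal and housekeeping summaries of harmonized eQTLs.

Covers the descriptive layer of the synthesis: the shape of the
significance-vs-distance profile per dataset (skewness/kurtosis of signed
SNP-gene distances — eQTL signal concentrates sharply at gene boundaries,
so these distributions are strongly leptokurtic), strand-oriented TSS
distance histograms, tissue-group comparisons of location-class shares,
chromosome-level cis-eQTL density rankings under several normalizations,
and the housekeeping vs non-housekeeping sharing comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, rankdata, ttest_ind


@dataclass
class DistanceProfile:
    """Moment summary of one dataset's signed SNP-gene distance distribution.

    Skewness g1 = m3 / m2^1.5 and excess kurtosis g2 = m4 / m2^2 - 3 use
    population (biased) central moments.  ``defined`` is False when fewer
    than 3 distances or zero variance.
    """

    dataset_id: str
    n: int
    mean_distance_bp: float
    skewness: float
    excess_kurtosis: float
    defined: bool


def distance_profile(bests: pd.DataFrame, dataset_id: str | None = None) -> DistanceProfile:
    """Moment profile of same-chromosome signed distances (in-gene = 0)."""
    df = bests if dataset_id is None else bests[bests["dataset_id"] == dataset_id]
    d = np.array([x for x in df["distance_bp"] if x is not None], dtype=float)
    label = dataset_id if dataset_id is not None else "all"
    if d.size < 3:
        return DistanceProfile(label, int(d.size), float(d.mean()) if d.size else np.nan,
                               np.nan, np.nan, False)
    mu = d.mean()
    c = d - mu
    m2 = np.mean(c**2)
    if m2 == 0:
        return DistanceProfile(label, int(d.size), float(mu), np.nan, np.nan, False)
    g1 = np.mean(c**3) / m2**1.5
    g2 = np.mean(c**4) / m2**2 - 3.0
    return DistanceProfile(label, int(d.size), float(mu), float(g1), float(g2), True)


def profile_all_datasets(bests: pd.DataFrame) -> pd.DataFrame:
    rows = [vars(distance_profile(bests, d)) for d in sorted(bests["dataset_id"].unique())]
    return pd.DataFrame(rows)


def tss_histogram(
    bests: pd.DataFrame, genes, window_bp: int, bin_bp: int
) -> pd.Series:
    """Counts of eQTLs per bin of strand-oriented distance from the 5' TSS.

    The TSS is the 5' end of the gene span (span_start for + strand, the
    last span base for - strand); minus-strand genes are mirrored so that
    positive distances always point downstream (into the gene body).  Bins
    tile [-window_bp, +window_bp) in steps of bin_bp.
    """
    if (2 * window_bp) % bin_bp != 0:
        raise ValueError("bin_bp must divide 2*window_bp")
    gene_by_key = {g.gene_key: g for g in genes}
    edges = np.arange(-window_bp, window_bp + bin_bp, bin_bp)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for row in bests.itertuples(index=False):
        gene = gene_by_key.get(row.gene_key)
        if gene is None or str(row.chrom) != gene.chrom:
            continue
        p = int(row.pos) - 1  # 0-based
        if gene.strand == "+":
            d = p - gene.span_start
        else:
            d = (gene.span_end - 1) - p
        if -window_bp <= d < window_bp:
            counts[(d + window_bp) // bin_bp] += 1
    return pd.Series(counts, index=edges[:-1], name="n_eqtls")


def compare_category_shares(
    bests: pd.DataFrame,
    meta: pd.DataFrame,
    location_class: str,
    group_a: str,
    group_b: str,
):
    """Compare one location class's share between two tissue groups.

    Builds the 2x2 table (class vs rest) x (group_a vs group_b) from best
    associations and applies the chi-square test without continuity
    correction, substituting Fisher's exact test when any expected cell is
    below 5.  Returns (proportions, p, test_name).
    """
    grp = meta.set_index("dataset_id")["tissue_group"]
    df = bests.assign(_grp=bests["dataset_id"].map(grp))
    table = []
    props = {}
    for g in (group_a, group_b):
        sub = df[df["_grp"] == g]
        if sub.empty:
            raise ValueError(f"tissue group {g!r} has no associations")
        k = int((sub["location_class"] == location_class).sum())
        table.append([k, len(sub) - k])
        props[g] = k / len(sub)
    table = np.asarray(table)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if (expected < 5).any():
        _, p = fisher_exact(table)
        test = "fisher"
    else:
        res = chi2_contingency(table, correction=False)
        p = res.pvalue
        test = "chi2"
    return props, float(p), test


def rank_chromosomes(cis_bests: pd.DataFrame, metrics: pd.DataFrame) -> pd.DataFrame:
    """Rank chromosomes by cis-eQTL density under 4 normalizations.

    ``metrics`` columns: chrom, length_bp, n_genes, rna_bp, n_variants.
    Each chromosome's cis count is divided by each metric; chromosomes are
    ranked per metric by descending density (ties mid-ranked) and the 4
    ranks averaged; mean rank ascending = most cis-enriched first.
    """
    counts = cis_bests.groupby("chrom").size()
    met = metrics.set_index("chrom")
    missing = set(counts.index) - set(met.index)
    if missing:
        raise ValueError(f"missing metrics for chromosomes: {sorted(missing)}")
    met = met.loc[sorted(met.index)]
    if (met <= 0).any().any():
        raise ValueError("chromosome metrics must be positive")
    out = pd.DataFrame(index=met.index)
    out["cis_count"] = counts.reindex(met.index, fill_value=0)
    rank_cols = []
    for col in ("length_bp", "n_genes", "rna_bp", "n_variants"):
        dens = out["cis_count"] / met[col]
        out[f"density_per_{col}"] = dens
        rcol = f"rank_{col}"
        out[rcol] = rankdata(-dens.to_numpy(), method="average")
        rank_cols.append(rcol)
    out["mean_rank"] = out[rank_cols].mean(axis=1)
    return out.sort_values("mean_rank", kind="mergesort")


@dataclass
class HousekeepingReport:
    """Housekeeping vs other eGenes, compared on datasets-per-eGene counts."""

    n_housekeeping: int
    n_other: int
    mean_housekeeping: float
    mean_other: float
    t_statistic: float
    df: float
    p_value: float


def compare_housekeeping(
    frequencies: pd.Series, housekeeping, equal_var: bool = True
) -> HousekeepingReport:
    """Two-sample t-test of eGene sharing between housekeeping and other genes.

    ``frequencies`` maps gene_key -> number of datasets in which the gene is
    an eGene; ``housekeeping`` is the set of housekeeping gene keys.  The
    classic pooled-variance Student's t-test is the default
    (``equal_var=False`` switches to Welch).
    """
    hk = set(str(g) for g in housekeeping)
    is_hk = frequencies.index.astype(str).isin(hk)
    a = frequencies[is_hk].to_numpy(dtype=float)
    b = frequencies[~is_hk].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 members")
    res = ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return HousekeepingReport(
        n_housekeeping=int(a.size),
        n_other=int(b.size),
        mean_housekeeping=float(a.mean()),
        mean_other=float(b.mean()),
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
    )
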