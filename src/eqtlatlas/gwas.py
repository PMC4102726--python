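"""GWAS integration: catalog overlap, signal correlation, λ subset enrichment.

Two complementary views of eQTL/GWAS convergence are implemented:

* **Catalog overlap** — what fraction of curated top GWAS hits coincides
  with a best eQTL, counted directly and after expanding through perfect-LD
  (r^2 = 1) proxies, since many eQTL studies tested unimputed array SNPs.

* **Genomic-inflation subset enrichment** — within a full GWA scan, the
  genomic inflation factor λ (median 1-df chi-square deviate of the p-values
  divided by the null median, 0.4549364) is computed separately for a SNP
  subset (e.g., best eQTLs, or nonsynonymous SNPs) and its complement; a
  ratio above 1 means the subset carries systematically stronger association
  signal.  λ is also recomputed restricted to the significant tail
  (scan p < 1e-2), and a two-sample Kolmogorov-Smirnov test compares the
  subset and complement p-value distributions directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import chi2, ks_2samp, spearmanr

# median of the 1-df chi-square distribution (null expectation for lambda)
CHI2_NULL_MEDIAN = float(chi2.isf(0.5, 1))

TAIL_P = 1e-2


def expand_proxies(snps, proxy_pairs) -> set:
    """Close a SNP set under perfect-LD (r^2 = 1) proxy partnership.

    Closure is over connected components of the proxy graph, so chained
    partners (a-b-c all at r^2 = 1) are all included.  Always a superset of
    the input; idempotent.
    """
    snps = set(str(s) for s in snps)
    g = nx.Graph()
    for a, b, r2 in proxy_pairs:
        if abs(float(r2) - 1.0) <= 1e-12:
            g.add_edge(str(a), str(b))
    out = set(snps)
    for s in snps:
        if s in g:
            out |= nx.node_connected_component(g, s)
    return out


@dataclass
class OverlapReport:
    """Overlap of a GWAS catalog with an eQTL SNP set."""

    n_catalog: int
    n_direct_overlap: int
    n_with_proxies: int
    pct_direct: float
    pct_with_proxies: float


def overlap_catalog(eqtl_snps, catalog_snps, proxy_pairs=None) -> OverlapReport:
    """Direct and proxy-expanded overlap of catalog SNPs with eQTL SNPs.

    Catalog SNPs are deduplicated to unique rsids (a SNP reported for
    several traits counts once).  Percentages are of the catalog size,
    rounded to 1 decimal.
    """
    catalog = set(str(s) for s in catalog_snps)
    if not catalog:
        raise ValueError("empty GWAS catalog")
    eqtls = set(str(s) for s in eqtl_snps)
    direct = len(catalog & eqtls)
    if proxy_pairs is not None:
        expanded = expand_proxies(eqtls, proxy_pairs)
        with_prox = len(catalog & expanded)
    else:
        with_prox = direct
    return OverlapReport(
        n_catalog=len(catalog),
        n_direct_overlap=direct,
        n_with_proxies=with_prox,
        pct_direct=round(100 * direct / len(catalog), 1),
        pct_with_proxies=round(100 * with_prox / len(catalog), 1),
    )


def correlate_signal(p_eqtl, p_gwas):
    """Spearman correlation of -log10 p between shared eQTL and GWAS SNPs.

    Inputs are aligned per-SNP p-value pairs (per-SNP multiplicity should be
    collapsed to the minimum p on each side before calling).  Ties are
    mid-ranked.  Returns (rho, p).
    """
    x = -np.log10(np.asarray(p_eqtl, dtype=float))
    y = -np.log10(np.asarray(p_gwas, dtype=float))
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 aligned p-value pairs")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


def genomic_lambda(pvals) -> float:
    """Genomic inflation factor λ from a set of association p-values.

    Each p is converted to its 1-df chi-square deviate (upper-tail
    quantile); λ is the median deviate divided by the null median 0.4549364.
    Under the null (uniform p) λ = 1; systematic signal inflates it.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.median(chi2.isf(p, 1)) / CHI2_NULL_MEDIAN)


@dataclass
class LambdaReport:
    """λ-based enrichment of a SNP subset within a full GWA scan."""

    subset_name: str
    n_subset: int
    n_complement: int
    lambda_subset: float
    lambda_complement: float
    enrichment_ratio: float
    lambda_subset_tail: float | None
    lambda_complement_tail: float | None
    ks_D: float
    ks_p: float
    status: str  # "enriched" | "depleted" | "null"


def subset_enrichment(scan_pvals: dict, subset_snps, subset_name: str = "subset") -> LambdaReport:
    """λ and K-S comparison of a SNP subset against its scan complement.

    ``scan_pvals`` maps rsid -> scan p-value.  Tail λ values (restricted to
    scan p < 1e-2) are None when a side has no tail SNPs.  K-S is the
    two-sided two-sample test on the raw p-value distributions.
    """
    subset = set(str(s) for s in subset_snps)
    in_sub = np.array([str(r) in subset for r in scan_pvals], dtype=bool)
    pv = np.fromiter(scan_pvals.values(), dtype=float, count=len(scan_pvals))
    p_sub = pv[in_sub]
    p_comp = pv[~in_sub]
    if p_sub.size == 0:
        raise ValueError("subset does not intersect the scan")
    if p_comp.size == 0:
        raise ValueError("subset covers the whole scan; no complement")
    lam_s = genomic_lambda(p_sub)
    lam_c = genomic_lambda(p_comp)
    tail_s = p_sub[p_sub < TAIL_P]
    tail_c = p_comp[p_comp < TAIL_P]
    ks = ks_2samp(p_sub, p_comp, alternative="two-sided")
    ratio = lam_s / lam_c
    status = "enriched" if ratio > 1 else ("depleted" if ratio < 1 else "null")
    return LambdaReport(
        subset_name=subset_name,
        n_subset=int(p_sub.size),
        n_complement=int(p_comp.size),
        lambda_subset=lam_s,
        lambda_complement=lam_c,
        enrichment_ratio=float(ratio),
        lambda_subset_tail=genomic_lambda(tail_s) if tail_s.size else None,
        lambda_complement_tail=genomic_lambda(tail_c) if tail_c.size else None,
        ks_D=float(ks.statistic),
        ks_p=float(ks.pvalue),
        status=status,
    )
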