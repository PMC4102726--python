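"""Harmonization of heterogeneous eQTL result tables.

Published eQTL studies report significant SNP-gene associations under wildly
different conventions: mixed gene symbols and aliases, stale rsIDs, assorted
cis-window definitions.  This module unifies them into one table of
per-(dataset, eGene) best associations with a consistent signed SNP-gene
distance and a four-way genomic location class:

``in_gene``
    the SNP falls inside the gene's maximal isoform-union span;
``cis``
    within ``window_bp`` (default 500 kb, inclusive) of the span edge;
``trans_same_chr``
    beyond the window but on the gene's chromosome;
``trans_diff_chr``
    on a different chromosome.

Internally all coordinates are 0-based half-open; SNP input positions are
1-based (dbSNP convention) and converted on ingestion.  Distances are signed
by gene orientation: negative = upstream (5'), positive = downstream (3'),
0 = inside the gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOCATION_CLASSES = ("in_gene", "cis", "trans_same_chr", "trans_diff_chr")

DEFAULT_CIS_WINDOW_BP = 500_000

# drop-log reason codes
UNMAPPED_GENE = "unmapped_gene"
AMBIGUOUS_ALIAS = "ambiguous_alias"
UNMAPPED_SNP = "unmapped_snp"
MULTI_MAP = "multi_map"
PSEUDO_AUTOSOMAL = "pseudo_autosomal"
AMBIGUOUS_SNP_ALIAS = "ambiguous_snp_alias"


@dataclass(frozen=True)
class GeneModel:
    """A gene as the maximal union of its isoform spans.

    ``span_start``/``span_end`` are 0-based half-open.  ``aliases`` never
    contains the gene's own symbol.
    """

    gene_key: str
    symbol: str
    aliases: frozenset
    chrom: str
    span_start: int
    span_end: int
    strand: str

    def __post_init__(self):
        if not self.span_start < self.span_end:
            raise ValueError(f"gene {self.gene_key}: empty span")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_key}: strand must be + or -")


def genes_from_frame(df: pd.DataFrame) -> list[GeneModel]:
    """Build GeneModel objects from a gene annotation frame.

    Expected columns: gene_key, symbol, aliases (``|``-separated string or
    iterable), chrom, start, end, strand.
    """
    out = []
    for row in df.itertuples(index=False):
        aliases = row.aliases
        if isinstance(aliases, str):
            aliases = [a for a in aliases.split("|") if a]
        elif aliases is None or (isinstance(aliases, float) and np.isnan(aliases)):
            aliases = []
        aliases = frozenset(a for a in aliases if a != row.symbol)
        out.append(
            GeneModel(
                gene_key=str(row.gene_key),
                symbol=str(row.symbol),
                aliases=aliases,
                chrom=str(row.chrom),
                span_start=int(row.start),
                span_end=int(row.end),
                strand=str(row.strand),
            )
        )
    symbols = [g.symbol for g in out]
    if len(set(symbols)) != len(symbols):
        raise ValueError("gene symbols must be unique within the annotation set")
    return out


def map_genes(records: pd.DataFrame, genes) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve raw gene identifiers to gene keys.

    Direct symbol matches take priority over alias matches.  Records whose
    raw id matches nothing, or matches aliases of more than one gene, are
    dropped and logged with a reason code.

    Returns ``(mapped, drop_log)``; ``mapped`` carries a ``gene_key`` column,
    ``drop_log`` has columns ``(row, value, reason)``.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene annotation set")
    # canonical keys and symbols are both direct matches, so re-harmonizing
    # already-canonical output is a no-op
    symbol_to_key = {g.gene_key: g.gene_key for g in genes}
    symbol_to_key.update({g.symbol: g.gene_key for g in genes})
    alias_to_keys: dict[str, set] = {}
    for g in genes:
        for a in g.aliases:
            alias_to_keys.setdefault(a, set()).add(g.gene_key)

    def resolve(raw: str):
        if raw in symbol_to_key:
            return symbol_to_key[raw], None
        hits = alias_to_keys.get(raw)
        if hits is None:
            return None, UNMAPPED_GENE
        if len(hits) > 1:
            return None, AMBIGUOUS_ALIAS
        return next(iter(hits)), None

    keys = []
    drops = []
    for i, raw in zip(records.index, records["gene_id"].astype(str)):
        key, reason = resolve(raw)
        keys.append(key)
        if reason is not None:
            drops.append((i, raw, reason))
    mapped = records.assign(gene_key=keys)
    drop_log = pd.DataFrame(drops, columns=["row", "value", "reason"])
    mapped = mapped[mapped["gene_key"].notna()].copy()
    return mapped, drop_log


def map_snps(records: pd.DataFrame, snp_map: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve raw SNP identifiers to a canonical rsid and unique placement.

    ``snp_map`` columns: rsid, chrom, pos (1-based), aliases (``|`` string),
    pseudo_autosomal (0/1).  Multi-mapping SNPs appear as repeated rsid rows.
    Direct rsid lookup happens first, alias lookup second; SNPs with more
    than one placement or a pseudo-autosomal placement are dropped.
    """
    placements: dict[str, list] = {}
    pa_flags: dict[str, bool] = {}
    alias_to_rsid: dict[str, set] = {}
    for row in snp_map.itertuples(index=False):
        rsid = str(row.rsid)
        placements.setdefault(rsid, []).append((str(row.chrom), int(row.pos)))
        pa_flags[rsid] = pa_flags.get(rsid, False) or bool(int(row.pseudo_autosomal))
        aliases = getattr(row, "aliases", "")
        if isinstance(aliases, str) and aliases:
            for a in aliases.split("|"):
                if a and a != rsid:
                    alias_to_rsid.setdefault(a, set()).add(rsid)

    def resolve(raw: str):
        rsid = raw
        if rsid not in placements:
            hits = alias_to_rsid.get(raw)
            if hits is None:
                return None, None, None, UNMAPPED_SNP
            if len(hits) > 1:
                return None, None, None, AMBIGUOUS_SNP_ALIAS
            rsid = next(iter(hits))
        pl = placements[rsid]
        if len(set(pl)) > 1:
            return None, None, None, MULTI_MAP
        if pa_flags[rsid]:
            return None, None, None, PSEUDO_AUTOSOMAL
        chrom, pos = pl[0]
        return rsid, chrom, pos, None

    rsids, chroms, poss, drops = [], [], [], []
    for i, raw in zip(records.index, records["snp_id"].astype(str)):
        rsid, chrom, pos, reason = resolve(raw)
        rsids.append(rsid)
        chroms.append(chrom)
        poss.append(pos)
        if reason is not None:
            drops.append((i, raw, reason))
    mapped = records.assign(rsid=rsids, chrom=chroms, pos=poss)
    drop_log = pd.DataFrame(drops, columns=["row", "value", "reason"])
    mapped = mapped[mapped["rsid"].notna()].copy()
    mapped["pos"] = mapped["pos"].astype(int)
    return mapped, drop_log


def compute_distance(pos: int, chrom: str, gene: GeneModel):
    """Signed SNP-gene distance in bp, or None when chromosomes differ.

    ``pos`` is 1-based.  0 when the SNP falls within the gene span; otherwise
    the gap in bases to the nearest span edge, negative on the gene's 5'
    (upstream) side in gene orientation and positive on the 3' side.
    """
    if pos <= 0:
        raise ValueError("SNP position must be positive (1-based)")
    if chrom != gene.chrom:
        return None
    p = pos - 1  # to 0-based
    if gene.span_start <= p < gene.span_end:
        return 0
    if p < gene.span_start:
        gap = gene.span_start - p
        left = True
    else:
        gap = p - gene.span_end + 1
        left = False
    upstream = left if gene.strand == "+" else not left
    return -gap if upstream else gap


def classify_location(distance_bp, same_chrom: bool, window_bp: int = DEFAULT_CIS_WINDOW_BP) -> str:
    """Four-way location class; the cis window is inclusive (<= window_bp)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not same_chrom:
        return "trans_diff_chr"
    d = abs(distance_bp)
    if d == 0:
        return "in_gene"
    if d <= window_bp:
        return "cis"
    return "trans_same_chr"


def annotate_locations(
    mapped: pd.DataFrame, genes, window_bp: int = DEFAULT_CIS_WINDOW_BP
) -> pd.DataFrame:
    """Attach distance_bp and location_class columns."""
    gene_by_key = {g.gene_key: g for g in genes}
    dists = np.empty(len(mapped), dtype=object)
    classes = np.empty(len(mapped), dtype=object)
    for j, row in enumerate(mapped.itertuples(index=False)):
        gene = gene_by_key[row.gene_key]
        d = compute_distance(int(row.pos), str(row.chrom), gene)
        dists[j] = d
        classes[j] = classify_location(d, d is not None, window_bp)
    out = mapped.copy()
    out["distance_bp"] = dists
    out["location_class"] = classes
    return out


def select_best(mapped: pd.DataFrame) -> pd.DataFrame:
    """One minimum-p association per (dataset_id, gene_key).

    Exact duplicates are removed first.  Ties on p are broken by smaller
    |distance| (cross-chromosome counts as +inf), then smaller position, then
    lexicographic rsid, so the result is independent of input row order.
    """
    df = mapped.drop_duplicates(subset=["dataset_id", "rsid", "gene_key", "pvalue"]).copy()
    absd = df["distance_bp"].map(lambda d: np.inf if d is None else abs(d))
    df["_absd"] = absd.astype(float)
    df = df.sort_values(
        ["dataset_id", "gene_key", "pvalue", "_absd", "pos", "rsid"],
        kind="mergesort",
    )
    best = df.drop_duplicates(subset=["dataset_id", "gene_key"], keep="first")
    return best.drop(columns=["_absd"]).reset_index(drop=True)


def summarize_locations(bests: pd.DataFrame) -> dict:
    """Location-class counts and integer percentages, overall and per dataset.

    The "cis summary" pools ``in_gene`` and ``cis`` (a SNP inside its gene is
    trivially cis-acting); its complement pools both trans classes.
    """

    def one(df):
        counts = {c: int((df["location_class"] == c).sum()) for c in LOCATION_CLASSES}
        total = len(df)
        cis_summary = counts["in_gene"] + counts["cis"]
        trans_summary = counts["trans_same_chr"] + counts["trans_diff_chr"]
        pct = {
            c: (round(100 * counts[c] / total) if total else 0) for c in LOCATION_CLASSES
        }
        return {
            "counts": counts,
            "total": total,
            "percent": pct,
            "cis_summary": cis_summary,
            "trans_summary": trans_summary,
            "cis_summary_percent": round(100 * cis_summary / total) if total else 0,
            "trans_summary_percent": round(100 * trans_summary / total) if total else 0,
        }

    per_dataset = {d: one(g) for d, g in bests.groupby("dataset_id")}
    return {"overall": one(bests), "per_dataset": per_dataset}


def harmonize(
    assoc: pd.DataFrame,
    genes,
    snp_map: pd.DataFrame,
    window_bp: int = DEFAULT_CIS_WINDOW_BP,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full harmonization: id mapping, filtering, annotation, best selection.

    Parameters
    ----------
    assoc : DataFrame with columns dataset_id, snp_id, gene_id, pvalue.
    genes : iterable of GeneModel (or a frame accepted by genes_from_frame).
    snp_map : SNP map frame (see map_snps).
    window_bp : inclusive cis window, default 500,000.

    Returns
    -------
    (best, mapped, drop_log)
        ``best`` holds one row per (dataset, gene); ``mapped`` all surviving
        annotated associations; ``drop_log`` all drops with reason codes.
    """
    if isinstance(genes, pd.DataFrame):
        genes = genes_from_frame(genes)
    else:
        genes = list(genes)
    if (assoc["pvalue"] <= 0).any() or (assoc["pvalue"] > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    g_mapped, g_drops = map_genes(assoc, genes)
    s_mapped, s_drops = map_snps(g_mapped, snp_map)
    annotated = annotate_locations(s_mapped, genes, window_bp)
    best = select_best(annotated)
    drop_log = pd.concat([g_drops, s_drops], ignore_index=True)
    return best, annotated, drop_log
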