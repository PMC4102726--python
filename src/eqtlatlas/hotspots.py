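"""Trans-eQTL hotspot detection via perfect-LD blocks.

Trans-acting signals reported in different studies frequently tag the same
underlying locus through different, perfectly correlated markers.  Grouping
SNPs into blocks of perfect linkage disequilibrium (connected components of
the r^2 = 1 proxy graph) lets recurrence be counted per locus rather than
per marker.  A block is reported as a hotspot when trans associations from
its members recur in at least ``min_datasets`` datasets (default 4, chosen
to exceed the typical number of same-sample tissues per study).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .harmonize import DEFAULT_CIS_WINDOW_BP

R2_TOL = 1e-12


@dataclass(frozen=True)
class LdBlock:
    """A maximal set of mutually perfectly correlated SNPs."""

    members: frozenset
    representative: str  # lexicographically smallest member


def build_ld_blocks(snps, proxy_pairs) -> list[LdBlock]:
    """Connected components of the r^2 = 1 proxy graph.

    ``proxy_pairs`` is an iterable of (rsid_a, rsid_b, r2); pairs below
    perfect LD are ignored, singletons from ``snps`` become their own block.
    """
    g = nx.Graph()
    g.add_nodes_from(str(s) for s in snps)
    for a, b, r2 in proxy_pairs:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0 + R2_TOL:
            raise ValueError(f"r2 out of range: {r2}")
        if abs(r2 - 1.0) <= R2_TOL:
            g.add_edge(str(a), str(b))
    blocks = []
    for comp in nx.connected_components(g):
        members = frozenset(comp)
        blocks.append(LdBlock(members=members, representative=min(members)))
    return sorted(blocks, key=lambda b: b.representative)


@dataclass
class HotspotRecord:
    """A perfect-LD block with recurrent trans targets across datasets."""

    block: LdBlock
    per_target: dict = field(default_factory=dict)  # gene_key -> n datasets
    n_supporting_datasets: int = 0
    category: str = "mixed"  # long_range_cis | diff_chr | mixed


def detect_hotspots(
    bests: pd.DataFrame,
    blocks,
    min_datasets: int = 4,
    window_bp: int = DEFAULT_CIS_WINDOW_BP,
    excluded_pairs=None,
) -> list[HotspotRecord]:
    """Report LD blocks whose trans targets recur in >= min_datasets datasets.

    Only best associations classified ``trans_same_chr`` or ``trans_diff_chr``
    are considered.  A block's category is ``long_range_cis`` when every
    target association is same-chromosome (>window but within the
    chromosome), ``diff_chr`` when none is, else ``mixed``.

    ``excluded_pairs`` is an optional set of (rsid, gene_key) pairs to drop
    before counting — a hook for screening out homology or probe
    cross-hybridization artifacts identified externally.
    """
    trans = bests[bests["location_class"].isin(["trans_same_chr", "trans_diff_chr"])]
    if excluded_pairs:
        excluded = set(excluded_pairs)
        keep = [
            (r, g) not in excluded for r, g in zip(trans["rsid"], trans["gene_key"])
        ]
        trans = trans[keep]
    block_of = {}
    for blk in blocks:
        for m in blk.members:
            block_of[m] = blk
    # rsids absent from the proxy data form their own singleton blocks
    for r in trans["rsid"].unique():
        if r not in block_of:
            block_of[r] = LdBlock(members=frozenset([r]), representative=r)
    records = []
    grouped: dict[LdBlock, pd.DataFrame] = {}
    idx = trans["rsid"].map(lambda r: block_of[r])
    for blk, sub in trans.groupby(idx, sort=False):
        grouped[blk] = sub
    for blk in sorted(grouped, key=lambda b: b.representative):
        sub = grouped[blk]
        n_support = sub["dataset_id"].nunique()
        if n_support < min_datasets:
            continue
        per_target = (
            sub.groupby("gene_key")["dataset_id"].nunique().astype(int).to_dict()
        )
        classes = set(sub["location_class"])
        if classes == {"trans_same_chr"}:
            category = "long_range_cis"
        elif classes == {"trans_diff_chr"}:
            category = "diff_chr"
        else:
            category = "mixed"
        records.append(
            HotspotRecord(
                block=blk,
                per_target=per_target,
                n_supporting_datasets=int(n_support),
                category=category,
            )
        )
    return records


def hotspot_table(records) -> pd.DataFrame:
    """Flatten hotspot records into a report table.

    Targets are rendered ``gene[k]`` with the per-gene dataset count in
    brackets, mirroring the conventional presentation of trans-hotspot
    tables.
    """
    rows = []
    for rec in records:
        targets = ", ".join(
            f"{g}[{k}]"
            for g, k in sorted(rec.per_target.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        rows.append(
            {
                "representative": rec.block.representative,
                "n_members": len(rec.block.members),
                "n_supporting_datasets": rec.n_supporting_datasets,
                "category": rec.category,
                "targets": targets,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "representative",
            "n_members",
            "n_supporting_datasets",
            "category",
            "targets",
        ],
    )
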