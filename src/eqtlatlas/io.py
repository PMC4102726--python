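"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are TSV with a header row; BED tracks are 0-based half-open
three-column (+ optional name).  SNP positions in the SNP map and
association tables are 1-based; genes and BED intervals are 0-based
half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import GenomicTrack
from .harmonize import genes_from_frame


def read_assoc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"dataset_id": str, "snp_id": str, "gene_id": str})
    required = {"dataset_id", "snp_id", "gene_id", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    return df


def read_genes(path):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return genes_from_frame(df)


def read_snp_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["pos"] = df["pos"].astype(int)
    df["pseudo_autosomal"] = df["pseudo_autosomal"].astype(int)
    return df


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"dataset_id": str})


def read_bed(path) -> list:
    """Read BED3(+name) intervals as (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def read_track_registry(path) -> list:
    """Track registry TSV (name, path, targeted_fraction) -> GenomicTracks."""
    base = Path(path).parent
    reg = pd.read_csv(path, sep="\t")
    tracks = []
    for row in reg.itertuples(index=False):
        bed = Path(row.path)
        if not bed.is_absolute():
            bed = base / bed
        tracks.append(
            GenomicTrack.from_intervals(
                str(row.name), read_bed(bed), float(row.targeted_fraction)
            )
        )
    return tracks


def read_proxy_pairs(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
    return [(a, b, float(r)) for a, b, r in zip(df["rsid_a"], df["rsid_b"], df["r2"])]


def read_scan(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    return dict(zip(df["rsid"], df["pvalue"].astype(float)))


def read_snp_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
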