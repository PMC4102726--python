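"""Cross-dataset occurrence analysis of harmonized eQTL results.

Given per-(dataset, gene) best associations, this module builds binary
entity-by-dataset occurrence matrices (entities are eGenes or eQTL rsids),
derives frequency spectra ("how many datasets share this eGene?"),
hierarchically clusters widely shared entities with the binary (asymmetric
Jaccard) dissimilarity, assembles master-eQTL summary tables, and fits the
logarithmic sample-size saturation curve relating a study's sample size to
the number of eGenes it detects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform


def build_occurrence(bests: pd.DataFrame, axis: str = "gene") -> pd.DataFrame:
    """Binary occurrence matrix (entities x datasets) from best associations.

    ``axis='gene'`` uses gene_key as the entity, ``axis='eqtl'`` uses rsid.
    A cell is 1 iff the entity has at least one best association in that
    dataset (an rsid that is best for two genes in one dataset counts once).
    """
    if axis == "gene":
        col = "gene_key"
    elif axis == "eqtl":
        col = "rsid"
    else:
        raise ValueError("axis must be 'gene' or 'eqtl'")
    if bests.empty:
        warnings.warn("empty input: occurrence matrix is empty")
        return pd.DataFrame()
    mat = (
        bests.assign(_one=1)
        .pivot_table(index=col, columns="dataset_id", values="_one", aggfunc="max", fill_value=0)
        .astype(np.int8)
    )
    return mat.sort_index()


def frequency_spectrum(matrix: pd.DataFrame, min_count: int = 1):
    """Histogram of row sums, plus entities shared by >= min_count datasets.

    Returns ``(histogram, subset)``: histogram is a Series over bins
    1..n_datasets; subset is sorted by descending occurrence then entity id.
    """
    n_datasets = matrix.shape[1]
    sums = matrix.sum(axis=1)
    hist = sums.value_counts().reindex(range(1, n_datasets + 1), fill_value=0)
    hist.index.name = "n_datasets"
    if min_count > n_datasets:
        warnings.warn("min_count exceeds the number of datasets: empty subset")
    qual = sums[sums >= min_count]
    subset = (
        pd.DataFrame({"entity": qual.index, "n_datasets": qual.values})
        .sort_values(["n_datasets", "entity"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return hist, subset


def binary_distance(row_i, row_j) -> float:
    """Binary (asymmetric) dissimilarity between two presence vectors.

    d = (# discordant positions) / (# positions where at least one is 1);
    matching on shared 1s, 0/0 positions are uninformative. Two all-zero
    rows get distance 0 by convention.
    """
    a = np.asarray(row_i, dtype=bool)
    b = np.asarray(row_j, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("rows must have equal length")
    union = (a | b).sum()
    if union == 0:
        return 0.0
    return float((a ^ b).sum() / union)


def _binary_pdist(mat: np.ndarray) -> np.ndarray:
    """Condensed pairwise binary distance matrix for binary rows."""
    m = mat.astype(bool)
    inter = (m @ m.T.astype(int)).astype(float)
    sums = m.sum(axis=1)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, (union - inter) / np.where(union > 0, union, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


@dataclass
class ClusterResult:
    """Hierarchical clustering of an occurrence matrix along both axes."""

    entity_linkage: np.ndarray | None
    dataset_linkage: np.ndarray | None
    entity_order: list = field(default_factory=list)
    dataset_order: list = field(default_factory=list)


def cluster_occurrence(
    matrix: pd.DataFrame, min_datasets: int = 1, method: str = "complete"
) -> ClusterResult:
    """Agglomerative clustering of entities (and datasets) sharing patterns.

    Entities are filtered to row sum >= min_datasets, then clustered with the
    binary dissimilarity and complete linkage (the classic R ``heatmap``
    defaults for presence/absence matrices). Both axes are clustered.
    """
    sums = matrix.sum(axis=1)
    sub = matrix.loc[sums[sums >= min_datasets].index]

    def one_axis(mat: np.ndarray, labels):
        if len(labels) < 2:
            return None, list(labels)
        z = linkage(_binary_pdist(mat), method=method)
        order = [labels[i] for i in leaves_list(z)]
        return z, order

    ez, eorder = one_axis(sub.to_numpy(), list(sub.index))
    dz, dorder = one_axis(sub.to_numpy().T, list(sub.columns))
    return ClusterResult(ez, dz, eorder, dorder)


def linkage_to_newick(z: np.ndarray | None, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick tree (for inspection)."""
    labels = list(labels)
    if z is None:
        return (labels[0] if labels else "") + ";"
    n = len(labels)
    nodes = {i: (labels[i], 0.0) for i in range(n)}
    for k, (a, b, h, _) in enumerate(z):
        sa, ha = nodes.pop(int(a))
        sb, hb = nodes.pop(int(b))
        nodes[n + k] = (f"({sa}:{h - ha:g},{sb}:{h - hb:g})", h)
    (s, _), = nodes.values()
    return s + ";"


def master_table(bests: pd.DataFrame, matrix: pd.DataFrame, min_datasets: int) -> pd.DataFrame:
    """Master-eGene summary for genes shared by >= min_datasets datasets.

    For each qualifying gene: the number of datasets where it is an eGene,
    the best eQTL (lowest p across all datasets, ties broken by |distance|,
    position, rsid), and the most common eQTL (the rsid that is the
    per-dataset best in the most datasets; ties go to the lower p).
    ``most_common_is_best`` flags genes where the two coincide.
    """
    sums = matrix.sum(axis=1)
    qualifying = sums[sums >= min_datasets].sort_values(ascending=False, kind="mergesort")
    rows = []
    for gene in qualifying.index:
        sub = bests[bests["gene_key"] == gene]
        absd = sub["distance_bp"].map(lambda d: np.inf if d is None else abs(d))
        sub = sub.assign(_absd=absd.astype(float)).sort_values(
            ["pvalue", "_absd", "pos", "rsid"], kind="mergesort"
        )
        best = sub.iloc[0]
        counts = sub.groupby("rsid").agg(n=("dataset_id", "nunique"), minp=("pvalue", "min"))
        counts = counts.sort_values(["n", "minp"], ascending=[False, True], kind="mergesort")
        mc_rsid = counts.index[0]
        rows.append(
            {
                "gene_key": gene,
                "n_datasets": int(qualifying[gene]),
                "best_eqtl": best["rsid"],
                "lowest_p": float(best["pvalue"]),
                "most_common_eqtl": mc_rsid,
                "most_common_n": int(counts.iloc[0]["n"]),
                "most_common_is_best": mc_rsid == best["rsid"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_key",
            "n_datasets",
            "best_eqtl",
            "lowest_p",
            "most_common_eqtl",
            "most_common_n",
            "most_common_is_best",
        ],
    )


@dataclass
class SaturationFit:
    """Least-squares fit of count = a + b * ln(sample_size)."""

    intercept: float
    slope: float
    r_squared: float


def saturation_fit(sample_sizes, counts) -> SaturationFit:
    """Fit the logarithmic saturation curve of eGene yield vs sample size.

    r^2 is the squared Pearson correlation between fitted and observed
    counts.  Constant counts give slope 0 and r^2 reported as 0.
    """
    n = np.asarray(sample_sizes, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(n) < 3:
        raise ValueError("need at least 3 datasets")
    if (n <= 0).any():
        raise ValueError("sample sizes must be positive")
    if np.allclose(y, y[0]):
        return SaturationFit(float(y[0]), 0.0, 0.0)
    x = np.log(n)
    b, a = np.polyfit(x, y, 1)
    fitted = a + b * x
    if np.allclose(fitted, fitted[0]):
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    return SaturationFit(float(a), float(b), r2)
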