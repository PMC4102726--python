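"""Per-base binomial enrichment of SNP positions in genomic feature tracks.

The model: a feature track covers ``coverage_bp`` unique bases of a genome of
``genome_len`` bases (default 3,080,436,451 for the human reference), so a
random base lands in the track with probability

    p0 = coverage_bp / (targeted_fraction * genome_len).

For n unique single-base SNP positions, the number overlapping the track is
Binomial(n_eff, p0) under the null, with n_eff = round(targeted_fraction * n)
— for a whole-genome track targeted_fraction is 1 and n_eff = n; for a
targeted assay interrogating only a fraction of the genome (e.g., a 5C
experiment covering ~1% of it) both the base probability and the number of
informative SNPs are restricted to the targeted territory.  Enrichment is
the one-sided upper tail P(X >= observed), computed exactly; the tail is
accumulated in log space so values far below the smallest normal double
(~1e-308) remain quantifiable via ``log10_p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

HUMAN_GENOME_LEN = 3_080_436_451


def merge_coverage(intervals):
    """Union of half-open intervals; returns (merged, coverage_bp).

    ``intervals`` is an iterable of (chrom, start, end), 0-based half-open.
    Merged intervals are disjoint, sorted, and abutting runs are joined.
    """
    by_chrom: dict[str, list] = {}
    for chrom, start, end in intervals:
        start, end = int(start), int(end)
        if start >= end:
            raise ValueError(f"empty interval [{start}, {end})")
        by_chrom.setdefault(str(chrom), []).append((start, end))
    merged = []
    coverage = 0
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                coverage += cur_e - cur_s
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
        coverage += cur_e - cur_s
    return merged, coverage


@dataclass
class GenomicTrack:
    """A named feature track with merged coverage.

    ``targeted_fraction`` < 1 marks a targeted assay that interrogates only
    that fraction of the genome.
    """

    name: str
    intervals: list = field(default_factory=list)  # merged, disjoint, sorted
    coverage_bp: int = 0
    targeted_fraction: float = 1.0

    @classmethod
    def from_intervals(cls, name, intervals, targeted_fraction: float = 1.0):
        if not 0.0 < targeted_fraction <= 1.0:
            raise ValueError("targeted_fraction must be in (0, 1]")
        merged, cov = merge_coverage(intervals)
        return cls(name=name, intervals=merged, coverage_bp=cov,
                   targeted_fraction=targeted_fraction)


def count_overlaps(positions, track: GenomicTrack) -> int:
    """Number of unique (chrom, pos) positions inside the track.

    Positions are 0-based single bases; interval ends are exclusive.
    Duplicate positions count once.
    """
    uniq = set((str(c), int(p)) for c, p in positions)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, s, e in track.intervals:
        starts.setdefault(chrom, []).append(s)
        ends.setdefault(chrom, []).append(e)
    for chrom in starts:
        starts[chrom] = np.asarray(starts[chrom])
        ends[chrom] = np.asarray(ends[chrom])
    n = 0
    for chrom, pos in uniq:
        if chrom not in starts:
            continue
        i = np.searchsorted(starts[chrom], pos, side="right") - 1
        if i >= 0 and pos < ends[chrom][i]:
            n += 1
    return n


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1)


@dataclass
class EnrichmentResult:
    """Binomial enrichment of SNP positions in one track.

    Reported ``probability``/``expected``/``ratio``/``p_binomial`` are
    rounded to 3 significant figures; the ``*_exact`` fields keep full
    precision.  ``p_binomial`` is 0.0 when the exact tail underflows the
    double range; ``log10_p`` is always finite for observed <= n_eff.
    """

    track_name: str
    genome_len: int
    n_tested: int
    n_effective: int
    coverage_bp: int
    targeted_fraction: float
    probability: float
    expected: float
    observed: int
    ratio: float
    p_binomial: float
    log10_p: float
    probability_exact: float
    expected_exact: float
    ratio_exact: float


def _log10_binom_sf(k: int, n: int, p: float) -> float:
    """log10 P(X >= k) for X ~ Binomial(n, p), exact, log-space."""
    if k <= 0:
        return 0.0
    if k > n:
        return -np.inf
    ls = binom.logsf(k - 1, n, p)
    if np.isfinite(ls):
        return float(ls / np.log(10))
    # logsf underflowed: accumulate the tail terms directly
    kk = np.arange(k, n + 1)
    return float(logsumexp(binom.logpmf(kk, n, p)) / np.log(10))


def binomial_enrichment(
    n_tested: int,
    track: GenomicTrack,
    observed: int,
    genome_len: int = HUMAN_GENOME_LEN,
) -> EnrichmentResult:
    """One-sided exact binomial enrichment test for one track."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    tf = track.targeted_fraction
    n_eff = int(round(tf * n_tested))
    if observed > n_eff:
        raise ValueError("observed exceeds the effective number of positions")
    p0 = track.coverage_bp / (tf * genome_len)
    if p0 > 1.0:
        raise ValueError("track coverage exceeds the targeted genome fraction")
    if track.coverage_bp == 0 and observed > 0:
        raise ValueError("observed overlaps with zero track coverage")
    expected = p0 * n_eff
    ratio = observed / expected if expected > 0 else (0.0 if observed == 0 else np.inf)
    if track.coverage_bp == 0:
        p_tail, l10 = 1.0, 0.0
    else:
        l10 = _log10_binom_sf(observed, n_eff, p0)
        p_tail = float(binom.sf(observed - 1, n_eff, p0)) if observed > 0 else 1.0
    return EnrichmentResult(
        track_name=track.name,
        genome_len=genome_len,
        n_tested=n_tested,
        n_effective=n_eff,
        coverage_bp=track.coverage_bp,
        targeted_fraction=tf,
        probability=_round_sig(p0),
        expected=_round_sig(expected),
        observed=int(observed),
        ratio=_round_sig(ratio),
        p_binomial=_round_sig(p_tail),
        log10_p=l10,
        probability_exact=p0,
        expected_exact=expected,
        ratio_exact=float(ratio),
    )


def enrich_all(positions, tracks, genome_len: int = HUMAN_GENOME_LEN) -> pd.DataFrame:
    """Enrichment table over many tracks, sorted by ratio descending.

    ``positions`` is deduplicated to unique (chrom, pos); targeted tracks
    apply their ``targeted_fraction`` to both the base probability and the
    effective number of tested positions.
    """
    uniq = sorted(set((str(c), int(p)) for c, p in positions))
    n = len(uniq)
    rows = []
    for track in tracks:
        obs = count_overlaps(uniq, track)
        if track.targeted_fraction < 1.0:
            # only positions inside the targeted territory are informative
            obs = min(obs, int(round(track.targeted_fraction * n)))
        res = binomial_enrichment(n, track, obs, genome_len)
        rows.append(vars(res))
    df = pd.DataFrame(rows)
    return df.sort_values("ratio_exact", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
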