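"""Seeded generation of a full synthetic multi-dataset eQTL study.

The generator emulates the statistical structure that the downstream
analyses assume, not real human genetics: a toy genome with uniformly
placed genes; a SNP map with configurable rates of alias identifiers,
multi-mapping rows and pseudo-autosomal flags (to exercise the low-quality
SNP filters); heterogeneous per-dataset significant-association lists with
planted cross-dataset sharing (a small set of "master" genes shared by most
datasets against a background shared by almost none, a boosted housekeeping
stratum, and tissue-group-specific genes), distance-decay significance
(two-sided exponential SNP placement around genes with -log10 p decaying in
distance), a minority of trans associations including planted perfect-LD
hotspot blocks, regulatory tracks (one TSS-concentrated, one uniform null,
one targeted-subregion), and full GWAS scans with a planted
Beta-distributed enriched SNP subset.

Every random draw flows from one root seed through named substreams, so
adding a generator does not perturb the others and the same seed always
yields byte-identical outputs.  The planted ground truth is returned (and
written) separately from the data so pipeline code can never consume it by
accident.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GenomicTrack
from .harmonize import GeneModel

# stable substream identifiers: appending entries never reshuffles existing ones
_STREAMS = {
    "genes": 1,
    "snps": 2,
    "sharing": 3,
    "datasets": 4,
    "tracks": 5,
    "gwas": 6,
    "hotspots": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class SynthConfig:
    """Parameters of the synthetic study (defaults follow the emulated design).

    The 53-dataset layout (24 brain / 14 blood / 5 liver / 3 fat / 7 other)
    matches the tissue composition of the collection being emulated; genome
    and gene counts are deliberately small so a full end-to-end run takes
    seconds.
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 3
    chrom_len_bp: int = 10_000_000
    n_genes: int = 300
    gene_len_range: tuple = (5_000, 50_000)
    # datasets
    n_datasets: int = 53
    tissue_groups: dict = field(
        default_factory=lambda: {"brain": 24, "blood": 14, "liver": 5, "fat": 3, "other": 7}
    )
    sample_size_range: tuple = (50, 1500)
    # sharing structure
    master_fraction: float = 20 / 300
    master_share_prob: float = 0.9
    background_share_prob: float = 0.02
    housekeeping_fraction: float = 0.10
    housekeeping_boost: float = 0.15
    group_specific_fraction: float = 0.2
    group_share_prob: float = 0.35
    # significance model
    tau_bp: float = 20_000.0
    baseline_neglogp: float = 6.0
    effect_scale: float = 12.0
    noise_sd: float = 1.0
    report_threshold_range: tuple = (5.0, 8.0)
    # per-gene SNP pool and LD
    snps_per_gene: int = 8
    snp_window_bp: int = 100_000
    ld_block_geom_p: float = 0.6
    max_ld_block: int = 4
    ld_duplicate_rate: float = 0.15
    max_eqtls_per_pair: int = 5
    # trans structure
    trans_fraction: float = 0.04
    trans_fraction_brain: float = 0.10
    n_hotspots: int = 2
    hotspot_n_datasets: int = 8
    # SNP-map corruption
    alias_rate: float = 0.05
    multimap_rate: float = 0.01
    pseudo_autosomal_rate: float = 0.005
    alias_use_rate: float = 0.5
    gene_alias_rate: float = 0.10
    gene_alias_use_rate: float = 0.5
    # regulatory tracks
    tss_window_bp: int = 10_000
    track_interval_bp: int = 500
    track_density_ratio: float = 5.0
    targeted_fraction: float = 0.01
    # GWAS scans
    gwas_n_snps: int = 10_000
    gwas_enriched_fraction: float = 0.10
    gwas_beta_alpha: float = 0.5
    n_scans: int = 2
    catalog_size: int = 200

    @property
    def genome_len(self) -> int:
        return self.n_chromosomes * self.chrom_len_bp


@dataclass
class SynthTruth:
    """Planted ground truth, emitted separately from the data."""

    master_genes: list
    housekeeping_genes: list
    group_specific: dict  # gene -> tissue group
    share_probs: dict  # gene -> baseline sharing probability
    planted_track: str
    null_track: str
    targeted_track: str
    gwas_enriched_snps: list
    hotspot_blocks: list  # list of lists of rsids
    hotspot_targets: dict  # representative rsid -> target gene


@dataclass
class Genome:
    """Toy genome: gene models, SNP map, chromosome metrics, SNP pools."""

    genes: list
    snp_map: pd.DataFrame
    metrics: pd.DataFrame
    snp_pool: pd.DataFrame  # rsid, chrom, pos, gene_key (cis pool) or '' (trans)
    ld_pairs: list  # (rsid_a, rsid_b, 1.0)
    gene_aliases: dict  # symbol -> alias used in dirty inputs
    snp_aliases: dict  # rsid -> alias used in dirty inputs


def make_genome(config: SynthConfig) -> Genome:
    """Generate gene models, a candidate-SNP pool, and a corrupted SNP map."""
    cfg = config
    grng = _rng(cfg.seed, "genes")
    srng = _rng(cfg.seed, "snps")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    lo, hi = cfg.gene_len_range
    if cfg.n_genes * hi > cfg.genome_len:
        raise ValueError("genes denser than chromosome capacity")
    genes = []
    for i in range(cfg.n_genes):
        chrom = chroms[i % cfg.n_chromosomes]
        length = int(grng.integers(lo, hi))
        start = int(grng.integers(0, cfg.chrom_len_bp - length))
        strand = "+" if grng.random() < 0.5 else "-"
        sym = f"G{i:04d}"
        genes.append(
            GeneModel(
                gene_key=sym, symbol=sym, aliases=frozenset(),
                chrom=chrom, span_start=start, span_end=start + length, strand=strand,
            )
        )

    # candidate eQTL positions around each gene (two-sided exponential decay)
    rows = []
    rsid_counter = 0
    for g in genes:
        center = (g.span_start + g.span_end) // 2
        for _ in range(cfg.snps_per_gene):
            d = srng.exponential(cfg.tau_bp)
            d = min(d, cfg.snp_window_bp)
            sign = -1 if srng.random() < 0.5 else 1
            pos0 = int(np.clip(center + sign * int(d), 0, cfg.chrom_len_bp - 1))
            rows.append((f"rs{rsid_counter:06d}", g.chrom, pos0 + 1, g.gene_key))
            rsid_counter += 1
    # free-floating SNPs usable as trans markers; the pool is kept large so
    # independent trans placements rarely recur on the same marker by chance
    n_trans_pool = max(500, cfg.n_hotspots * cfg.max_ld_block * 3)
    for _ in range(n_trans_pool):
        chrom = chroms[int(srng.integers(0, cfg.n_chromosomes))]
        pos0 = int(srng.integers(0, cfg.chrom_len_bp))
        rows.append((f"rs{rsid_counter:06d}", chrom, pos0 + 1, ""))
        rsid_counter += 1
    pool = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "gene_key"])

    # perfect-LD blocks: group consecutive SNPs within each gene's pool
    ld_pairs = []
    for _, sub in pool[pool["gene_key"] != ""].groupby("gene_key", sort=False):
        rsids = list(sub["rsid"])
        i = 0
        while i < len(rsids):
            size = int(min(srng.geometric(cfg.ld_block_geom_p), cfg.max_ld_block))
            block = rsids[i : i + size]
            for a, b in zip(block, block[1:]):
                ld_pairs.append((a, b, 1.0))
            i += size

    # corrupted SNP map
    snp_rows = []
    snp_aliases = {}
    for row in pool.itertuples(index=False):
        alias = ""
        if srng.random() < cfg.alias_rate:
            alias = row.rsid.replace("rs", "ss")
            snp_aliases[row.rsid] = alias
        pa = int(srng.random() < cfg.pseudo_autosomal_rate)
        snp_rows.append((row.rsid, row.chrom, row.pos, alias, pa))
        if srng.random() < cfg.multimap_rate:
            chrom2 = chroms[int(srng.integers(0, cfg.n_chromosomes))]
            pos2 = int(srng.integers(1, cfg.chrom_len_bp + 1))
            snp_rows.append((row.rsid, chrom2, pos2, alias, pa))
    snp_map = pd.DataFrame(
        snp_rows, columns=["rsid", "chrom", "pos", "aliases", "pseudo_autosomal"]
    )

    gene_aliases = {}
    for g in genes:
        if grng.random() < cfg.gene_alias_rate:
            gene_aliases[g.symbol] = g.symbol.replace("G", "GA")
    genes = [
        GeneModel(
            gene_key=g.gene_key, symbol=g.symbol,
            aliases=frozenset([gene_aliases[g.symbol]]) if g.symbol in gene_aliases else frozenset(),
            chrom=g.chrom, span_start=g.span_start, span_end=g.span_end, strand=g.strand,
        )
        for g in genes
    ]

    per_chrom = pool.groupby("chrom").size()
    metrics = pd.DataFrame(
        {
            "chrom": chroms,
            "length_bp": cfg.chrom_len_bp,
            "n_genes": [sum(g.chrom == c for g in genes) for c in chroms],
            "rna_bp": [
                sum(g.span_end - g.span_start for g in genes if g.chrom == c)
                for c in chroms
            ],
            "n_variants": [int(per_chrom.get(c, 1)) for c in chroms],
        }
    )
    return Genome(
        genes=genes, snp_map=snp_map, metrics=metrics, snp_pool=pool,
        ld_pairs=ld_pairs, gene_aliases=gene_aliases, snp_aliases=snp_aliases,
    )


def _dataset_meta(config: SynthConfig, rng) -> pd.DataFrame:
    rows = []
    i = 0
    for group, k in config.tissue_groups.items():
        for _ in range(k):
            n = int(rng.integers(*config.sample_size_range))
            rows.append((f"ds{i:02d}", group, group, n))
            i += 1
    if i != config.n_datasets:
        raise ValueError("tissue_groups sizes must sum to n_datasets")
    return pd.DataFrame(rows, columns=["dataset_id", "tissue", "tissue_group", "sample_size"])


def make_datasets(config: SynthConfig, genome: Genome):
    """Generate per-dataset significant-association tables and the truth.

    Returns (assoc, meta, truth): ``assoc`` has one row per reported
    association (columns dataset_id, snp_id, gene_id, pvalue) with the
    configured rates of alias identifiers and LD-correlated duplicates;
    ``meta`` is the dataset metadata table; ``truth`` the planted ground
    truth.
    """
    cfg = config
    shrng = _rng(cfg.seed, "sharing")
    drng = _rng(cfg.seed, "datasets")
    hrng = _rng(cfg.seed, "hotspots")

    meta = _dataset_meta(cfg, drng)
    gene_keys = [g.gene_key for g in genome.genes]
    n_master = int(round(cfg.master_fraction * cfg.n_genes))
    perm = list(shrng.permutation(gene_keys))
    master = sorted(perm[:n_master])
    rest = perm[n_master:]
    n_hk = int(round(cfg.housekeeping_fraction * cfg.n_genes))
    housekeeping = sorted(rest[:n_hk])
    n_grp = int(round(cfg.group_specific_fraction * cfg.n_genes))
    groups = list(cfg.tissue_groups)
    group_specific = {
        g: groups[int(shrng.integers(0, len(groups)))] for g in rest[n_hk : n_hk + n_grp]
    }

    share = {}
    for g in gene_keys:
        if g in master:
            share[g] = cfg.master_share_prob
        elif g in housekeeping:
            share[g] = cfg.background_share_prob + cfg.housekeeping_boost
        else:
            share[g] = cfg.background_share_prob

    # larger studies report somewhat more genes: scale the background share
    sizes = meta.set_index("dataset_id")["sample_size"]
    size_scale = (np.log(sizes) / np.log(sizes).mean()).to_dict()
    thresholds = {
        d: float(drng.uniform(*cfg.report_threshold_range)) for d in meta["dataset_id"]
    }
    groups_of = meta.set_index("dataset_id")["tissue_group"].to_dict()

    pool_by_gene = {
        k: sub for k, sub in genome.snp_pool[genome.snp_pool["gene_key"] != ""].groupby("gene_key")
    }
    trans_pool = genome.snp_pool[genome.snp_pool["gene_key"] == ""]
    gene_by_key = {g.gene_key: g for g in genome.genes}
    ld_partner = {}
    for a, b, _ in genome.ld_pairs:
        ld_partner.setdefault(a, b)
        ld_partner.setdefault(b, a)

    rows = []

    def emit(dataset_id, rsid, gene_key, pval):
        snp_id = rsid
        if rsid in genome.snp_aliases and drng.random() < cfg.alias_use_rate:
            snp_id = genome.snp_aliases[rsid]
        gid = gene_key
        if gene_key in genome.gene_aliases and drng.random() < cfg.gene_alias_use_rate:
            gid = genome.gene_aliases[gene_key]
        rows.append((dataset_id, snp_id, gid, pval))

    for d in meta["dataset_id"]:
        grp = groups_of[d]
        tf = cfg.trans_fraction_brain if grp == "brain" else cfg.trans_fraction
        for g in gene_keys:
            p_share = share[g]
            if g in group_specific and group_specific[g] == grp:
                p_share = max(p_share, cfg.group_share_prob)
            if g not in master:
                p_share = min(1.0, p_share * size_scale[d])
            if shrng.random() >= p_share:
                continue
            gene = gene_by_key[g]
            cand = pool_by_gene[g]
            k = int(drng.integers(1, cfg.max_eqtls_per_pair + 1))
            idx = drng.choice(len(cand), size=min(k, len(cand)), replace=False)
            cand_rows = cand.iloc[sorted(idx)]
            best_done = False
            scored = []
            for c in cand_rows.itertuples(index=False):
                dist = _signed_offset(c.pos, gene)
                nlp = (
                    cfg.baseline_neglogp
                    + cfg.effect_scale * np.exp(-abs(dist) / cfg.tau_bp)
                    + drng.normal(0, cfg.noise_sd)
                )
                scored.append((c.rsid, nlp))
            scored.sort(key=lambda t: -t[1])
            for j, (rsid, nlp) in enumerate(scored):
                # the top candidate is always reported (the source study called
                # this gene significant by its own criteria); others must pass
                # the dataset's reporting threshold
                if j > 0 and nlp < thresholds[d]:
                    continue
                if drng.random() < tf:
                    # re-place a minority of signals in trans
                    t = trans_pool.iloc[int(drng.integers(0, len(trans_pool)))]
                    rsid = t.rsid
                pval = 10.0 ** -min(nlp, 300.0)
                emit(d, rsid, g, pval)
                if rsid in ld_partner and drng.random() < cfg.ld_duplicate_rate:
                    emit(d, ld_partner[rsid], g, min(1.0, pval * 10.0))
                best_done = True
            if not best_done:  # pragma: no cover - top candidate always reported
                emit(d, scored[0][0], g, 10.0 ** -scored[0][1])

    # planted trans hotspots: one LD block trans-associated with one target
    # gene in a fixed number of datasets
    hotspot_blocks = []
    hotspot_targets = {}
    dataset_ids = list(meta["dataset_id"])
    for h in range(cfg.n_hotspots):
        size = int(hrng.integers(2, cfg.max_ld_block + 1))
        idx = hrng.choice(len(trans_pool), size=size, replace=False)
        block = sorted(trans_pool.iloc[sorted(idx)]["rsid"])
        for a, b in zip(block, block[1:]):
            genome.ld_pairs.append((a, b, 1.0))
        # target on a chromosome different from the block anchor where possible
        anchor_chrom = trans_pool.set_index("rsid").loc[block[0], "chrom"]
        far = [g for g in genome.genes if g.chrom != anchor_chrom]
        target = far[int(hrng.integers(0, len(far)))].gene_key
        supporting = hrng.choice(dataset_ids, size=cfg.hotspot_n_datasets, replace=False)
        for d in supporting:
            rsid = block[int(hrng.integers(0, len(block)))]
            nlp = cfg.baseline_neglogp + float(hrng.uniform(4, 10))
            emit(d, rsid, target, 10.0 ** -nlp)
        hotspot_blocks.append(list(block))
        hotspot_targets[block[0]] = target

    assoc = pd.DataFrame(rows, columns=["dataset_id", "snp_id", "gene_id", "pvalue"])
    truth = SynthTruth(
        master_genes=master,
        housekeeping_genes=housekeeping,
        group_specific=group_specific,
        share_probs=share,
        planted_track="tss_proximal",
        null_track="uniform_null",
        targeted_track="targeted_subregion",
        gwas_enriched_snps=[],
        hotspot_blocks=hotspot_blocks,
        hotspot_targets=hotspot_targets,
    )
    return assoc, meta, truth


def _signed_offset(pos_1based: int, gene: GeneModel) -> int:
    p = pos_1based - 1
    if gene.span_start <= p < gene.span_end:
        return 0
    if p < gene.span_start:
        return p - gene.span_start
    return p - gene.span_end + 1


def make_tracks(config: SynthConfig, genome: Genome) -> list[GenomicTrack]:
    """Three feature tracks: TSS-concentrated, uniform null, targeted.

    The planted track places ``track_density_ratio`` times as many intervals
    inside gene TSS windows as the uniform null does genome-wide, at equal
    total coverage, so SNP positions that concentrate near genes enrich in
    the planted track only.
    """
    cfg = config
    rng = _rng(cfg.seed, "tracks")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    L = cfg.track_interval_bp
    n_intervals = max(1, int(cfg.n_genes * cfg.track_density_ratio))

    planted = []
    for _ in range(n_intervals):
        g = genome.genes[int(rng.integers(0, len(genome.genes)))]
        tss = g.span_start if g.strand == "+" else g.span_end - 1
        off = int(rng.integers(-cfg.tss_window_bp, cfg.tss_window_bp))
        s = int(np.clip(tss + off, 0, cfg.chrom_len_bp - L - 1))
        planted.append((g.chrom, s, s + L))

    null = []
    for _ in range(n_intervals):
        chrom = chroms[int(rng.integers(0, cfg.n_chromosomes))]
        s = int(rng.integers(0, cfg.chrom_len_bp - L))
        null.append((chrom, s, s + L))

    # targeted assay: interrogates only a contiguous subregion of chr1
    t_len = int(cfg.targeted_fraction * cfg.genome_len)
    t_start = int(rng.integers(0, cfg.chrom_len_bp - t_len))
    targeted = []
    for _ in range(max(1, n_intervals // 10)):
        s = int(rng.integers(t_start, t_start + t_len - L))
        targeted.append(("chr1", s, s + L))

    return [
        GenomicTrack.from_intervals("tss_proximal", planted),
        GenomicTrack.from_intervals("uniform_null", null),
        GenomicTrack.from_intervals(
            "targeted_subregion", targeted, targeted_fraction=cfg.targeted_fraction
        ),
    ]


@dataclass
class GwasData:
    """Synthetic GWAS side: full scans, catalog, nSNP list, proxy pairs."""

    scans: dict  # trait -> {rsid: p}
    catalog: pd.DataFrame  # rsid, trait, pvalue
    nsnps: list
    proxy_pairs: list


def make_gwas(config: SynthConfig, genome: Genome, truth: SynthTruth) -> GwasData:
    """Full GWA scans with a planted Beta(alpha, 1)-enriched SNP subset.

    Background scan p-values are Uniform(0, 1]; the planted subset (a
    fraction ``gwas_enriched_fraction`` of scan SNPs) draws from
    Beta(alpha, 1) with alpha < 1, concentrating mass near 0.  The catalog
    collects each scan's smallest p-values; proxy pairs mirror the genome's
    perfect-LD blocks.  ``truth.gwas_enriched_snps`` is filled in here.
    """
    cfg = config
    rng = _rng(cfg.seed, "gwas")
    # the scan universe shares part of the genome's SNP pool, so eQTL rsids
    # genuinely appear among scan and catalog SNPs
    pool_rsids = list(genome.snp_pool["rsid"])
    n_from_pool = min(cfg.gwas_n_snps // 10, len(pool_rsids))
    from_pool = sorted(rng.choice(pool_rsids, size=n_from_pool, replace=False))
    snp_ids = from_pool + [
        f"gs{i:06d}" for i in range(cfg.gwas_n_snps - n_from_pool)
    ]
    n_enriched = int(round(cfg.gwas_enriched_fraction * cfg.gwas_n_snps))
    enriched = sorted(rng.choice(snp_ids, size=n_enriched, replace=False))
    enriched_set = set(enriched)
    scans = {}
    catalog_rows = []
    for t in range(cfg.n_scans):
        trait = f"trait{t}"
        p = np.clip(rng.uniform(0, 1, size=cfg.gwas_n_snps), 1e-12, 1.0)
        if n_enriched:
            beta = rng.beta(cfg.gwas_beta_alpha, 1.0, size=n_enriched)
            mask = np.array([s in enriched_set for s in snp_ids])
            p[mask] = np.clip(beta, 1e-12, 1.0)
        scans[trait] = dict(zip(snp_ids, p.tolist()))
        order = np.argsort(p)[: cfg.catalog_size]
        for i in order:
            catalog_rows.append((snp_ids[i], trait, float(p[i])))
    catalog = pd.DataFrame(catalog_rows, columns=["rsid", "trait", "pvalue"])
    n_nsnp = max(10, cfg.gwas_n_snps // 20)
    nsnps = sorted(rng.choice(snp_ids, size=n_nsnp, replace=False))
    truth.gwas_enriched_snps = list(enriched)
    return GwasData(
        scans=scans, catalog=catalog, nsnps=nsnps, proxy_pairs=list(genome.ld_pairs)
    )


@dataclass
class SynthStudy:
    """A complete generated study bundle."""

    config: SynthConfig
    genome: Genome
    assoc: pd.DataFrame
    meta: pd.DataFrame
    tracks: list
    gwas: GwasData
    truth: SynthTruth


def generate_study(config: SynthConfig | None = None) -> SynthStudy:
    """Generate the full synthetic study from one seeded configuration."""
    cfg = config or SynthConfig()
    genome = make_genome(cfg)
    assoc, meta, truth = make_datasets(cfg, genome)
    tracks = make_tracks(cfg, genome)
    gwas = make_gwas(cfg, genome, truth)
    return SynthStudy(
        config=cfg, genome=genome, assoc=assoc, meta=meta,
        tracks=tracks, gwas=gwas, truth=truth,
    )


def write_study(study: SynthStudy, outdir) -> None:
    """Emit every input format the pipeline consumes, plus truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.assoc.to_csv(out / "assoc.tsv", sep="\t", index=False)
    study.meta.to_csv(out / "datasets.tsv", sep="\t", index=False)
    genes = pd.DataFrame(
        [
            (g.gene_key, g.symbol, "|".join(sorted(g.aliases)), g.chrom,
             g.span_start, g.span_end, g.strand)
            for g in study.genome.genes
        ],
        columns=["gene_key", "symbol", "aliases", "chrom", "start", "end", "strand"],
    )
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    study.genome.snp_map.to_csv(out / "snps.tsv", sep="\t", index=False)
    study.genome.metrics.to_csv(out / "chrom_metrics.tsv", sep="\t", index=False)
    pd.DataFrame(study.gwas.proxy_pairs, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
        out / "ld_proxies.tsv", sep="\t", index=False
    )
    registry = []
    for tr in study.tracks:
        bed = out / f"track_{tr.name}.bed"
        with open(bed, "w") as fh:
            for chrom, s, e in tr.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{tr.name}\n")
        registry.append((tr.name, bed.name, tr.targeted_fraction))
    pd.DataFrame(registry, columns=["name", "path", "targeted_fraction"]).to_csv(
        out / "tracks.tsv", sep="\t", index=False
    )
    study.gwas.catalog.to_csv(out / "gwas_catalog.tsv", sep="\t", index=False)
    scans_dir = out / "scans"
    scans_dir.mkdir(exist_ok=True)
    for trait, pv in study.gwas.scans.items():
        pd.DataFrame(
            {"rsid": list(pv), "pvalue": list(pv.values())}
        ).to_csv(scans_dir / f"{trait}.tsv", sep="\t", index=False)
    with open(out / "nsnps.txt", "w") as fh:
        fh.write("\n".join(study.gwas.nsnps) + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(asdict(study.truth), fh, indent=1)
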