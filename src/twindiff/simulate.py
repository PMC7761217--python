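"""Synthetic discordant-twin dataset generator with a machine-readable truth manifest.

Emulates the data structure of a monozygotic twin pair discordant for disease:
a shared germline with a small set of planted discordant small variants (each
class engineered to a deterministic fate in the filter funnel), SV/CNV tables
with planted rare affected-only events, beta-binomial methylomes with planted
feature-localized differential CpGs, an unmethylated phage spike-in, and the
regulatory feature tracks, gene lists and expression tables the downstream
arms consume. Everything is deterministic per seed, and the manifest records
the expected outcome of every pipeline stage for closure testing.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from . import annotation, svcnv
from .model import (
    CNVRecord,
    CpGSiteCounts,
    FeatureTrack,
    GeneModel,
    GenomicInterval,
    SVRecord,
    write_feature_bed,
    write_gene_models,
    write_methylation_counts,
)

# Baseline methylome mixture: most CpGs highly methylated, a CpG-island-like
# minority essentially unmethylated. Overall mean 0.825.
METH_MIXTURE = (
    (0.875, 140.5, 9.45),  # weight, alpha, beta — high-methylation component
    (0.125, 4.0, 96.0),  # low-methylation (island-like) component
)

VARIANT_CLASSES = (
    "coding_damaging",
    "coding_tolerated",
    "noncoding_high_cadd",
    "noncoding_low_cadd",
    "common",
    "low_quality",
    "zygosity_diff",
)

LAMBDA_CHROM = "lambda"


def _default_planted_discordant() -> Dict[str, int]:
    return {
        "coding_damaging": 5,
        "coding_tolerated": 4,
        "noncoding_high_cadd": 5,
        "noncoding_low_cadd": 4,
        "common": 4,
        "low_quality": 4,
        "zygosity_diff": 4,
    }


def _default_planted_dmcs() -> List[Tuple[str, int, float]]:
    # cardiac TFBS planted before the general TFBS class: the cardiac track is
    # a subset of the TFBS track and its motifs hold far fewer CpGs
    return [
        ("promoter_cgi", 40, 40.0),
        ("cgi_shore", 40, 40.0),
        ("cardiac_tfbs", 10, 40.0),
        ("tfbs", 20, 40.0),
        ("enhancer", 30, 40.0),
        ("intergenic", 60, 40.0),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic twin pair.

    Genome shape, planted variant classes, methylome priors and spike-in model.
    ``noiseless`` replaces all sampling of counts with expectations and fixes
    coverage, making every planted signal exactly recoverable.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    n_genes: int = 50
    n_cgis: int = 30
    n_tfbs: int = 60
    n_enhancers: int = 10
    n_shared_variants: int = 400
    n_healthy_only_variants: int = 3
    planted_discordant: Dict[str, int] = field(default_factory=_default_planted_discordant)
    n_cpgs: int = 100_000
    meth_alpha: Optional[float] = None  # None -> bimodal mixture default
    meth_beta: Optional[float] = None
    cov_mean: float = 50.0
    cov_dispersion: float = 25.0  # negative-binomial size parameter
    planted_dmcs: List[Tuple[str, int, float]] = field(default_factory=_default_planted_dmcs)
    lambda_sites: int = 2000
    lambda_coverage: int = 50
    conversion_error: float = 0.003
    n_sv_rare_affected: int = 4
    n_sv_common_affected: int = 3
    n_sv_low_impact: int = 2
    n_sv_shared: int = 3
    n_sv_healthy_only: int = 2
    n_cnv_gains: int = 2
    n_cnv_losses: int = 2
    n_cnv_neutral: int = 1
    noiseless: bool = False

    def __post_init__(self) -> None:
        counts = [
            self.n_chroms, self.chrom_length, self.n_genes, self.n_cgis,
            self.n_tfbs, self.n_enhancers, self.n_shared_variants, self.n_cpgs,
            self.lambda_sites,
        ]
        if any(c < 0 for c in counts) or self.n_chroms == 0:
            raise ValueError("genome-shape counts must be positive")
        for cls, n in self.planted_discordant.items():
            if cls not in VARIANT_CLASSES:
                raise ValueError(f"unknown planted variant class {cls!r}")
            if n < 0:
                raise ValueError("planted counts must be >= 0")
        for feat, n, delta in self.planted_dmcs:
            if n < 0:
                raise ValueError("planted DMC counts must be >= 0")
            if not 25.0 <= delta <= 100.0:
                raise ValueError(f"planted delta must lie in [25, 100], got {delta}")
        if not 0.0 <= self.conversion_error <= 1.0:
            raise ValueError("conversion_error must be a fraction")

    @property
    def chroms(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


# ---------------------------------------------------------------------------
# Feature track simulation
# ---------------------------------------------------------------------------

# layout margins (bp): keep genes far enough apart that each promoter window,
# promoter CGI and upstream spacer belongs unambiguously to its own gene
_SLOT_MARGIN = 3000
_MIN_SLOT = 14_000


def simulate_feature_tracks(cfg: SimulationConfig, rng: np.random.Generator):
    """Generate gene models and CGI/TFBS/enhancer tracks.

    Genes are placed in disjoint slots (non-nested, >= 3 kb apart); about half
    of the CGIs straddle a TSS (promoter CGIs), the rest are intergenic; TFBS
    are short motifs inside promoters or elsewhere, a third labeled cardiac;
    enhancers are intergenic blocks.
    """
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1

    genes: List[GeneModel] = []
    free_zones: List[Tuple[str, int]] = []  # (chrom, slot base) gene-free left margins
    gi = 0
    for ci, chrom in enumerate(cfg.chroms):
        n_on = per_chrom[ci]
        if n_on == 0:
            continue
        slot = (cfg.chrom_length - 2 * _SLOT_MARGIN) // n_on
        if slot < _MIN_SLOT:
            raise ValueError(
                f"genome too small: slot {slot} bp < {_MIN_SLOT} bp needed per gene"
            )
        for k in range(n_on):
            base = _SLOT_MARGIN + k * slot
            glen = int(rng.integers(2000, 6001))
            start = base + _SLOT_MARGIN + int(rng.integers(0, slot - glen - 2 * _SLOT_MARGIN))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 5))
            inner = np.sort(rng.choice(np.arange(start + 100, start + glen - 100),
                                       size=2 * n_ex - 2, replace=False))
            edges = [start, *inner.tolist(), start + glen]
            exons = tuple(
                (edges[j], edges[j + 1]) for j in range(0, len(edges) - 1, 2)
            )
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:04d}",
                    name=f"GENE{gi:03d}",
                    chrom=chrom,
                    start=start,
                    end=start + glen,
                    strand=strand,
                    exons=exons,
                )
            )
            free_zones.append((chrom, base))
            gi += 1

    # CGIs: first half anchored at a TSS, second half in gene-free zones
    cgi_ivs: List[GenomicInterval] = []
    n_prom_cgi = cfg.n_cgis // 2
    order = rng.permutation(len(genes))
    for j in range(min(n_prom_cgi, len(genes))):
        g = genes[order[j]]
        clen = int(rng.integers(500, 1501))
        off = int(rng.integers(0, 301))
        if g.strand == "+":
            s = g.tss - off
        else:
            s = g.tss - clen + off
        s = max(0, s)
        cgi_ivs.append(GenomicInterval(g.chrom, s, s + clen, label=f"cgi_{g.name}"))
    zone_order = rng.permutation(len(free_zones))
    zi = 0
    while len(cgi_ivs) < cfg.n_cgis:
        if zi >= len(zone_order):
            raise ValueError("genome too small for requested intergenic CGIs")
        chrom, base = free_zones[zone_order[zi]]
        zi += 1
        clen = int(rng.integers(500, 1501))
        s = base + 200
        cgi_ivs.append(GenomicInterval(chrom, s, s + clen, label="cgi_intergenic"))
    cgis = FeatureTrack("cgi", cgi_ivs)

    promoters = annotation.build_promoters(genes)

    # TFBS: 40% inside promoters, the rest anywhere inside gene slots
    tfbs_ivs: List[GenomicInterval] = []
    cardiac_ivs: List[GenomicInterval] = []
    n_in_prom = int(round(0.4 * cfg.n_tfbs))
    prom_list = promoters.intervals
    for t in range(cfg.n_tfbs):
        tlen = int(rng.integers(10, 31))
        if t < n_in_prom and prom_list:
            p = prom_list[int(rng.integers(0, len(prom_list)))]
            s = int(rng.integers(p.start + 50, max(p.start + 51, p.end - 50 - tlen)))
            chrom = p.chrom
        else:
            chrom = cfg.chroms[int(rng.integers(0, cfg.n_chroms))]
            s = int(rng.integers(1000, cfg.chrom_length - 1000 - tlen))
        iv = GenomicInterval(chrom, s, s + tlen, label=f"tfbs{t:03d}")
        tfbs_ivs.append(iv)
        if t % 3 == 0:
            cardiac_ivs.append(iv)
    tfbs = FeatureTrack("tfbs", tfbs_ivs)
    cardiac_tfbs = FeatureTrack("cardiac_tfbs", cardiac_ivs)

    # enhancers: intergenic, away from genes and CGIs
    occupied: Dict[str, IntervalTree] = {c: IntervalTree() for c in cfg.chroms}
    for g in genes:
        occupied[g.chrom].addi(max(0, g.start - 2600), g.end + 2600)
    for iv in cgi_ivs:
        occupied[iv.chrom].addi(max(0, iv.start - 100), iv.end + 100)
    enh_ivs: List[GenomicInterval] = []
    attempts = 0
    while len(enh_ivs) < cfg.n_enhancers:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("genome too small for requested enhancers")
        elen = int(rng.integers(500, 2001))
        chrom = cfg.chroms[int(rng.integers(0, cfg.n_chroms))]
        s = int(rng.integers(1000, cfg.chrom_length - 1000 - elen))
        if occupied[chrom].overlap(s, s + elen):
            continue
        occupied[chrom].addi(s, s + elen)
        enh_ivs.append(GenomicInterval(chrom, s, s + elen, label=f"enh{len(enh_ivs):02d}"))
    enhancers = FeatureTrack("enhancer", enh_ivs)

    tracks = {
        "cgi": cgis,
        "tfbs": tfbs,
        "cardiac_tfbs": cardiac_tfbs,
        "enhancer": enhancers,
    }
    return genes, tracks


# ---------------------------------------------------------------------------
# Twin genomes: small variants, SVs, CNVs
# ---------------------------------------------------------------------------

_BASES = "ACGT"


@dataclass
class _SimVariant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alts: Tuple[str, ...]
    gt_affected: str  # VCF genotype strings
    gt_healthy: str
    dp_a: int
    dp_h: int
    gq_a: int
    gq_h: int
    info: Dict[str, object]
    truth_class: str  # planted class or shared/healthy_only/multiallelic
    expected_fate: str  # survivor | zygosity_survivor | removed_<stage> | not_selected


def _rand_base(rng, not_base: Optional[str] = None) -> str:
    while True:
        b = _BASES[int(rng.integers(0, 4))]
        if b != not_base:
            return b


def _pick_position(rng, cfg, used: set, predicate=None, max_tries: int = 5000) -> Tuple[str, int]:
    for _ in range(max_tries):
        chrom = cfg.chroms[int(rng.integers(0, cfg.n_chroms))]
        pos = int(rng.integers(1000, cfg.chrom_length - 1000))
        if (chrom, pos) in used:
            continue
        if predicate is not None and not predicate(chrom, pos):
            continue
        used.add((chrom, pos))
        return chrom, pos
    raise ValueError("could not place variant: position collisions exhausted retries")


def simulate_twin_genomes(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
):
    """Plant shared and class-labeled discordant variants plus SV/CNV tables.

    Each planted discordant class carries annotations that force a
    deterministic fate in the filter funnel (e.g. 'common' passes quality but
    carries a population frequency at/above 1%).
    """
    used: set = set()
    gene_trees: Dict[str, IntervalTree] = {}
    exon_pool: List[Tuple[GeneModel, Tuple[int, int]]] = []
    for g in genes:
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
        for ex in g.exons or ((g.start, g.end),):
            exon_pool.append((g, ex))

    def intergenic(chrom: str, pos: int) -> bool:
        tree = gene_trees.get(chrom)
        return tree is None or not tree.overlap(pos - 3000, pos + 3000)

    def in_exon(rng) -> Tuple[str, int, GeneModel]:
        for _ in range(5000):
            g, (s, e) = exon_pool[int(rng.integers(0, len(exon_pool)))]
            pos = int(rng.integers(s, e))
            if (g.chrom, pos) not in used:
                used.add((g.chrom, pos))
                return g.chrom, pos, g
        raise ValueError("could not place exonic variant")

    def q_pass(rng):
        return int(rng.integers(30, 100)), int(rng.integers(15, 61))

    tools = ("polyphen2", "sift", "mutationtaster")
    key_of = {"polyphen2": "POLYPHEN", "sift": "SIFT", "mutationtaster": "MUTATIONTASTER"}

    sims: List[_SimVariant] = []

    def add(chrom, pos, info, gt_a, gt_h, gq_a, dp_a, gq_h, dp_h, tclass, fate,
            ref=None, alts=None):
        ref = ref or _rand_base(rng)
        alts = alts or (_rand_base(rng, ref),)
        sims.append(
            _SimVariant(chrom, pos, ref, alts, gt_a, gt_h, dp_a, dp_h, gq_a, gq_h,
                        info, tclass, fate)
        )

    def damaging_info(rng, damaging: bool) -> Dict[str, object]:
        info: Dict[str, object] = {"CONSEQUENCE": "missense_variant"}
        dmg_tool = tools[int(rng.integers(0, 3))]
        for t in tools:
            if damaging and t == dmg_tool:
                info[key_of[t]] = "damaging"
            else:
                info[key_of[t]] = "tolerated"
        if rng.random() < 0.5:
            info["AF_GNOMAD"] = round(float(rng.uniform(0.0, 0.005)), 6)
        return info

    # planted discordant variants
    for cls in VARIANT_CLASSES:
        n = cfg.planted_discordant.get(cls, 0)
        for _ in range(n):
            if cls in ("coding_damaging", "coding_tolerated", "common",
                       "low_quality", "zygosity_diff"):
                chrom, pos, _g = in_exon(rng)
            else:
                chrom, pos = _pick_position(rng, cfg, used, predicate=intergenic)
            gq_a, dp_a = q_pass(rng)
            gq_h, dp_h = q_pass(rng)
            gt_a, gt_h = "0/1", "0/0"
            if cls == "coding_damaging":
                info, fate = damaging_info(rng, True), "survivor"
            elif cls == "coding_tolerated":
                info, fate = damaging_info(rng, False), "removed_consequence"
            elif cls == "noncoding_high_cadd":
                info = {"CONSEQUENCE": "intergenic_variant",
                        "CADD_PHRED": round(float(rng.uniform(15.5, 35.0)), 2)}
                fate = "survivor"
            elif cls == "noncoding_low_cadd":
                info = {"CONSEQUENCE": "intergenic_variant",
                        "CADD_PHRED": round(float(rng.uniform(0.5, 14.5)), 2)}
                fate = "removed_consequence"
            elif cls == "common":
                info = damaging_info(rng, True)
                info["AF_1000G"] = round(float(rng.uniform(0.01, 0.5)), 4)
                fate = "removed_rarity"
            elif cls == "low_quality":
                info = damaging_info(rng, True)
                if rng.random() < 0.5:
                    gq_a = int(rng.integers(0, 20))
                else:
                    dp_a = int(rng.integers(0, 10))
                fate = "removed_quality"
            else:  # zygosity_diff
                info = damaging_info(rng, True)
                gt_a, gt_h = "1/1", "0/1"
                fate = "zygosity_survivor"
            add(chrom, pos, info, gt_a, gt_h, gq_a, dp_a, gq_h, dp_h, cls, fate)

    # healthy-only variants (affected funnel never selects them)
    for _ in range(cfg.n_healthy_only_variants):
        chrom, pos = _pick_position(rng, cfg, used)
        gq_a, dp_a = q_pass(rng)
        gq_h, dp_h = q_pass(rng)
        add(chrom, pos, damaging_info(rng, True), "0/0", "0/1",
            gq_a, dp_a, gq_h, dp_h, "healthy_only", "not_selected")

    # shared (concordant) background variants
    benign_infos = (
        {"CONSEQUENCE": "intron_variant"},
        {"CONSEQUENCE": "synonymous_variant"},
        {"CONSEQUENCE": "intergenic_variant", "CADD_PHRED": 2.0},
    )
    for _ in range(cfg.n_shared_variants):
        chrom, pos = _pick_position(rng, cfg, used)
        gq_a, dp_a = q_pass(rng)
        gq_h, dp_h = q_pass(rng)
        gt = "0/1" if rng.random() < 0.7 else "1/1"
        info = dict(benign_infos[int(rng.integers(0, len(benign_infos)))])
        if rng.random() < 0.5:
            info["AF_GNOMAD"] = round(float(rng.uniform(0.01, 0.6)), 4)
        add(chrom, pos, info, gt, gt, gq_a, dp_a, gq_h, dp_h, "shared", "not_selected")

    # one multiallelic concordant record to exercise per-allele decomposition
    chrom, pos = _pick_position(rng, cfg, used)
    ref = _rand_base(rng)
    alt1 = _rand_base(rng, ref)
    alt2 = _rand_base(rng, ref)
    while alt2 == alt1:
        alt2 = _rand_base(rng, ref)
    gq_a, dp_a = q_pass(rng)
    add(chrom, pos, {"CONSEQUENCE": "intron_variant"}, "1/2", "1/2",
        gq_a, dp_a, gq_a, dp_a, "multiallelic_shared", "not_selected",
        ref=ref, alts=(alt1, alt2))

    sims.sort(key=lambda v: (v.chrom, v.pos))

    # --- SVs -------------------------------------------------------------
    sv_types = ("DEL", "DUP", "INV")
    svs: List[SVRecord] = []
    common_ivs: Dict[str, List[GenomicInterval]] = {t: [] for t in sv_types}
    sv_gene_order = rng.permutation(len(genes))
    gidx = 0
    sid = 0

    def next_gene() -> GeneModel:
        nonlocal gidx
        g = genes[sv_gene_order[gidx % len(genes)]]
        gidx += 1
        return g

    def sv_over_gene(g: GeneModel, rng) -> GenomicInterval:
        s = max(0, g.start - int(rng.integers(0, 1000)))
        e = g.end + int(rng.integers(0, 1000))
        return GenomicInterval(g.chrom, s, e)

    rare_sv_genes: List[str] = []
    for k in range(cfg.n_sv_rare_affected):
        g = next_gene()
        span = sv_over_gene(g, rng)
        impact = "HIGH" if k == 0 else "MODIFIER"
        svs.append(SVRecord(f"sv{sid:03d}", span, sv_types[k % 3], impact, "affected"))
        rare_sv_genes.append(g.name)
        sid += 1
    for k in range(cfg.n_sv_common_affected):
        g = next_gene()
        span = sv_over_gene(g, rng)
        t = sv_types[k % 3]
        svs.append(SVRecord(f"sv{sid:03d}", span, t, "MODIFIER", "affected"))
        common_ivs[t].append(span)  # identical interval in the reference set
        sid += 1
    for k in range(cfg.n_sv_low_impact):
        g = next_gene()
        svs.append(SVRecord(f"sv{sid:03d}", sv_over_gene(g, rng), sv_types[k % 3],
                            "LOW", "affected"))
        sid += 1
    for k in range(cfg.n_sv_shared):
        g = next_gene()
        svs.append(SVRecord(f"sv{sid:03d}", sv_over_gene(g, rng), sv_types[k % 3],
                            "MODIFIER", "both"))
        sid += 1
    for k in range(cfg.n_sv_healthy_only):
        g = next_gene()
        svs.append(SVRecord(f"sv{sid:03d}", sv_over_gene(g, rng), sv_types[k % 3],
                            "MODIFIER", "healthy"))
        sid += 1
    # decoy intervals in the common reference set, overlapping nothing we keep
    for t in sv_types:
        s = int(rng.integers(1000, cfg.chrom_length // 2))
        common_ivs[t].append(GenomicInterval(cfg.chroms[0], s, s + 5000))
    common_set = {t: FeatureTrack(t, ivs) for t, ivs in common_ivs.items()}

    # --- CNVs ------------------------------------------------------------
    cnvs: List[CNVRecord] = []
    cid = 0
    for _ in range(cfg.n_cnv_gains):
        g = next_gene()
        cnvs.append(CNVRecord(f"cnv{cid:02d}", sv_over_gene(g, rng),
                              int(rng.integers(3, 5)), "affected"))
        cid += 1
    for _ in range(cfg.n_cnv_losses):
        g = next_gene()
        cnvs.append(CNVRecord(f"cnv{cid:02d}", sv_over_gene(g, rng),
                              int(rng.integers(0, 2)), "affected"))
        cid += 1
    for _ in range(cfg.n_cnv_neutral):
        g = next_gene()
        cnvs.append(CNVRecord(f"cnv{cid:02d}", sv_over_gene(g, rng), 2, "affected"))
        cid += 1

    return sims, svs, common_set, cnvs


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------


def _baseline_levels(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.meth_alpha is not None and cfg.meth_beta is not None:
        return rng.beta(cfg.meth_alpha, cfg.meth_beta, size=n)
    p = np.empty(n)
    u = rng.random(n)
    start = 0.0
    assigned = np.zeros(n, dtype=bool)
    for w, a, b in METH_MIXTURE:
        sel = (~assigned) & (u < start + w)
        p[sel] = rng.beta(a, b, size=int(sel.sum()))
        assigned |= sel
        start += w
    p[~assigned] = rng.beta(*METH_MIXTURE[0][1:], size=int((~assigned).sum()))
    return p


def simulate_methylomes(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    tracks: Dict[str, FeatureTrack],
    rng: np.random.Generator,
):
    """Generate per-CpG counts for both twins plus the spike-in control.

    Baseline levels are shared between twins (monozygotic germline); planted
    DMC sites shift the affected twin's true level by +/- delta. Coverage is
    negative-binomial around ``cov_mean`` (fixed in noiseless mode).

    Returns (affected sites, healthy sites, lambda sites, planted records).
    """
    # CpG positions, sorted per chromosome
    per_chrom = [cfg.n_cpgs // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_cpgs % cfg.n_chroms):
        per_chrom[i] += 1
    chrom_arr: List[str] = []
    pos_arr: List[np.ndarray] = []
    for ci, chrom in enumerate(cfg.chroms):
        if per_chrom[ci] > cfg.chrom_length - 2:
            raise ValueError("more CpGs requested than genome positions available")
        pos = np.sort(rng.choice(cfg.chrom_length - 2, size=per_chrom[ci], replace=False))
        pos_arr.append(pos)
        chrom_arr.extend([chrom] * per_chrom[ci])
    positions = np.concatenate(pos_arr) if pos_arr else np.array([], dtype=int)
    chroms = np.array(chrom_arr)
    n = positions.size

    # feature membership for planting
    derived = dict(tracks)
    derived["promoter"] = annotation.build_promoters(genes)
    derived["cgi_shore"] = annotation.build_cgi_shores(derived["cgi"])
    derived["promoter_cgi"] = annotation.build_promoter_cgis(
        derived["promoter"], derived["cgi"]
    )

    def member_mask(track: FeatureTrack) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        by_chrom = track.by_chrom()
        for chrom in np.unique(chroms):
            idx = np.where(chroms == chrom)[0]
            pos = positions[idx]
            for iv in by_chrom.get(chrom, ()):
                lo = np.searchsorted(pos, iv.start, side="left")
                hi = np.searchsorted(pos, iv.end - 1, side="right")
                mask[idx[lo:hi]] = True
        return mask

    masks = {name: member_mask(t) for name, t in derived.items()}
    gene_mask = member_mask(FeatureTrack("genes", [g.span for g in genes]))
    any_feature = gene_mask.copy()
    for m in masks.values():
        any_feature |= m
    masks["intergenic"] = ~any_feature

    p_base = _baseline_levels(cfg, n, rng)

    planted_idx: List[int] = []
    planted_meta: List[Tuple[int, str, float, str]] = []  # idx, feature, delta, direction
    taken = np.zeros(n, dtype=bool)
    for feat, count, delta in cfg.planted_dmcs:
        if feat not in masks:
            raise ValueError(f"unknown planted DMC feature class {feat!r}")
        avail = np.where(masks[feat] & ~taken)[0]
        if avail.size < count:
            raise ValueError(
                f"cannot plant {count} DMCs in feature class {feat!r}: only "
                f"{avail.size} unplanted CpGs fall in that class — enlarge the "
                "genome, densify CpGs or reduce the planting request"
            )
        chosen = rng.choice(avail, size=count, replace=False)
        taken[chosen] = True
        for idx in np.sort(chosen):
            direction = "hyper" if rng.random() < 0.5 else "hypo"
            planted_idx.append(int(idx))
            planted_meta.append((int(idx), feat, float(delta), direction))

    # engineered baseline for planted sites: near-extreme start, shifted level
    p_aff = p_base.copy()
    for idx, feat, delta, direction in planted_meta:
        hi = max(0.03, min(0.15, 0.97 - delta / 100.0))
        lo = min(0.02, hi - 0.01)
        base = float(rng.uniform(lo, hi))
        if direction == "hyper":
            p_base[idx] = base
            p_aff[idx] = base + delta / 100.0
        else:
            p_base[idx] = 1.0 - base
            p_aff[idx] = 1.0 - base - delta / 100.0
    p_heal = p_base

    if cfg.noiseless:
        cov = int(round(cfg.cov_mean))
        cov_a = np.full(n, cov)
        cov_h = np.full(n, cov)
        meth_h = np.rint(p_heal * cov).astype(int)
        meth_a = meth_h.copy()
        for idx, feat, delta, direction in planted_meta:
            d = int(np.ceil(delta * cov / 100.0))
            if direction == "hyper":
                meth_a[idx] = min(cov, meth_h[idx] + d)
            else:
                meth_a[idx] = max(0, meth_h[idx] - d)
    else:
        size = cfg.cov_dispersion
        p_nb = size / (size + cfg.cov_mean)
        cov_a = rng.negative_binomial(size, p_nb, size=n)
        cov_h = rng.negative_binomial(size, p_nb, size=n)
        meth_a = rng.binomial(cov_a, p_aff)
        meth_h = rng.binomial(cov_h, p_heal)

    def to_sites(cov, meth):
        out = []
        for i in range(n):
            if cov[i] == 0:
                continue
            out.append(
                CpGSiteCounts(
                    chrom=str(chroms[i]),
                    pos=int(positions[i]),
                    meth=int(meth[i]),
                    unmeth=int(cov[i] - meth[i]),
                )
            )
        return out

    affected_sites = to_sites(cov_a, meth_a)
    healthy_sites = to_sites(cov_h, meth_h)

    # spike-in: fully unmethylated control; apparent methylation = conversion error
    lam_pos = np.arange(cfg.lambda_sites) * 10 + 1
    lam_cov = np.full(cfg.lambda_sites, cfg.lambda_coverage)
    if cfg.noiseless:
        lam_meth = np.rint(lam_cov * cfg.conversion_error).astype(int)
    else:
        lam_meth = rng.binomial(lam_cov, cfg.conversion_error)
    lambda_sites = [
        CpGSiteCounts(LAMBDA_CHROM, int(p), int(m), int(c - m))
        for p, c, m in zip(lam_pos, lam_cov, lam_meth)
    ]

    planted_records = []
    for idx, feat, delta, direction in planted_meta:
        ca, ch = int(cov_a[idx]), int(cov_h[idx])
        la = 100.0 * meth_a[idx] / ca if ca else None
        lh = 100.0 * meth_h[idx] / ch if ch else None
        planted_records.append(
            {
                "chrom": str(chroms[idx]),
                "pos": int(positions[idx]),
                "feature": feat,
                "delta": delta,
                "direction": direction,
                "true_level_affected": round(100.0 * p_aff[idx], 4),
                "true_level_healthy": round(100.0 * p_heal[idx], 4),
                "emitted_diff": None if la is None or lh is None else round(la - lh, 4),
            }
        )
    return affected_sites, healthy_sites, lambda_sites, planted_records, derived


# ---------------------------------------------------------------------------
# VCF writer
# ---------------------------------------------------------------------------

_VCF_INFO_HEADER = """##INFO=<ID=CONSEQUENCE,Number=1,Type=String,Description="Pre-reduced consequence class">
##INFO=<ID=AF_1000G,Number=A,Type=Float,Description="1000 Genomes global allele frequency">
##INFO=<ID=AF_GNOMAD,Number=A,Type=Float,Description="gnomAD global allele frequency">
##INFO=<ID=POLYPHEN,Number=1,Type=String,Description="PolyPhen-2 verdict">
##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT verdict">
##INFO=<ID=MUTATIONTASTER,Number=1,Type=String,Description="MutationTaster2 verdict">
##INFO=<ID=CADD_PHRED,Number=1,Type=Float,Description="CADD Phred-scaled score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

SAMPLE_AFFECTED = "TWIN_TOF"
SAMPLE_HEALTHY = "TWIN_H"


def write_twin_vcf(sims: Sequence[_SimVariant], cfg: SimulationConfig, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in cfg.chroms:
            fh.write(f"##contig=<ID={chrom},length={cfg.chrom_length}>\n")
        fh.write(_VCF_INFO_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{SAMPLE_AFFECTED}\t{SAMPLE_HEALTHY}\n"
        )
        for v in sims:
            info = ";".join(f"{k}={val}" for k, val in sorted(v.info.items()))
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{','.join(v.alts)}\t50\tPASS\t"
                f"{info or '.'}\tGT:DP:GQ\t"
                f"{v.gt_affected}:{v.dp_a}:{v.gq_a}\t{v.gt_healthy}:{v.dp_h}:{v.gq_h}\n"
            )


# ---------------------------------------------------------------------------
# Dataset emission with truth manifest
# ---------------------------------------------------------------------------


def _expected_variant_funnel(sims: Sequence[_SimVariant]) -> Dict[str, List[int]]:
    uniq = [v for v in sims if v.truth_class in (
        "coding_damaging", "coding_tolerated", "noncoding_high_cadd",
        "noncoding_low_cadd", "common", "low_quality")]
    n0 = len(uniq)
    n1 = n0 - sum(1 for v in uniq if v.expected_fate == "removed_quality")
    n2 = n1 - sum(1 for v in uniq if v.expected_fate == "removed_rarity")
    n3 = n2 - sum(1 for v in uniq if v.expected_fate == "removed_consequence")
    nz = sum(1 for v in sims if v.truth_class == "zygosity_diff")
    return {"unique": [n0, n1, n2, n3], "zygosity": [nz, nz, nz, nz]}


def emit_dataset(cfg: SimulationConfig, outdir: str, force: bool = False) -> dict:
    """Write the complete dataset plus ``truth.json`` and return the manifest."""
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(
            f"output directory {outdir!r} is not empty (pass force=True to overwrite)"
        )
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes, tracks = simulate_feature_tracks(cfg, rng)
    sims, svs, common_set, cnvs = simulate_twin_genomes(cfg, genes, rng)
    aff, heal, lam, planted_dmcs, derived = simulate_methylomes(cfg, genes, tracks, rng)

    # ----- expected outcomes ------------------------------------------------
    funnel = _expected_variant_funnel(sims)
    surv = [v for v in sims if v.expected_fate == "survivor"]
    zyg_surv = [v for v in sims if v.expected_fate == "zygosity_survivor"]

    sv_survivors = svcnv.filter_svs(svs, common_set)
    sv_genes = svcnv.genes_affected(sv_survivors, genes)
    cnv_kept = svcnv.filter_cnvs(cnvs)
    cnv_genes = svcnv.genes_affected(cnv_kept, genes)

    # nominations (same rule the pipeline applies)
    nominations: Dict[str, set] = {}

    def nominate(gene: str, source: str) -> None:
        nominations.setdefault(gene, set()).add(source)

    for v in surv:
        site = GenomicInterval(v.chrom, v.pos, v.pos + 1)
        for gname, _d in annotation.nearest_gene(site, genes):
            nominate(gname, "variant")
    for gname in sv_genes:
        nominate(gname, "sv")
    for gname in cnv_genes:
        nominate(gname, "cnv")

    track_list = [derived[k] for k in
                  ("promoter", "cgi", "promoter_cgi", "cgi_shore", "tfbs",
                   "cardiac_tfbs", "enhancer")]
    dmc_sites = [GenomicInterval(d["chrom"], d["pos"], d["pos"] + 1) for d in planted_dmcs]
    annotated = annotation.overlap_sites(dmc_sites, track_list, genes=genes)
    for ann in annotated:
        if "promoter_cgi" in ann.feature_hits:
            for gname, _d in ann.nearest_genes:
                nominate(gname, "dmc_promoter_cgi")
        if ("tfbs_in_promoter" in ann.feature_hits
                or "cardiac_tfbs_in_promoter" in ann.feature_hits):
            for gname, _d in ann.nearest_genes:
                nominate(gname, "dmc_tfbs_promoter")

    expected_counts = annotation.summarize_feature_counts(annotated)

    # expression: nominated genes expressed, except one SV-nominated decoy
    decoy = None
    for gname in sorted(sv_genes):
        if len(nominations.get(gname, ())) == 1:
            decoy = gname
            break
    datasets = ("RV_normal", "RV_TOF", "CM_day15", "CM_day60")
    expression: Dict[str, Dict[str, float]] = {d: {} for d in datasets}
    for g in genes:
        nominated = g.name in nominations
        for d in datasets:
            if g.name == decoy:
                val = round(float(rng.uniform(0.0, 1.0)), 3)
            elif nominated:
                val = round(float(rng.uniform(1.5, 60.0)), 3)
            else:
                val = round(float(rng.uniform(0.0, 2.0)), 3)
            expression[d][g.name] = val

    gene_lists: Dict[str, List[str]] = {}
    nominated_sorted = sorted(nominations)
    from .prioritize import EVIDENCE_LABELS

    for li, label in enumerate(EVIDENCE_LABELS):
        members: List[str] = []
        for k in range(min(2, len(nominated_sorted))):
            members.append(nominated_sorted[(li + k) % len(nominated_sorted)]
                           if nominated_sorted else "")
        extra = rng.permutation(len(genes))[:2]
        members.extend(genes[int(i)].name for i in extra)
        gene_lists[label] = sorted(set(m for m in members if m))

    expected_candidates = sorted(g for g in nominations if g != decoy)

    lam_meth = sum(s.meth for s in lam)
    lam_total = sum(s.coverage for s in lam)
    achieved_conversion = (
        100.0 - 100.0 * lam_meth / lam_total if lam_total else None
    )

    manifest = {
        "seed": cfg.seed,
        "noiseless": cfg.noiseless,
        "samples": {"affected": SAMPLE_AFFECTED, "healthy": SAMPLE_HEALTHY},
        "variants": [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alts": list(v.alts),
                "class": v.truth_class,
                "expected_fate": v.expected_fate,
            }
            for v in sims
        ],
        "expected_variant_funnel": funnel,
        "expected_variant_survivors": sorted((v.chrom, v.pos) for v in surv),
        "expected_zygosity_survivors": sorted((v.chrom, v.pos) for v in zyg_surv),
        "expected_sv_survivors": sorted(s.record_id for s in sv_survivors),
        "expected_sv_genes": {g: sorted(ids) for g, ids in sorted(sv_genes.items())},
        "expected_cnv_classes": {
            "gain": sum(1 for c in cnv_kept if svcnv.classify_cnv(c) == "gain"),
            "loss": sum(1 for c in cnv_kept if svcnv.classify_cnv(c) == "loss"),
        },
        "expected_cnv_genes": {g: sorted(ids) for g, ids in sorted(cnv_genes.items())},
        "planted_dmcs": planted_dmcs,
        "expected_dmc_positions": sorted((d["chrom"], d["pos"]) for d in planted_dmcs),
        "expected_feature_counts": expected_counts,
        "expected_candidates": expected_candidates,
        "expected_candidates_soft": sorted(nominations),
        "nominations": {g: sorted(s) for g, s in sorted(nominations.items())},
        "decoy_gene": decoy,
        "achieved_conversion_rate": achieved_conversion,
        "true_conversion_rate": 100.0 * (1.0 - cfg.conversion_error),
    }

    # ----- write files ------------------------------------------------------
    write_gene_models(genes, os.path.join(outdir, "genes.tsv"))
    for name in ("cgi", "tfbs", "cardiac_tfbs", "enhancer"):
        write_feature_bed(tracks[name], os.path.join(outdir, f"{name}.bed"))
    write_twin_vcf(sims, cfg, os.path.join(outdir, "twins.vcf"))
    svcnv.write_sv_table(svs, os.path.join(outdir, "svs.tsv"))
    svcnv.write_cnv_table(cnvs, os.path.join(outdir, "cnvs.tsv"))
    for t, track in common_set.items():
        write_feature_bed(track, os.path.join(outdir, f"common_sv_{t}.bed"))
    write_methylation_counts(aff, os.path.join(outdir, "methylation.affected.cov"))
    write_methylation_counts(heal, os.path.join(outdir, "methylation.healthy.cov"))
    write_methylation_counts(lam, os.path.join(outdir, "lambda.cov"))
    os.makedirs(os.path.join(outdir, "gene_lists"), exist_ok=True)
    for label, members in gene_lists.items():
        with open(os.path.join(outdir, "gene_lists", f"{label}.txt"), "w") as fh:
            fh.write("\n".join(members) + ("\n" if members else ""))
    with open(os.path.join(outdir, "expression.tsv"), "w") as fh:
        fh.write("gene\t" + "\t".join(datasets) + "\n")
        for g in genes:
            vals = "\t".join(f"{expression[d][g.name]}" for d in datasets)
            fh.write(f"{g.name}\t{vals}\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
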