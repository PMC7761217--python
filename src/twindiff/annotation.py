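"""Regulatory feature construction, interval overlap and nearest-gene logic.

Derived tracks built here: strand-aware promoter windows around each TSS, CGI
shores (2 kb flanks outside any island) and promoter-CGIs (base-pair
intersection of promoter and island tracks). Sites (DMCs, variants) are then
annotated with every feature class they intersect by >=1 bp under half-open
semantics, assigned a nearest gene, and summarised per feature class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .model import (
    COMPOSITE_LABELS,
    FeatureTrack,
    GeneModel,
    GenomicInterval,
    ThresholdConfig,
)

# Two promoter-window conventions around the TSS seen in the field; the
# default anchors a short upstream and long downstream window.
PROMOTER_ORIENTATIONS = {
    "minus500_plus2k": (500, 2000),
    "minus2k_plus500": (2000, 500),
}


@dataclass(frozen=True)
class PromoterDefinition:
    """Promoter window in bp around the TSS, strand-aware.

    ``upstream`` extends against the direction of transcription, ``downstream``
    with it. Construct from a named convention with :meth:`from_orientation`.
    """

    upstream: int = 500
    downstream: int = 2000

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("promoter extents must be >= 0")

    @classmethod
    def from_orientation(cls, name: str) -> "PromoterDefinition":
        try:
            up, down = PROMOTER_ORIENTATIONS[name]
        except KeyError:
            raise ValueError(
                f"unknown promoter orientation {name!r}; "
                f"choose from {sorted(PROMOTER_ORIENTATIONS)}"
            ) from None
        return cls(upstream=up, downstream=down)


@dataclass
class AnnotatedSite:
    """A site with its feature hits, location class and nearest gene(s)."""

    site: GenomicInterval
    feature_hits: set = field(default_factory=set)
    location_class: Optional[str] = None  # exonic | intronic | intergenic
    nearest_genes: List[Tuple[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Interval set arithmetic (per chromosome, half-open)
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals as disjoint sorted intervals (labels dropped)."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> List[GenomicInterval]:
    """Base set difference a \\ b, both treated as unions."""
    a_merged = merge_intervals(a)
    b_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in merge_intervals(b):
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for iv in a_merged:
        cuts = b_by_chrom.get(iv.chrom, ())
        pos = iv.start
        for cut in cuts:
            if cut.end <= pos or cut.start >= iv.end:
                continue
            if cut.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, cut.start))
            pos = max(pos, cut.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return out


def intersect_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> List[GenomicInterval]:
    """Base set intersection of two interval unions."""
    a_merged = merge_intervals(a)
    b_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in merge_intervals(b):
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for iv in a_merged:
        for other in b_by_chrom.get(iv.chrom, ()):
            s, e = max(iv.start, other.start), min(iv.end, other.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return out


# ---------------------------------------------------------------------------
# Derived track construction
# ---------------------------------------------------------------------------


def build_promoters(
    genes: Iterable[GeneModel], pdef: Optional[PromoterDefinition] = None
) -> FeatureTrack:
    """Strand-aware promoter windows, one labeled interval per gene.

    '+' strand TSS t spans [t - upstream, t + downstream); '-' strand mirrors
    it as [t - downstream + 1, t + upstream + 1). Windows are clipped at 0.
    Overlapping promoters of different genes are kept separate so gene
    attribution survives.
    """
    pdef = pdef or PromoterDefinition()
    intervals = []
    for g in genes:
        t = g.tss
        if g.strand == "+":
            s, e = t - pdef.upstream, t + pdef.downstream
        else:
            s, e = t - pdef.downstream + 1, t + pdef.upstream + 1
        s = max(0, s)
        if e > s:
            intervals.append(GenomicInterval(g.chrom, s, e, g.strand, g.name))
    return FeatureTrack(name="promoter", intervals=intervals)


def build_cgi_shores(
    cgis: FeatureTrack, cfg: Optional[ThresholdConfig] = None
) -> FeatureTrack:
    """Regions outside any CpG island but within ``shore_width`` bp of one.

    Union of both-side flanks of every island minus the union of all island
    bodies; the result is merged and sorted. Flanks are clipped at 0.
    """
    width = (cfg or ThresholdConfig()).shore_width
    flanks = []
    for iv in cgis:
        if iv.start > 0:
            flanks.append(
                GenomicInterval(iv.chrom, max(0, iv.start - width), iv.start)
            )
        flanks.append(GenomicInterval(iv.chrom, iv.end, iv.end + width))
    shores = subtract_intervals(flanks, cgis.intervals) if flanks else []
    return FeatureTrack(name="cgi_shore", intervals=shores)


def build_promoter_cgis(promoters: FeatureTrack, cgis: FeatureTrack) -> FeatureTrack:
    """Base-pair intersection (>=1 bp) of the promoter and CGI tracks."""
    return FeatureTrack(
        name="promoter_cgi",
        intervals=intersect_intervals(promoters.intervals, cgis.intervals),
    )


# ---------------------------------------------------------------------------
# Overlap, nearest gene, location
# ---------------------------------------------------------------------------


def _build_trees(tracks: Sequence[FeatureTrack]) -> Dict[str, Dict[str, IntervalTree]]:
    trees: Dict[str, Dict[str, IntervalTree]] = {}
    for track in tracks:
        per_chrom: Dict[str, IntervalTree] = {}
        for iv in track:
            per_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        trees[track.name] = per_chrom
    return trees


def overlap_sites(
    sites: Iterable[GenomicInterval],
    tracks: Sequence[FeatureTrack],
    genes: Optional[Sequence[GeneModel]] = None,
) -> List[AnnotatedSite]:
    """Annotate each site with every feature class it intersects by >=1 bp.

    Composite labels (tfbs_in_promoter, cardiac_tfbs_in_promoter) are added
    when the site simultaneously hits both parent tracks. When gene models are
    supplied, the location class and nearest gene(s) are filled in as well.
    """
    trees = _build_trees(tracks)
    gene_list = list(genes) if genes is not None else None
    out: List[AnnotatedSite] = []
    for site in sites:
        hits = set()
        for name, per_chrom in trees.items():
            tree = per_chrom.get(site.chrom)
            if tree is not None and tree.overlap(site.start, site.end):
                hits.add(name)
        for comp, (p1, p2) in COMPOSITE_LABELS.items():
            if p1 in hits and p2 in hits:
                hits.add(comp)
        ann = AnnotatedSite(site=site, feature_hits=hits)
        if gene_list is not None:
            ann.nearest_genes = nearest_gene(site, gene_list)
            ann.location_class = classify_location(site, gene_list)
        out.append(ann)
    return out


def nearest_gene(
    site: GenomicInterval, genes: Sequence[GeneModel]
) -> List[Tuple[str, int]]:
    """All genes at minimal span distance from the site, with signed distance.

    Distance is 0 when the site overlaps the gene span; otherwise the gap in
    bp, negative when the gene lies to the left of the site (site downstream
    of the gene end in genome coordinates), positive to the right. Returns an
    empty list when no gene shares the site's chromosome (unassigned).
    """
    best: List[Tuple[str, int]] = []
    best_abs: Optional[int] = None
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.name)):
        if g.chrom != site.chrom:
            continue
        if site.start < g.end and g.start < site.end:
            d = 0
        elif g.end <= site.start:
            d = -(site.start - g.end + 1)
        else:
            d = g.start - site.end + 1
        if best_abs is None or abs(d) < best_abs:
            best, best_abs = [(g.name, d)], abs(d)
        elif abs(d) == best_abs:
            best.append((g.name, d))
    return best


def classify_location(site: GenomicInterval, genes: Sequence[GeneModel]) -> str:
    """exonic > intronic > intergenic, single label.

    A gene without exon blocks contributes its whole span as exonic.
    """
    in_gene = False
    for g in genes:
        if g.chrom != site.chrom or not (site.start < g.end and g.start < site.end):
            continue
        in_gene = True
        if g.exons is None:
            return "exonic"
        for s, e in g.exons:
            if site.start < e and s < site.end:
                return "exonic"
    return "intronic" if in_gene else "intergenic"


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

#: Summary row order and human-readable labels for the per-feature table.
SUMMARY_ROWS = (
    ("total", "DMCs total"),
    ("promoter", "DMCs in promoters"),
    ("cgi", "DMCs in CpG islands (CGIs)"),
    ("promoter_cgi", "DMCs in promoter CGIs"),
    ("cgi_shore", "DMCs in CGI shores"),
    ("tfbs", "DMCs at TFBS"),
    ("cardiac_tfbs", "DMCs at cardiac TFBS"),
    ("tfbs_in_promoter", "DMCs at TFBS in promoters"),
    ("cardiac_tfbs_in_promoter", "DMCs at cardiac TFBS in promoters"),
    ("enhancer", "DMCs in cardiac enhancers (p300)"),
)


def summarize_feature_counts(annotated: Iterable[AnnotatedSite]) -> Dict[str, int]:
    """Per-feature site counts; rows are not mutually exclusive.

    Each site is counted once per feature class it hits, plus once in 'total'.
    """
    counts = {key: 0 for key, _ in SUMMARY_ROWS}
    for ann in annotated:
        counts["total"] += 1
        for key, _ in SUMMARY_ROWS:
            if key != "total" and key in ann.feature_hits:
                counts[key] += 1
    return counts


def summarize_locations(annotated: Iterable[AnnotatedSite]) -> Dict[str, int]:
    counts = {"exonic": 0, "intronic": 0, "intergenic": 0}
    for ann in annotated:
        if ann.location_class:
            counts[ann.location_class] += 1
    return counts


def write_feature_summary_tsv(counts: Dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tcount\n")
        for key, label in SUMMARY_ROWS:
            fh.write(f"{label}\t{counts.get(key, 0)}\n")
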