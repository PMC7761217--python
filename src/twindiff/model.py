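"""Core coordinate model, domain types and readers/writers for standard formats.

All internal coordinates are 0-based, half-open ``[start, end)``. Conversions
to/from 1-based conventions (VCF, bismark coverage) happen only at the format
boundary, in the readers and writers below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, Optional

import pysam

logger = logging.getLogger("twindiff")

# Closed vocabulary of regulatory feature-class labels used in annotation.
FEATURE_LABELS = frozenset(
    {
        "cgi",
        "tfbs",
        "cardiac_tfbs",
        "enhancer",
        "promoter",
        "cgi_shore",
        "promoter_cgi",
    }
)

# Composite labels: a site carries one iff it hits both parent tracks.
COMPOSITE_LABELS = {
    "tfbs_in_promoter": ("tfbs", "promoter"),
    "cardiac_tfbs_in_promoter": ("cardiac_tfbs", "promoter"),
}


class FormatError(ValueError):
    """Malformed input file (carries file context and line number when known)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome.

    ``label`` optionally attributes the interval to a source entity (e.g. the
    gene whose promoter it is); it does not participate in overlap logic.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self):
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand-aware TSS and optional exon blocks.

    The TSS is derived from the strand: span start on '+', span end - 1 on '-'.
    ``exons`` are half-open sub-intervals of the span; ``None`` means the gene
    has no block structure recorded (the whole span is treated as exonic).
    """

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: Optional[tuple] = None  # tuple of (start, end) pairs

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("gene span must be non-empty")
        if self.exons is not None:
            for s, e in self.exons:
                if not (self.start <= s < e <= self.end):
                    raise ValueError(f"exon [{s},{e}) outside gene span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.name)


@dataclass
class FeatureTrack:
    """A named, position-sorted collection of genomic intervals."""

    name: str
    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=GenomicInterval.sort_key)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def by_chrom(self) -> dict:
        out: dict = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)


@dataclass
class ThresholdConfig:
    """Every numeric cutoff of the comparison pipeline, with field defaults.

    min_gq / min_dp        genotype-quality and read-depth floors (inclusive)
    max_maf                population allele frequency at/above which a variant
                           is treated as common and removed
    min_cadd               Phred-scaled deleteriousness floor for non-coding
                           variants (strict: retained only if score > min_cadd)
    dmc_min_diff           minimum absolute co-twin methylation difference, in
                           percentage points (inclusive)
    meth_min_cov/max_cov   per-sample CpG coverage window (inclusive both ends)
    promoter_upstream/downstream  promoter window around the TSS, in bp
    shore_width            CGI shore flank width in bp
    min_expression         RPKM/TPM floor (strict: expressed iff value > this)
    sv_reciprocal_overlap  reciprocal-overlap fraction at/above which two
                           same-type SVs are considered the same (common) event
    """

    min_gq: int = 20
    min_dp: int = 10
    max_maf: float = 0.01
    min_cadd: float = 15.0
    dmc_min_diff: float = 25.0
    meth_min_cov: int = 10
    meth_max_cov: int = 500
    promoter_upstream: int = 500
    promoter_downstream: int = 2000
    shore_width: int = 2000
    min_expression: float = 1.0
    sv_reciprocal_overlap: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.meth_min_cov > self.meth_max_cov:
            raise ValueError("meth_min_cov must not exceed meth_max_cov")
        if not 0.0 <= self.max_maf <= 1.0:
            raise ValueError("max_maf must lie in [0, 1]")


@dataclass(frozen=True)
class TwinVariantCall:
    """One small variant (post multiallelic split) with co-twin genotypes.

    Genotypes are recoded against the single ALT allele of the record:
    homref / het / homalt / missing. Annotation fields that were absent in the
    source VCF stay ``None`` — absence is never coerced to zero.
    """

    site: GenomicInterval
    ref: str
    alt: str
    variant_class: str  # snv | indel
    gt_affected: str
    gt_healthy: str
    dp_affected: Optional[int] = None
    dp_healthy: Optional[int] = None
    gq_affected: Optional[int] = None
    gq_healthy: Optional[int] = None
    consequence: Optional[str] = None
    coding: Optional[bool] = None
    maf: Optional[float] = None
    predictor_verdicts: tuple = ()  # ((tool, verdict), ...) verdict: damaging|tolerated
    cadd: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        for v in (self.dp_affected, self.dp_healthy, self.gq_affected, self.gq_healthy):
            if v is not None and v < 0:
                raise ValueError("depths and qualities must be >= 0")
        expect = "snv" if len(self.ref) == len(self.alt) == 1 else "indel"
        if self.variant_class != expect:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with alleles "
                f"{self.ref}>{self.alt}"
            )

    def verdict(self, tool: str) -> str:
        for t, v in self.predictor_verdicts:
            if t == tool:
                return v
        return "absent"


@dataclass(frozen=True)
class SVRecord:
    """Structural variant call with type, annotated impact and carrier."""

    record_id: str
    span: GenomicInterval
    sv_type: str  # DEL | DUP | INS | INV | BND
    impact: str  # HIGH | MODERATE | LOW | MODIFIER
    carrier: str  # affected | healthy | both

    def __post_init__(self) -> None:
        if self.sv_type not in ("DEL", "DUP", "INS", "INV", "BND"):
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.impact not in ("HIGH", "MODERATE", "LOW", "MODIFIER"):
            raise ValueError(f"unknown impact {self.impact!r}")
        if self.carrier not in ("affected", "healthy", "both"):
            raise ValueError(f"unknown carrier {self.carrier!r}")
        if self.sv_type == "BND" and len(self.span) != 1:
            raise ValueError("BND spans must be single-base anchors")


@dataclass(frozen=True)
class CNVRecord:
    """Copy-number segment with integer copy number and carrier."""

    record_id: str
    span: GenomicInterval
    copy_number: int
    carrier: str

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.carrier not in ("affected", "healthy", "both"):
            raise ValueError(f"unknown carrier {self.carrier!r}")


@dataclass(frozen=True)
class CpGSiteCounts:
    """Methylated/unmethylated read counts at one cytosine position."""

    chrom: str
    pos: int  # 0-based
    meth: int
    unmeth: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.meth < 0 or self.unmeth < 0:
            raise ValueError("counts must be non-negative")
        if self.pos < 0:
            raise ValueError("position must be >= 0")

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth

    @property
    def site(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1, self.strand)


@dataclass(frozen=True)
class DMCRecord:
    """A differentially methylated CpG between the co-twins.

    ``diff`` is signed percentage points (affected − healthy); ``direction`` is
    hyper iff the affected twin is more methylated.
    """

    chrom: str
    pos: int
    level_affected: float
    level_healthy: float
    diff: float
    direction: str  # hyper | hypo
    cov_affected: int = 0
    cov_healthy: int = 0
    fisher_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be hyper or hypo")
        if (self.diff > 0) != (self.direction == "hyper"):
            raise ValueError("direction inconsistent with sign of diff")

    @property
    def site(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1)


@dataclass(frozen=True)
class ConversionQC:
    """Bisulfite conversion-rate estimate from the unmethylated spike-in."""

    lambda_meth: int
    lambda_unmeth: int
    conversion_rate: Optional[float]  # percent; None when no spike-in coverage

    @property
    def available(self) -> bool:
        return self.conversion_rate is not None


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

#: Default INFO-key names for pre-computed annotations; override to adapt to a
#: different annotator's VCF output.
DEFAULT_ANNOTATION_KEYS = {
    "consequence": "CONSEQUENCE",
    "maf": ("AF_1000G", "AF_GNOMAD"),
    "polyphen2": "POLYPHEN",
    "sift": "SIFT",
    "mutationtaster": "MUTATIONTASTER",
    "cadd": "CADD_PHRED",
}

_DAMAGING_WORDS = ("damaging", "deleterious", "disease_causing", "disease causing")
_TOLERATED_WORDS = ("tolerated", "benign", "polymorphism", "neutral")


def _normalize_verdict(raw: Optional[str]) -> str:
    if raw is None:
        return "absent"
    low = str(raw).lower()
    if any(w in low for w in _DAMAGING_WORDS):
        return "damaging"
    if any(w in low for w in _TOLERATED_WORDS):
        return "tolerated"
    return "absent"


def _gt_for_allele(gt: tuple, allele_index: int) -> str:
    """Recode a raw GT tuple against one ALT allele (1-based allele index)."""
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return "missing"
    n = sum(1 for a in gt if a == allele_index)
    if n == 0:
        return "homref"
    if n == len(gt):
        return "homalt"
    return "het"


def _info_get(rec, key):
    """INFO lookup tolerant of keys absent from the header (treated as absent)."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _scalar(value, allele_idx: int):
    """Pick the per-allele entry out of a Number=A INFO value, if needed."""
    if isinstance(value, (tuple, list)):
        if allele_idx < len(value):
            value = value[allele_idx]
        else:
            value = value[0]
    return value


def read_vcf_records(
    path: str,
    sample_affected: str,
    sample_healthy: str,
    annotation_keys: Optional[dict] = None,
) -> Iterator[TwinVariantCall]:
    """Stream co-twin variant calls from a (plain-text) VCF.

    Multiallelic records are split into one call per ALT allele, genotypes
    recoded against each allele. VCF POS (1-based) is converted to the 0-based
    half-open internal convention. Missing annotations stay absent.
    """
    keys = dict(DEFAULT_ANNOTATION_KEYS)
    if annotation_keys:
        keys.update(annotation_keys)

    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    for s in (sample_affected, sample_healthy):
        if s not in samples:
            raise FormatError(f"sample column {s!r} not present in {path}")

    for rec in vf:
        alts = rec.alts or ()
        for ai, alt in enumerate(alts):
            try:
                gt_a = _gt_for_allele(rec.samples[sample_affected].get("GT"), ai + 1)
                gt_h = _gt_for_allele(rec.samples[sample_healthy].get("GT"), ai + 1)
            except (KeyError, TypeError) as exc:  # pragma: no cover - defensive
                raise FormatError(
                    f"malformed genotype at {rec.chrom}:{rec.pos} in {path}"
                ) from exc

            def fmt_int(sample, key):
                v = rec.samples[sample].get(key)
                return int(v) if v is not None else None

            csq = _info_get(rec, keys["consequence"])
            csq = _scalar(csq, ai)
            if isinstance(csq, (tuple, list)):
                csq = csq[0]

            mafs = []
            for k in keys["maf"]:
                v = _info_get(rec, k)
                if v is not None:
                    v = _scalar(v, ai)
                    if v is not None:
                        mafs.append(float(v))
            maf = max(mafs) if mafs else None

            verdicts = []
            for tool in ("polyphen2", "sift", "mutationtaster"):
                raw = _info_get(rec, keys[tool])
                raw = _scalar(raw, ai)
                v = _normalize_verdict(raw)
                if v != "absent":
                    verdicts.append((tool, v))

            cadd = _info_get(rec, keys["cadd"])
            cadd = _scalar(cadd, ai)
            cadd = float(cadd) if cadd is not None else None

            vclass = "snv" if len(rec.ref) == 1 and len(alt) == 1 else "indel"
            start = rec.pos - 1  # VCF is 1-based
            yield TwinVariantCall(
                site=GenomicInterval(rec.chrom, start, start + max(1, len(rec.ref))),
                ref=rec.ref,
                alt=alt,
                variant_class=vclass,
                gt_affected=gt_a,
                gt_healthy=gt_h,
                dp_affected=fmt_int(sample_affected, "DP"),
                dp_healthy=fmt_int(sample_healthy, "DP"),
                gq_affected=fmt_int(sample_affected, "GQ"),
                gq_healthy=fmt_int(sample_healthy, "GQ"),
                consequence=str(csq) if csq is not None else None,
                coding=None,
                maf=maf,
                predictor_verdicts=tuple(verdicts),
                cadd=cadd,
            )


# ---------------------------------------------------------------------------
# Methylation count files (bismark-coverage dialect)
# ---------------------------------------------------------------------------


def read_methylation_counts(path: str) -> Iterator[CpGSiteCounts]:
    """Stream per-cytosine counts from a bismark-coverage file.

    Columns: chrom, start (1-based), end, methylation percentage, methylated
    count, unmethylated count. The stored percentage is ignored — levels are
    always recomputed from the counts downstream.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            chrom, start_s, _end, _pct, meth_s, unmeth_s = parts[:6]
            try:
                start = int(start_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer count field") from exc
            if meth < 0 or unmeth < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            yield CpGSiteCounts(chrom=chrom, pos=start - 1, meth=meth, unmeth=unmeth)


def write_methylation_counts(sites: Iterable[CpGSiteCounts], path: str) -> None:
    """Write counts in the bismark-coverage dialect (1-based, recomputed %)."""
    with open(path, "w") as fh:
        for s in sites:
            pct = 100.0 * s.meth / s.coverage if s.coverage else 0.0
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.pos + 1}\t{pct:.6g}\t{s.meth}\t{s.unmeth}\n"
            )


# ---------------------------------------------------------------------------
# BED feature tracks
# ---------------------------------------------------------------------------


def read_feature_bed(path: str, name: str) -> FeatureTrack:
    """Read a BED3+ file into a sorted FeatureTrack (intervals not merged)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start_s, end_s = parts[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            label = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, label))
    return FeatureTrack(name=name, intervals=intervals)


def write_feature_bed(track: FeatureTrack, path: str) -> None:
    with open(path, "w") as fh:
        for iv in track:
            label = iv.label if iv.label is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene models and simple TSV inputs
# ---------------------------------------------------------------------------


def read_gene_models(path: str) -> list:
    """Read gene models from a headered TSV.

    Required columns: chrom, start, end, strand, name. Optional: gene_id,
    exon_starts, exon_ends (comma-separated half-open blocks). Duplicate gene
    names are kept, with a warning.
    """
    genes = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for col in ("chrom", "start", "end", "strand", "name"):
            if col not in idx:
                raise FormatError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            strand = parts[idx["strand"]]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            name = parts[idx["name"]]
            if name in seen:
                logger.warning("duplicate gene name %r in %s (both kept)", name, path)
            seen.add(name)
            exons = None
            if "exon_starts" in idx and "exon_ends" in idx:
                ss, es = parts[idx["exon_starts"]], parts[idx["exon_ends"]]
                if ss and es:
                    starts = [int(x) for x in ss.split(",") if x]
                    ends = [int(x) for x in es.split(",") if x]
                    exons = tuple(zip(starts, ends))
            genes.append(
                GeneModel(
                    gene_id=parts[idx["gene_id"]] if "gene_id" in idx else name,
                    name=name,
                    chrom=parts[idx["chrom"]],
                    start=int(parts[idx["start"]]),
                    end=int(parts[idx["end"]]),
                    strand=strand,
                    exons=exons,
                )
            )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tname\tgene_id\texon_starts\texon_ends\n")
        for g in genes:
            if g.exons:
                ss = ",".join(str(s) for s, _ in g.exons)
                es = ",".join(str(e) for _, e in g.exons)
            else:
                ss = es = ""
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.name}\t{g.gene_id}\t{ss}\t{es}\n"
            )


def read_gene_list(path: str) -> list:
    """One gene symbol per line; case preserved, duplicates dropped with warning."""
    out, seen = [], set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            key = sym.upper()
            if key in seen:
                logger.warning("duplicate symbol %r in %s (deduplicated)", sym, path)
                continue
            seen.add(key)
            out.append(sym)
    return out


def read_expression_tables(path: str) -> dict:
    """Read a wide expression TSV (gene + one column per dataset).

    Returns ``{dataset: {GENE_UPPER: value}}``.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0].lower() != "gene":
            raise FormatError(f"{path}: first column must be 'gene'")
        datasets = header[1:]
        tables: dict = {d: {} for d in datasets}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            gene = parts[0].upper()
            for d, raw in zip(datasets, parts[1:]):
                if raw in ("", "NA", "."):
                    continue
                try:
                    tables[d][gene] = float(raw)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad value {raw!r}") from exc
    return tables
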