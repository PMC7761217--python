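"""Structural-variant and copy-number screening for the affected twin.

Keeps SVs that are unique to the affected twin, rare against a common-SV
reference set (reciprocal overlap), and of HIGH or MODIFIER predicted impact;
classifies CNV segments as gain/loss/neutral against diploid baseline; maps
surviving records to overlapping genes.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional

from .model import (
    CNVRecord,
    FeatureTrack,
    FormatError,
    GeneModel,
    GenomicInterval,
    SVRecord,
    ThresholdConfig,
)

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


def classify_cnv(cnv: CNVRecord, baseline: int = 2) -> str:
    """gain / loss / neutral relative to the (autosomal) baseline copy number."""
    if cnv.copy_number > baseline:
        return "gain"
    if cnv.copy_number < baseline:
        return "loss"
    return "neutral"


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 for different chromosomes."""
    ov = a.overlap_length(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def is_common_sv(
    sv: SVRecord,
    common_set: Dict[str, FeatureTrack],
    cfg: Optional[ThresholdConfig] = None,
) -> bool:
    """True iff a same-type reference interval reciprocally overlaps the SV
    by at least the configured fraction."""
    cfg = cfg or ThresholdConfig()
    track = common_set.get(sv.sv_type)
    if track is None:
        return False
    for iv in track:
        if reciprocal_overlap(sv.span, iv) >= cfg.sv_reciprocal_overlap:
            return True
    return False


def filter_svs(
    svs: Iterable[SVRecord],
    common_set: Dict[str, FeatureTrack],
    cfg: Optional[ThresholdConfig] = None,
) -> List[SVRecord]:
    """Affected-only, rare, HIGH- or MODIFIER-impact SVs."""
    cfg = cfg or ThresholdConfig()
    return [
        sv
        for sv in svs
        if sv.carrier == "affected"
        and sv.impact in ("HIGH", "MODIFIER")
        and not is_common_sv(sv, common_set, cfg)
    ]


def filter_cnvs(
    cnvs: Iterable[CNVRecord],
    exclude_chroms: frozenset = SEX_CHROMS,
) -> List[CNVRecord]:
    """Affected-only, non-neutral autosomal CNV segments.

    Sex chromosomes are excluded by default because gain/loss calls against a
    fixed diploid baseline are not meaningful there without per-sample ploidy.
    """
    return [
        c
        for c in cnvs
        if c.carrier == "affected"
        and c.span.chrom not in exclude_chroms
        and classify_cnv(c) != "neutral"
    ]


def genes_affected(records: Iterable, genes: Iterable[GeneModel]) -> Dict[str, List[str]]:
    """Map gene name -> supporting record ids, for >=1 bp span overlap.

    Works for both SVRecord and CNVRecord (anything with .span and .record_id).
    """
    by_chrom: Dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    hits: Dict[str, List[str]] = {}
    for rec in records:
        for g in by_chrom.get(rec.span.chrom, ()):
            if rec.span.start < g.end and g.start < rec.span.end:
                hits.setdefault(g.name, []).append(rec.record_id)
    return hits


# ---------------------------------------------------------------------------
# Readers/writers
# ---------------------------------------------------------------------------


def read_sv_table(path: str) -> List[SVRecord]:
    """Read SVs from a headered TSV: chrom, start, end, sv_type, impact, carrier
    (optional leading id column)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for col in ("chrom", "start", "end", "sv_type", "impact", "carrier"):
            if col not in idx:
                raise FormatError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            p = line.split("\t")
            rid = p[idx["id"]] if "id" in idx else f"sv{lineno - 1}"
            out.append(
                SVRecord(
                    record_id=rid,
                    span=GenomicInterval(p[idx["chrom"]], int(p[idx["start"]]), int(p[idx["end"]])),
                    sv_type=p[idx["sv_type"]],
                    impact=p[idx["impact"]],
                    carrier=p[idx["carrier"]],
                )
            )
    return out


def read_cnv_table(path: str) -> List[CNVRecord]:
    """Read CNV segments from a headered TSV: chrom, start, end, copy_number,
    carrier (optional id)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for col in ("chrom", "start", "end", "copy_number", "carrier"):
            if col not in idx:
                raise FormatError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            p = line.split("\t")
            rid = p[idx["id"]] if "id" in idx else f"cnv{lineno - 1}"
            out.append(
                CNVRecord(
                    record_id=rid,
                    span=GenomicInterval(p[idx["chrom"]], int(p[idx["start"]]), int(p[idx["end"]])),
                    copy_number=int(p[idx["copy_number"]]),
                    carrier=p[idx["carrier"]],
                )
            )
    return out


def write_sv_table(svs: Iterable[SVRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tsv_type\timpact\tcarrier\n")
        for s in svs:
            fh.write(
                f"{s.record_id}\t{s.span.chrom}\t{s.span.start}\t{s.span.end}\t"
                f"{s.sv_type}\t{s.impact}\t{s.carrier}\n"
            )


def write_cnv_table(cnvs: Iterable[CNVRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tcopy_number\tcarrier\n")
        for c in cnvs:
            fh.write(
                f"{c.record_id}\t{c.span.chrom}\t{c.span.start}\t{c.span.end}\t"
                f"{c.copy_number}\t{c.carrier}\n"
            )
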