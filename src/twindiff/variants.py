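"""Co-twin genotype discordance classification and the small-variant filter funnel.

The funnel applies, in order: discordance-class selection, genotype quality and
read depth, population rarity, and predicted deleteriousness. Survivor counts
are recorded after each stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, List, Optional

from .model import ThresholdConfig, TwinVariantCall

# VEP-style consequence severity table. "Coding" here means the consequence
# alters the transcript product (HIGH/MODERATE/LOW); MODIFIER consequences are
# routed to the non-coding CADD branch.
CONSEQUENCE_IMPACT = {
    # HIGH
    "transcript_ablation": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "stop_gained": "HIGH",
    "frameshift_variant": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    # MODERATE
    "missense_variant": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "protein_altering_variant": "MODERATE",
    # LOW
    "synonymous_variant": "LOW",
    "splice_region_variant": "LOW",
    "stop_retained_variant": "LOW",
    "start_retained_variant": "LOW",
    "incomplete_terminal_codon_variant": "LOW",
    # MODIFIER
    "5_prime_UTR_variant": "MODIFIER",
    "3_prime_UTR_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
    "regulatory_region_variant": "MODIFIER",
    "non_coding_transcript_exon_variant": "MODIFIER",
    "non_coding_transcript_variant": "MODIFIER",
    "TF_binding_site_variant": "MODIFIER",
}

CODING_IMPACTS = ("HIGH", "MODERATE", "LOW")

DISCORDANCE_CLASSES = (
    "concordant",
    "unique_to_affected",
    "zygosity_difference",
    "unique_to_healthy",
)

FUNNEL_STAGES = ("discordance", "quality", "rarity", "consequence")


class UnknownConsequenceError(ValueError):
    """Consequence class not in the embedded severity table."""


def impact_of(consequence: str) -> str:
    try:
        return CONSEQUENCE_IMPACT[consequence]
    except KeyError:
        raise UnknownConsequenceError(
            f"unknown consequence class {consequence!r}; known classes: "
            f"{sorted(CONSEQUENCE_IMPACT)}"
        ) from None


def is_coding(consequence: Optional[str]) -> bool:
    if consequence is None:
        return False
    return impact_of(consequence) in CODING_IMPACTS


@dataclass
class FilterTrace:
    """Survivor counts after each funnel stage plus the final record set."""

    stage_names: tuple = FUNNEL_STAGES
    counts: List[int] = field(default_factory=list)
    survivors: List[TwinVariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts:
            if any(b > a for a, b in zip(self.counts, self.counts[1:])):
                raise ValueError("funnel counts must be non-increasing")
            if self.counts[-1] != len(self.survivors):
                raise ValueError("final count must equal number of survivors")

    def coding_survivors(self) -> List[TwinVariantCall]:
        return [c for c in self.survivors if is_coding(c.consequence)]

    def noncoding_survivors(self) -> List[TwinVariantCall]:
        return [c for c in self.survivors if not is_coding(c.consequence)]

    def to_dict(self) -> dict:
        return dict(zip(self.stage_names, self.counts))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _carries_alt(gt: str) -> bool:
    return gt in ("het", "homalt")


def classify_discordance(call: TwinVariantCall) -> str:
    """Assign one of the four co-twin discordance classes (total function).

    A variant is unique to one twin when that twin carries at least one ALT
    allele and the other is homozygous reference or uncalled; both carrying
    with different genotypes is a zygosity difference.
    """
    a, h = call.gt_affected, call.gt_healthy
    if a == h:
        return "concordant"
    if _carries_alt(a) and h in ("homref", "missing"):
        return "unique_to_affected"
    if _carries_alt(h) and a in ("homref", "missing"):
        return "unique_to_healthy"
    if _carries_alt(a) and _carries_alt(h):
        return "zygosity_difference"
    # one homref, one missing: no ALT evidence anywhere
    return "concordant"


def apply_quality_filter(
    call: TwinVariantCall, cfg: ThresholdConfig, strict: bool = False
) -> bool:
    """GQ/DP floor on the carrier (affected) twin; both twins in strict mode."""

    def ok(gq, dp):
        return gq is not None and dp is not None and gq >= cfg.min_gq and dp >= cfg.min_dp

    if not ok(call.gq_affected, call.dp_affected):
        return False
    if strict and not ok(call.gq_healthy, call.dp_healthy):
        return False
    return True


def apply_rarity_filter(call: TwinVariantCall, cfg: ThresholdConfig) -> bool:
    """Retain iff no configured population reports frequency >= max_maf.

    An unobserved frequency counts as rare (retained): absence of a population
    record is evidence of rarity, not of commonness.
    """
    return call.maf is None or call.maf < cfg.max_maf


def apply_consequence_filter(call: TwinVariantCall, cfg: ThresholdConfig) -> bool:
    """Deleteriousness filter.

    High-impact coding classes pass unconditionally; missense-type (MODERATE)
    needs at least one damaging predictor verdict; low-impact coding is
    removed; MODIFIER (non-coding) classes need CADD strictly above the cutoff.
    """
    if call.consequence is None:
        raise UnknownConsequenceError("record has no consequence class")
    impact = impact_of(call.consequence)
    if impact == "HIGH":
        return True
    if impact == "MODERATE":
        return any(v == "damaging" for _, v in call.predictor_verdicts)
    if impact == "LOW":
        return False
    # MODIFIER -> CADD branch
    return call.cadd is not None and call.cadd > cfg.min_cadd


def _absent_in_healthy(call: TwinVariantCall, cfg: ThresholdConfig, strict: bool) -> bool:
    if call.gt_healthy not in ("homref", "missing"):
        return False
    if strict:
        return call.dp_healthy is not None and call.dp_healthy >= cfg.min_dp
    return True


def run_variant_funnel(
    calls: Iterable[TwinVariantCall],
    mode: str = "unique",
    cfg: Optional[ThresholdConfig] = None,
    strict_absence: bool = False,
    strict_quality: bool = False,
) -> FilterTrace:
    """Run the staged filter cascade over one twin pair's calls.

    mode="unique" selects variants carried by the affected twin and absent in
    the healthy one; mode="zygosity" selects variants both twins carry with
    different genotypes. ``strict_absence`` additionally requires the healthy
    twin's site to be callable (DP >= min_dp) before claiming absence.
    """
    if mode not in ("unique", "zygosity"):
        raise ValueError(f"mode must be 'unique' or 'zygosity', got {mode!r}")
    cfg = cfg or ThresholdConfig()

    if mode == "unique":
        selected = [
            c
            for c in calls
            if classify_discordance(c) == "unique_to_affected"
            and _absent_in_healthy(c, cfg, strict_absence)
        ]
    else:
        selected = [c for c in calls if classify_discordance(c) == "zygosity_difference"]
    counts = [len(selected)]

    stage2 = [c for c in selected if apply_quality_filter(c, cfg, strict=strict_quality)]
    counts.append(len(stage2))

    stage3 = [c for c in stage2 if apply_rarity_filter(c, cfg)]
    counts.append(len(stage3))

    stage4 = [c for c in stage3 if apply_consequence_filter(c, cfg)]
    counts.append(len(stage4))

    return FilterTrace(stage_names=FUNNEL_STAGES, counts=counts, survivors=stage4)


def write_survivors_tsv(trace: FilterTrace, path: str) -> None:
    """Write surviving variants as a TSV, one row per call."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tvariant_class\tdiscordance\tconsequence\t"
            "coding\tmaf\tcadd\tverdicts\n"
        )
        for c in trace.survivors:
            verdicts = ";".join(f"{t}={v}" for t, v in c.predictor_verdicts) or "."
            fh.write(
                f"{c.site.chrom}\t{c.site.start}\t{c.ref}\t{c.alt}\t{c.variant_class}\t"
                f"{classify_discordance(c)}\t{c.consequence}\t"
                f"{int(is_coding(c.consequence))}\t"
                f"{'' if c.maf is None else c.maf}\t"
                f"{'' if c.cadd is None else c.cadd}\t{verdicts}\n"
            )
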