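"""Expression filtering, gene-list evidence overlay and candidate ranking.

Genes nominated by any arm (small variants, SVs, CNVs, DMC-associated) are
annotated with cardiac expression support and membership in curated disease
gene lists, then ranked. Candidate genes must be expressed (value strictly
above the threshold in at least one dataset) when the hard filter is on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .model import ThresholdConfig, logger

#: Closed vocabulary of evidence labels mirroring the curated dataset classes.
EVIDENCE_LABELS = (
    "cardiovascular_associated",
    "known_chd",
    "de_chd",
    "dm_chd",
    "cnv_chd",
    "mirna_target",
    "heart_muscle_relevant",
)

#: Nomination source labels, one per pipeline arm.
SOURCE_LABELS = (
    "variant",
    "sv",
    "cnv",
    "dmc_promoter_cgi",
    "dmc_tfbs_promoter",
)


@dataclass
class CandidateGene:
    gene: str
    sources: Set[str] = field(default_factory=set)
    expressed: bool = False
    expression_support: Tuple[str, ...] = ()
    evidence: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("a candidate must be nominated by at least one arm")


def expression_filter(
    gene: str,
    tables: Dict[str, Dict[str, float]],
    cfg: Optional[ThresholdConfig] = None,
) -> Tuple[bool, Tuple[str, ...]]:
    """(expressed?, supporting datasets). Strict: value must exceed the floor.

    Gene symbols are matched case-insensitively; a gene absent from every
    table is not expressed.
    """
    cfg = cfg or ThresholdConfig()
    key = gene.upper()
    support = tuple(
        sorted(d for d, vals in tables.items() if vals.get(key, 0.0) > cfg.min_expression)
    )
    return bool(support), support


def normalize_gene_lists(lists: Dict[str, Iterable[str]]) -> Dict[str, Set[str]]:
    """Case-normalize list membership, deduplicating with a warning."""
    out: Dict[str, Set[str]] = {}
    for label, symbols in lists.items():
        if label not in EVIDENCE_LABELS:
            raise ValueError(
                f"unknown evidence label {label!r}; known: {EVIDENCE_LABELS}"
            )
        seen: Set[str] = set()
        for s in symbols:
            key = s.upper()
            if key in seen:
                logger.warning("duplicate symbol %r in list %s (deduplicated)", s, label)
            seen.add(key)
        out[label] = seen
    return out


def gene_list_evidence(gene: str, lists: Dict[str, Set[str]]) -> Set[str]:
    """Evidence labels of every normalized list containing the gene."""
    key = gene.upper()
    return {label for label, members in lists.items() if key in members}


def assemble_candidates(
    nominations: Dict[str, Set[str]],
    tables: Dict[str, Dict[str, float]],
    lists: Dict[str, Set[str]],
    cfg: Optional[ThresholdConfig] = None,
    require_expression: bool = True,
) -> List[CandidateGene]:
    """Build the ranked candidate report.

    ``nominations`` maps gene name -> set of arm source labels. With
    ``require_expression`` the expression filter is a hard requirement;
    otherwise expression is annotated only. Ranking: number of nominating
    arms, then evidence count, both descending; gene name breaks ties.
    """
    cfg = cfg or ThresholdConfig()
    out: List[CandidateGene] = []
    for gene, sources in nominations.items():
        expressed, support = expression_filter(gene, tables, cfg)
        if require_expression and not expressed:
            continue
        out.append(
            CandidateGene(
                gene=gene,
                sources=set(sources),
                expressed=expressed,
                expression_support=support,
                evidence=gene_list_evidence(gene, lists),
            )
        )
    out.sort(key=lambda c: (-len(c.sources), -len(c.evidence), c.gene))
    return out


def funnel_percentage(survivors: int, total: int) -> Optional[float]:
    """Percentage of the input surviving the funnel, rounded half-up to 2 dp.

    Returns None (undefined) when the input total is zero.
    """
    if total == 0:
        return None
    pct = Decimal(100 * survivors) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_funnel_percentage(survivors: int, total: int) -> str:
    pct = funnel_percentage(survivors, total)
    return "NA" if pct is None else f"{pct:.2f}%"


def write_candidate_report(
    candidates: List[CandidateGene], tsv_path: str, json_path: Optional[str] = None
) -> None:
    """Deterministic TSV (+ optional JSON) candidate report."""
    with open(tsv_path, "w") as fh:
        fh.write("gene\tn_sources\tsources\texpressed\texpression_support\tevidence\n")
        for c in candidates:
            fh.write(
                f"{c.gene}\t{len(c.sources)}\t{','.join(sorted(c.sources))}\t"
                f"{int(c.expressed)}\t{','.join(c.expression_support) or '.'}\t"
                f"{','.join(sorted(c.evidence)) or '.'}\n"
            )
    if json_path:
        payload = [
            {
                "gene": c.gene,
                "sources": sorted(c.sources),
                "expressed": c.expressed,
                "expression_support": list(c.expression_support),
                "evidence": sorted(c.evidence),
            }
            for c in candidates
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
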