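"""Per-CpG methylation levels, spike-in conversion QC and differential calling.

A differentially methylated CpG (DMC) is a position covered in both co-twins
within the coverage window whose methylation levels differ by at least the
configured number of percentage points. This is a fixed-difference criterion,
not a statistical test; an optional per-site Fisher exact p-value on the 2x2
count table can be attached as extra output but never filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
from scipy import stats

from .model import ConversionQC, CpGSiteCounts, DMCRecord, ThresholdConfig


def methylation_level(counts: CpGSiteCounts) -> float:
    """Percent methylation, 100 * meth / coverage. Errors on zero coverage."""
    cov = counts.coverage
    if cov == 0:
        raise ValueError(
            f"methylation level undefined at {counts.chrom}:{counts.pos} "
            "(zero coverage; filter first)"
        )
    return 100.0 * counts.meth / cov


def bisulfite_conversion_rate(lambda_counts: Iterable[CpGSiteCounts]) -> ConversionQC:
    """Estimate conversion from the unmethylated phage spike-in.

    Aggregates CpG-context counts over the control genome; the rate is
    100 minus the apparent percent methylation. Zero total coverage yields an
    unavailable QC record rather than an error.
    """
    meth = unmeth = 0
    for c in lambda_counts:
        meth += c.meth
        unmeth += c.unmeth
    total = meth + unmeth
    if total == 0:
        return ConversionQC(lambda_meth=0, lambda_unmeth=0, conversion_rate=None)
    rate = 100.0 - 100.0 * meth / total
    return ConversionQC(lambda_meth=meth, lambda_unmeth=unmeth, conversion_rate=rate)


def _collect_sorted(stream: Iterable[CpGSiteCounts], who: str) -> Dict[str, Dict[int, CpGSiteCounts]]:
    """Group counts per chromosome, enforcing sorted positions within chroms
    and no revisiting of a finished chromosome."""
    out: Dict[str, Dict[int, CpGSiteCounts]] = {}
    last_chrom = None
    last_pos = -1
    for c in stream:
        if c.chrom != last_chrom:
            if c.chrom in out:
                raise ValueError(
                    f"{who}: input not sorted (chromosome {c.chrom} revisited)"
                )
            out[c.chrom] = {}
            last_chrom, last_pos = c.chrom, -1
        if c.pos <= last_pos:
            raise ValueError(
                f"{who}: input not sorted at {c.chrom}:{c.pos} (previous {last_pos})"
            )
        last_pos = c.pos
        out[c.chrom][c.pos] = c
    return out


def call_dmcs(
    affected: Iterable[CpGSiteCounts],
    healthy: Iterable[CpGSiteCounts],
    cfg: Optional[ThresholdConfig] = None,
    fisher: bool = False,
) -> List[DMCRecord]:
    """Call DMCs between the affected and healthy twin.

    Only positions present in both samples with coverage inside
    [meth_min_cov, meth_max_cov] in *both* are tested. The difference
    threshold is inclusive; direction is hyper iff the affected twin is more
    methylated. Inputs must be position-sorted within chromosomes.
    """
    cfg = cfg or ThresholdConfig()
    aff = _collect_sorted(affected, "affected")
    hea = _collect_sorted(healthy, "healthy")

    out: List[DMCRecord] = []
    for chrom, sites_a in aff.items():
        sites_h = hea.get(chrom)
        if not sites_h:
            continue
        for pos, ca in sites_a.items():
            ch = sites_h.get(pos)
            if ch is None:
                continue
            if not (cfg.meth_min_cov <= ca.coverage <= cfg.meth_max_cov):
                continue
            if not (cfg.meth_min_cov <= ch.coverage <= cfg.meth_max_cov):
                continue
            la = methylation_level(ca)
            lh = methylation_level(ch)
            diff = la - lh
            if abs(diff) < cfg.dmc_min_diff:
                continue
            pval = None
            if fisher:
                _, pval = stats.fisher_exact(
                    [[ca.meth, ca.unmeth], [ch.meth, ch.unmeth]]
                )
            out.append(
                DMCRecord(
                    chrom=chrom,
                    pos=pos,
                    level_affected=la,
                    level_healthy=lh,
                    diff=diff,
                    direction="hyper" if diff > 0 else "hypo",
                    cov_affected=ca.coverage,
                    cov_healthy=ch.coverage,
                    fisher_p=pval,
                )
            )
    return out


@dataclass
class MethylationSummary:
    """Genome-wide summary over one sample's covered CpGs."""

    n_sites: int = 0
    n_covered: int = 0
    mean_level: Optional[float] = None  # percent; None when no covered site
    coverage_histogram: Dict[str, int] = field(default_factory=dict)


_HIST_EDGES = (0, 1, 5, 10, 30, 50, 100, 500)


def global_methylation_summary(sample: Iterable[CpGSiteCounts]) -> MethylationSummary:
    """Mean CpG methylation over covered sites plus a coverage histogram."""
    n = n_cov = 0
    level_sum = 0.0
    hist = {f"[{a},{b})": 0 for a, b in zip(_HIST_EDGES, _HIST_EDGES[1:])}
    hist[f">={_HIST_EDGES[-1]}"] = 0
    for c in sample:
        n += 1
        cov = c.coverage
        for a, b in zip(_HIST_EDGES, _HIST_EDGES[1:]):
            if a <= cov < b:
                hist[f"[{a},{b})"] += 1
                break
        else:
            hist[f">={_HIST_EDGES[-1]}"] += 1
        if cov > 0:
            n_cov += 1
            level_sum += methylation_level(c)
    return MethylationSummary(
        n_sites=n,
        n_covered=n_cov,
        mean_level=(level_sum / n_cov) if n_cov else None,
        coverage_histogram=hist,
    )


def merge_symmetric_cpgs(sites: Iterable[CpGSiteCounts]) -> Iterator[CpGSiteCounts]:
    """Optionally merge +/- strand counts of a symmetric CpG (offset-1 pair).

    Off by default in the pipeline; sites are otherwise kept per strand as
    reported. Consecutive positions p (+) and p+1 (-) on the same chromosome
    are summed onto the + position.
    """
    prev: Optional[CpGSiteCounts] = None
    for c in sites:
        if (
            prev is not None
            and c.chrom == prev.chrom
            and c.pos == prev.pos + 1
            and prev.strand in ("+", ".")
            and c.strand == "-"
        ):
            yield CpGSiteCounts(
                chrom=prev.chrom,
                pos=prev.pos,
                meth=prev.meth + c.meth,
                unmeth=prev.unmeth + c.unmeth,
                strand="+",
            )
            prev = None
            continue
        if prev is not None:
            yield prev
        prev = c
    if prev is not None:
        yield prev


def expected_null_dmc_rate(
    levels: np.ndarray,
    coverage: int,
    min_diff: float = 25.0,
    n_sim: int = 200,
    seed: int = 0,
) -> Tuple[float, float]:
    """Monte-Carlo oracle: expected fraction of null sites called as DMCs.

    For each site with true methylation fraction ``levels[i]`` (in [0,1]) and
    fixed coverage, draws ``n_sim`` independent pairs of binomial counts and
    measures how often the absolute level difference reaches ``min_diff``
    percentage points. Returns (mean rate, standard error of the mean rate).
    Independent of the DMC caller; used to bound its false-call rate.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(levels, dtype=float)
    x1 = rng.binomial(coverage, p[:, None], size=(p.size, n_sim))
    x2 = rng.binomial(coverage, p[:, None], size=(p.size, n_sim))
    diffs = np.abs(x1 - x2) * (100.0 / coverage)
    exceed = diffs >= min_diff
    per_site = exceed.mean(axis=1)
    mean_rate = float(per_site.mean())
    # SE of the overall rate across n_sites * n_sim Bernoulli draws
    se = float(np.sqrt(max(mean_rate * (1 - mean_rate), 1e-12) / exceed.size))
    return mean_rate, se


def write_dmc_tsv(dmcs: Iterable[DMCRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tlevel_affected\tlevel_healthy\tdiff\tdirection\t"
            "cov_affected\tcov_healthy\tfisher_p\n"
        )
        for d in dmcs:
            fp = "" if d.fisher_p is None else f"{d.fisher_p:.4g}"
            fh.write(
                f"{d.chrom}\t{d.pos}\t{d.level_affected:.4f}\t{d.level_healthy:.4f}\t"
                f"{d.diff:+.4f}\t{d.direction}\t{d.cov_affected}\t{d.cov_healthy}\t{fp}\n"
            )
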