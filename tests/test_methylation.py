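"""Methylation levels, conversion QC, DMC calling and its statistical behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twindiff.methylation import (
    bisulfite_conversion_rate,
    call_dmcs,
    expected_null_dmc_rate,
    global_methylation_summary,
    merge_symmetric_cpgs,
    methylation_level,
)
from twindiff.model import CpGSiteCounts, ThresholdConfig

CFG = ThresholdConfig()


def site(pos, meth, unmeth, chrom="chr1"):
    return CpGSiteCounts(chrom=chrom, pos=pos, meth=meth, unmeth=unmeth)


class TestLevel:
    @pytest.mark.parametrize("meth,unmeth,expected", [(8, 2, 80.0), (0, 10, 0.0), (10, 0, 100.0)])
    def test_fraction_of_reads(self, meth, unmeth, expected):
        assert methylation_level(site(0, meth, unmeth)) == pytest.approx(expected)

    def test_zero_coverage_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            methylation_level(site(0, 0, 0))


class TestConversionQC:
    def test_rate_is_complement_of_apparent_methylation(self):
        qc = bisulfite_conversion_rate([site(0, 3, 997)])
        assert qc.conversion_rate == pytest.approx(99.7)

    @pytest.mark.parametrize("meth,unmeth,rate", [(0, 100, 100.0), (100, 0, 0.0)])
    def test_extremes(self, meth, unmeth, rate):
        assert bisulfite_conversion_rate([site(0, meth, unmeth)]).conversion_rate == rate

    def test_zero_coverage_unavailable_not_fatal(self):
        qc = bisulfite_conversion_rate([])
        assert not qc.available and qc.conversion_rate is None


class TestCallDmcs:
    def test_inclusive_difference_threshold(self):
        # cov 50 each: 80% vs 54% -> +26 hyper; 80% vs 56% -> 24 no call
        aff = [site(10, 40, 10), site(20, 40, 10)]
        heal = [site(10, 27, 23), site(20, 28, 22)]
        dmcs = call_dmcs(aff, heal, CFG)
        assert [(d.pos, d.direction) for d in dmcs] == [(10, "hyper")]
        assert dmcs[0].diff == pytest.approx(26.0)

    def test_exact_25_called_just_below_not(self):
        # cov 20: 16/20 = 80.0 vs 11/20 = 55.0 -> diff 25.0 (called)
        assert len(call_dmcs([site(1, 16, 4)], [site(1, 11, 9)], CFG)) == 1
        # cov 490: 392/490 = 80.0 vs 270/490 = 55.102 -> diff 24.9 (not called)
        assert call_dmcs([site(1, 392, 98)], [site(1, 270, 220)], CFG) == []

    @pytest.mark.parametrize("cov_h", [9, 501])
    def test_coverage_window_excludes_either_sample(self, cov_h):
        aff = [site(1, 45, 5)]
        heal = [site(1, 0, cov_h)]
        assert call_dmcs(aff, heal, CFG) == []

    @pytest.mark.parametrize("cov", [10, 500])
    def test_coverage_window_is_inclusive(self, cov):
        aff = [site(1, cov, 0)]
        heal = [site(1, 0, cov)]
        assert len(call_dmcs(aff, heal, CFG)) == 1

    def test_position_must_be_present_in_both(self):
        assert call_dmcs([site(1, 45, 5)], [site(2, 0, 50)], CFG) == []

    def test_unsorted_input_fatal(self):
        with pytest.raises(ValueError, match="not sorted"):
            call_dmcs([site(5, 45, 5), site(1, 45, 5)], [site(1, 0, 50)], CFG)
        with pytest.raises(ValueError, match="revisited"):
            call_dmcs(
                [site(1, 45, 5), site(1, 45, 5, chrom="chr2"), site(2, 45, 5)],
                [site(1, 0, 50)],
                CFG,
            )

    def test_fisher_p_is_extra_output_not_a_filter(self):
        aff, heal = [site(1, 45, 5)], [site(1, 10, 40)]
        plain = call_dmcs(aff, heal, CFG)
        with_p = call_dmcs(aff, heal, CFG, fisher=True)
        assert plain[0].fisher_p is None
        assert 0.0 <= with_p[0].fisher_p <= 1.0
        assert [(d.chrom, d.pos) for d in plain] == [(d.chrom, d.pos) for d in with_p]


@st.composite
def paired_streams(draw):
    n = draw(st.integers(1, 25))
    positions = sorted(draw(st.sets(st.integers(0, 10_000), min_size=n, max_size=n)))
    sites_a, sites_h = [], []
    for p in positions:
        ca = draw(st.integers(0, 60))
        ch = draw(st.integers(0, 60))
        ma = draw(st.integers(0, ca))
        mh = draw(st.integers(0, ch))
        sites_a.append(site(p, ma, ca - ma))
        sites_h.append(site(p, mh, ch - mh))
    return sites_a, sites_h


class TestProperties:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(paired_streams())
    def test_sample_swap_antisymmetry(self, streams):
        """Swapping samples negates diffs, flips directions, keeps positions."""
        a, h = streams
        fwd = call_dmcs(a, h, CFG)
        rev = call_dmcs(h, a, CFG)
        assert [(d.chrom, d.pos) for d in fwd] == [(d.chrom, d.pos) for d in rev]
        for f, r in zip(fwd, rev):
            assert f.diff == pytest.approx(-r.diff)
            assert {f.direction, r.direction} == {"hyper", "hypo"}

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(paired_streams())
    def test_emitted_coverage_within_window_and_direction_partition(self, streams):
        a, h = streams
        dmcs = call_dmcs(a, h, CFG)
        for d in dmcs:
            assert CFG.meth_min_cov <= d.cov_affected <= CFG.meth_max_cov
            assert CFG.meth_min_cov <= d.cov_healthy <= CFG.meth_max_cov
            assert abs(d.diff) >= CFG.dmc_min_diff
        n_hyper = sum(1 for d in dmcs if d.direction == "hyper")
        n_hypo = sum(1 for d in dmcs if d.direction == "hypo")
        assert n_hyper + n_hypo == len(dmcs)


class TestSummary:
    def test_mean_over_covered_sites(self):
        s = global_methylation_summary([site(1, 10, 0), site(2, 0, 10), site(3, 0, 0)])
        assert s.mean_level == pytest.approx(50.0)
        assert s.n_sites == 3 and s.n_covered == 2

    def test_empty_stream(self):
        s = global_methylation_summary([])
        assert s.n_sites == 0 and s.mean_level is None

    def test_simulator_default_mean_near_82_5(self, noiseless_dataset):
        """Baseline prior is centred so genome-wide mean CpG methylation ~82.5%."""
        import os
        from twindiff.model import read_methylation_counts

        dataset, _ = noiseless_dataset
        s = global_methylation_summary(
            read_methylation_counts(os.path.join(dataset, "methylation.healthy.cov"))
        )
        assert s.mean_level == pytest.approx(82.5, abs=2.0)


def test_symmetric_cpg_merge_sums_offset_pair():
    sites = [
        CpGSiteCounts("chr1", 10, 3, 7, strand="+"),
        CpGSiteCounts("chr1", 11, 2, 8, strand="-"),
        CpGSiteCounts("chr1", 50, 1, 1, strand="+"),
    ]
    merged = list(merge_symmetric_cpgs(sites))
    assert merged[0] == CpGSiteCounts("chr1", 10, 5, 15, strand="+")
    assert merged[1].pos == 50


def test_null_false_call_rate_below_monte_carlo_tail_bound():
    """Under the null (identical per-site levels, coverage 30), the empirical
    DMC rate stays below the independently simulated two-binomial tail rate."""
    from twindiff.simulate import (
        SimulationConfig,
        simulate_feature_tracks,
        simulate_methylomes,
    )

    rng = np.random.default_rng(42)
    cfg = SimulationConfig(seed=42, n_cpgs=10_000, planted_dmcs=[], cov_mean=30.0)
    genes, tracks = simulate_feature_tracks(cfg, rng)
    aff, heal, _lam, planted, _derived = simulate_methylomes(cfg, genes, tracks, rng)
    assert planted == []
    dmcs = call_dmcs(aff, heal, CFG)
    emp_rate = len(dmcs) / cfg.n_cpgs

    levels = np.array([s.meth / s.coverage for s in heal if s.coverage > 0])
    mc_rate, mc_se = expected_null_dmc_rate(levels, 30, CFG.dmc_min_diff, n_sim=100, seed=7)
    bound = mc_rate + 4 * np.sqrt(mc_rate * (1 - mc_rate) / cfg.n_cpgs + mc_se**2)
    assert emp_rate <= bound
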