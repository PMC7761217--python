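import pytest

from twindiff.model import GenomicInterval, TwinVariantCall
from twindiff.pipeline import RunConfig, run_pipeline
from twindiff.simulate import SimulationConfig, emit_dataset


@pytest.fixture(scope="session")
def noiseless_dataset(tmp_path_factory):
    """Full-scale noiseless twin dataset plus its truth manifest."""
    outdir = tmp_path_factory.mktemp("dataset")
    cfg = SimulationConfig(seed=11, noiseless=True)
    manifest = emit_dataset(cfg, str(outdir), force=True)
    return str(outdir), manifest


@pytest.fixture(scope="session")
def noiseless_run(noiseless_dataset, tmp_path_factory):
    """Pipeline report for the noiseless dataset."""
    dataset, manifest = noiseless_dataset
    outdir = tmp_path_factory.mktemp("run")
    report = run_pipeline(RunConfig.from_dataset_dir(dataset, str(outdir)))
    return report, manifest, str(outdir)


def make_call(
    gt_affected="het",
    gt_healthy="homref",
    gq=50,
    dp=30,
    gq_h=50,
    dp_h=30,
    consequence="missense_variant",
    maf=None,
    verdicts=(),
    cadd=None,
    pos=100,
    chrom="chr1",
):
    """Terse TwinVariantCall builder for unit tests."""
    return TwinVariantCall(
        site=GenomicInterval(chrom, pos, pos + 1),
        ref="A",
        alt="T",
        variant_class="snv",
        gt_affected=gt_affected,
        gt_healthy=gt_healthy,
        dp_affected=dp,
        dp_healthy=dp_h,
        gq_affected=gq,
        gq_healthy=gq_h,
        consequence=consequence,
        maf=maf,
        predictor_verdicts=tuple(verdicts),
        cadd=cadd,
    )
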