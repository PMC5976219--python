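import dataclasses

import numpy as np
import pytest

from mrkit.estimators import RatioEstimate
from mrkit.harmonize import HarmonizedPair
from mrkit.simulate import Scenario
from mrkit.studygen import generate_study_files
from mrkit.summary_io import SummaryRecord


def make_record(
    vid="rs1",
    chrom="1",
    pos=1000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    p=1e-8,
    n=50000,
):
    return SummaryRecord(
        variant_id=vid,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=p,
        n=n,
    )


def make_pair(vid="rs1", bx=0.1, sx=0.01, by=0.05, sy=0.02):
    return HarmonizedPair(
        variant_id=vid,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
    )


def make_ratios(theta, s):
    return [
        RatioEstimate(variant_id=f"rs{i + 1}", theta=float(t), s=float(si))
        for i, (t, si) in enumerate(zip(theta, s))
    ]


def random_ratios(rng, j=None):
    j = j or int(rng.integers(3, 12))
    theta = rng.normal(0.2, 0.5, j)
    s = rng.uniform(0.05, 0.4, j)
    return make_ratios(theta, s)


#: small, fast scenario for pipeline-level tests
TINY_SCENARIO = Scenario(
    n_variants=24,
    n_exposure_sample=3000,
    n_outcome_sample=3000,
    n_cohort=500,
    ld_blocks=((3, 0.8), (2, 0.5)),
    binary_exposure=True,
    seed=42,
)


@pytest.fixture(scope="session")
def tiny_study_dir(tmp_path_factory):
    """A complete synthetic study on disk (small sizes, all seven outcomes)."""
    out = tmp_path_factory.mktemp("study")
    config = generate_study_files(out, seed=42, scenario=TINY_SCENARIO)
    return out, config


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
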