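import numpy as np
import pytest

from splicevis.fixtures import FixtureConfig, simulate


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """40-sample cohort for fast I/O and CLI tests."""
    outdir = tmp_path_factory.mktemp("cohort_small")
    cfg = FixtureConfig(seed=7, n_samples=40)
    manifest = simulate(cfg, outdir)
    return cfg, manifest


@pytest.fixture(scope="session")
def study_cohort(tmp_path_factory):
    """Full study-condition cohort: 200 samples, cassette inclusion 0.9 vs 0.1."""
    outdir = tmp_path_factory.mktemp("cohort_study")
    cfg = FixtureConfig(seed=20)
    manifest = simulate(cfg, outdir)
    return cfg, manifest


@pytest.fixture(scope="session")
def multigene_cohort(tmp_path_factory):
    """3 genes x 2 transcripts, for gene-model and resolution tests."""
    outdir = tmp_path_factory.mktemp("cohort_multigene")
    cfg = FixtureConfig(seed=11, n_genes=3, n_samples=24)
    manifest = simulate(cfg, outdir)
    return cfg, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
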