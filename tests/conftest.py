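import pytest

from cazpipe.catalog import load_catalog
from cazpipe.config import PipelineConfig
from cazpipe.pipeline import run_pipeline
from cazpipe.synthetic import CommunityPlan, generate_community


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture()
def config():
    return PipelineConfig()


SMALL_SPLIT = {"Bacteroidia": 6, "Clostridia": 4, "Bacilli": 2, "Desulfobacteria": 1}


@pytest.fixture(scope="session")
def small_plan():
    return CommunityPlan(
        rng_seed=5, genes_per_mag=200, n_mags_per_class=dict(SMALL_SPLIT)
    )


@pytest.fixture(scope="session")
def small_bundle_dir(small_plan, tmp_path_factory):
    """A small noise-free community written to disk, with its ground truth."""
    out = tmp_path_factory.mktemp("bundle")
    bundle, truth = generate_community(small_plan, out_dir=out)
    return out, bundle, truth


@pytest.fixture(scope="session")
def default_community(tmp_path_factory):
    """The default 68-MAG noise-free community plus full pipeline results."""
    plan = CommunityPlan(rng_seed=1)
    out = tmp_path_factory.mktemp("default_bundle")
    bundle, truth = generate_community(plan, out_dir=out)
    results = run_pipeline(PipelineConfig(), out, tmp_path_factory.mktemp("default_out"))
    return plan, bundle, truth, results
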