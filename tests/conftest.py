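import pytest

from splithom import PipelineInputs, run_pipeline
from splithom.fixtures import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic input bundle (seed 42, full decoy panel)."""
    outdir = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureConfig(seed=42), outdir)


@pytest.fixture(scope="session")
def inputs(bundle):
    return PipelineInputs.load(
        bundle.alignments, bundle.cluster_map, bundle.gff3, taxonomy=bundle.taxonomy
    )


@pytest.fixture(scope="session")
def run(inputs):
    """One default-parameter pipeline execution on the session bundle."""
    return run_pipeline(inputs)
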