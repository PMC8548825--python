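import pytest

from gwas2drug import synthetic
from gwas2drug.pipeline import PipelinePaths, run_all
from gwas2drug.types import PipelineConfig


@pytest.fixture(scope="session")
def mini_bundle():
    return synthetic.mini_study()


@pytest.fixture(scope="session")
def stoch_bundle():
    return synthetic.generate(synthetic.GeneratorParams(rng_seed=42))


@pytest.fixture(scope="session")
def mini_fixture_dir(mini_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("mini_fixtures")
    mini_bundle.write(d)
    return d


@pytest.fixture(scope="session")
def mini_run(mini_bundle, mini_fixture_dir, tmp_path_factory):
    """Full pipeline run on the mini-study preset: (manifest, out_dir)."""
    out = tmp_path_factory.mktemp("mini_out")
    manifest = run_all(
        PipelinePaths.from_dir(mini_fixture_dir),
        PipelineConfig(disease="mini dermatitis"),
        out,
    )
    return manifest, out
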