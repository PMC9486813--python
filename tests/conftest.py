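import pytest

from nshlscreen.pipeline import RunConfig, run_screen
from nshlscreen.simulate import generate_cohort, paper_fixture, small_config


@pytest.fixture(scope="session")
def paper_run(tmp_path_factory):
    """The frozen study-scale fixture, generated and screened once per session."""
    base = tmp_path_factory.mktemp("paper")
    bundle = base / "bundle"
    generate_cohort(paper_fixture(seed=7), bundle)
    config = RunConfig.from_yaml(bundle / "run_config.yaml", base / "run")
    result = run_screen(config)
    return bundle, result


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A compact cohort bundle plus its screen result."""
    base = tmp_path_factory.mktemp("small")
    bundle = base / "bundle"
    generate_cohort(small_config(seed=11), bundle)
    config = RunConfig.from_yaml(bundle / "run_config.yaml", base / "run")
    result = run_screen(config)
    return bundle, result
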