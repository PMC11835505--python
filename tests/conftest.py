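import logging

import pytest
from hypothesis import settings

from esccmrd.fixture import paper_fixture
from esccmrd.pipeline import PipelineConfig, run_pipeline

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

logging.getLogger("esccmrd").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fixture_bundle():
    """The packaged deterministic 35-patient reference cohort (in memory)."""
    return paper_fixture()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_bundle):
    """Reference cohort written to disk (VCFs, evidence TSV, clinical CSV)."""
    d = tmp_path_factory.mktemp("fixture_cohort")
    fixture_bundle.write(d)
    return d


@pytest.fixture(scope="session")
def fixture_report(tmp_path_factory):
    """Full pipeline report bundle for the reference cohort."""
    out = tmp_path_factory.mktemp("fixture_run")
    report = run_pipeline(PipelineConfig(fixture=True), out)
    return report, out
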