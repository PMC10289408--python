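import pytest

from cdsseval import AssessmentOptions, GeneratorConfig, assemble_study, run_assessment


@pytest.fixture(scope="session")
def study_bundle():
    """A full-size synthetic study under the default conditions (fixed seed)."""
    return assemble_study(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def study_report(study_bundle):
    """The complete assessment of the default synthetic study."""
    return run_assessment(study_bundle, AssessmentOptions(seed=1))


@pytest.fixture()
def small_bundle():
    """A cheap 2-group x 4-case bundle for IO and shape tests."""
    return assemble_study(GeneratorConfig(seed=7, n_groups=2, cases_per_group=4))
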