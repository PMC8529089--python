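import pytest

from fechsurvey.pipeline import PipelineConfig, run_pipeline
from fechsurvey.synthetic_data import (
    GeneratorConfig,
    generate_dataset,
    make_synthetic_reference,
)


@pytest.fixture(scope="session")
def reference():
    return make_synthetic_reference()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-record labeled cohort shared across tests (seed-fixed)."""
    return generate_dataset(GeneratorConfig(n_records=60, seed=3))


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    dataset, truth, ref = small_cohort
    bundle = run_pipeline(dataset, ref, PipelineConfig(do_tree=False))
    return bundle, truth
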