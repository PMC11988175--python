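import warnings

import pytest

from tepscore import SyntheticCohortConfig, run_pipeline, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic study cohort, fixed seed."""
    return simulate_dataset(SyntheticCohortConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    """Full pipeline run on the session cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occasional reference-Cq window notice
        return run_pipeline(dataset.counts.log2cpm(), dataset.meta, dataset.cq)
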