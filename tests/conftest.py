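import numpy as np
import pytest

from heartwoodkit import anatomy, datagen, pipeline

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study():
    """One default two-cohort dataset shared across tests (fixed seed)."""
    dataset, truth = datagen.generate_study(seed=STUDY_SEED)
    return dataset, truth


@pytest.fixture(scope="session")
def derived(study):
    dataset, _ = study
    return anatomy.derive_discs(
        dataset["discs"], dataset["vessels"], dataset["leaves"]
    )


@pytest.fixture(scope="session")
def bundle():
    """A full default pipeline run (fixed seed)."""
    return pipeline.run_pipeline(pipeline.RunConfig(seed=STUDY_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
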