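import numpy as np
import pytest

from heifersim.cleaning import clean_pipeline
from heifersim.model import model_frame
from heifersim.synthetic import HERD_YEARS, SyntheticConfig, generate_dataset


def small_config(seed=0, **overrides):
    """A reduced-size herd structure for fast end-to-end tests."""
    herd_years = {h: ys[:3] for h, ys in HERD_YEARS.items()}
    defaults = dict(herd_years=herd_years, seed=seed)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def study_config():
    """Full study-sized synthetic configuration (12 herds, all seasons)."""
    return SyntheticConfig(seed=20)


@pytest.fixture(scope="session")
def study_dataset(study_config):
    """Defect-free study-sized dataset: (services, calvings)."""
    services, calvings, _ = generate_dataset(study_config, with_defects=False)
    return services, calvings


@pytest.fixture(scope="session")
def defected_dataset(study_config):
    """Same dataset with planted defects and its ledger."""
    return generate_dataset(study_config, with_defects=True)


@pytest.fixture(scope="session")
def cleaned_frame(study_dataset):
    """Cleaned, complete-case modelling frame of the study-sized dataset."""
    services, calvings = study_dataset
    cleaned, _ = clean_pipeline(services, calvings)
    return model_frame(cleaned)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
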