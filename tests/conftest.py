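import numpy as np
import pytest

from renalnet.model_assembly import solve_reference_config
import renalnet.synthetic_data as sd


@pytest.fixture(scope="session")
def solved_cfg():
    return solve_reference_config()


@pytest.fixture(scope="session")
def appearance():
    return sd.ClassAppearanceModel()


@pytest.fixture(scope="session")
def small_records():
    """80 patches: 20 per class over 5 cases per class."""
    return sd.generate_dataset(n_per_class=20, cases_per_class=5, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
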