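import numpy as np
import pytest

from hdsemg_seating.core import ElectrodeGridSpec, TrialKey


@pytest.fixture(scope="session")
def grid() -> ElectrodeGridSpec:
    """The study grid: 16 x 8 electrodes, 10 mm pitch, 2048 Hz."""
    return ElectrodeGridSpec()


@pytest.fixture(scope="session")
def small_grid() -> ElectrodeGridSpec:
    """A reduced grid for fast signal-level tests."""
    return ElectrodeGridSpec(n_rows=8, n_cols=4)


@pytest.fixture()
def key() -> TrialKey:
    return TrialKey(subject_id=1, chair="SS", side="L", trial_index=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
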