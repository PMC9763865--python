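import numpy as np
import pytest

from lckcycle import kinase, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_kinase_params():
    return kinase.ModelParams(p_pa=0.3, p_aa=0.1, arena_size=100,
                              n_replicates=200, seed=7)


@pytest.fixture(scope="session")
def small_fcm_spec():
    """Cheap three-population FCM spec used by several test modules."""
    return synth.FCMGenSpec(
        n_cells_per_population=2000,
        barcode_levels=(100.0, 1000.0, 10000.0),
        noise_cv=0.2,
        background_T=20.0,
        background_A=5.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_fcm_data(small_fcm_spec):
    return synth.gen_fcm_events(small_fcm_spec)
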