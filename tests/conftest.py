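import numpy as np
import pytest

from stpe.phantom_forward import MaterialParams, PhantomSpec, generate_strain_series
from stpe.rf_simulation import TransducerSpec, make_scatterer_field, synthesize_rf


@pytest.fixture(scope="session")
def transducer():
    return TransducerSpec()


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Compact sphere phantom: 2x stiffness contrast, 10 s time
    constants, coarse grid to keep the suite fast."""
    from stpe.evaluation import lp_for_tau

    return PhantomSpec(
        inclusion=MaterialParams(E=20e3, nu=0.40, Lp=lp_for_tau(20e3, 0.40, 10.0), k=1e-13),
        background=MaterialParams(E=10e3, nu=0.30, Lp=lp_for_tau(10e3, 0.30, 10.0), k=1e-13),
        duration_s=60.0,
        dt_s=0.1,
        grid_pixels_per_mm=2.0,
    )


@pytest.fixture(scope="session")
def small_series(small_phantom_spec):
    return generate_strain_series(small_phantom_spec)


@pytest.fixture(scope="session")
def speckle_field(transducer):
    return make_scatterer_field((20.0, 20.0), 10, seed=1, spec=transducer)


@pytest.fixture(scope="session")
def speckle_frame(speckle_field, transducer):
    return synthesize_rf(speckle_field, transducer, snr_db=np.inf)
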