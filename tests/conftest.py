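import numpy as np
import pytest

from porescope import PhantomParams, build_phantom

# Compact geometry (wild-type proportions scaled by 0.6) so alignment and
# averaging tests run on small grids.
MINI = dict(membrane_pore_diameter=63.0, channel_diameter=34.2,
            ir_outer_diameter=63.0, cr_distal_offset=22.2,
            nr_distal_offset=17.4, angle_cyto=42.0, angle_nucleo=28.0)


@pytest.fixture(scope="session")
def wt_params():
    return PhantomParams()


@pytest.fixture(scope="session")
def wt_phantom(wt_params):
    """Wild-type phantom at the 4x-binned sampling used for measurements."""
    return build_phantom(wt_params, (128, 128, 128), 13.6)


@pytest.fixture(scope="session")
def mini_params():
    return PhantomParams(**MINI)


@pytest.fixture(scope="session")
def mini_phantom(mini_params):
    return build_phantom(mini_params, (48, 48, 48), 20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
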