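import numpy as np
import pytest

from cardioafm import Cantilever
from cardioafm.elasticity import PYRAMID_EFFECTIVE_HALF_ANGLE


@pytest.fixture
def sphere_cantilever():
    return Cantilever(spring_constant=0.2, tip_geometry="sphere", tip_radius=1e-6)


@pytest.fixture
def cone_cantilever():
    return Cantilever(spring_constant=0.2, tip_geometry="cone",
                      half_angle=np.deg2rad(20.0))


@pytest.fixture
def pyramid_cantilever():
    return Cantilever(spring_constant=0.2, tip_geometry="pyramid",
                      half_angle=PYRAMID_EFFECTIVE_HALF_ANGLE)


@pytest.fixture(params=["sphere", "cone", "pyramid"])
def any_cantilever(request, sphere_cantilever, cone_cantilever, pyramid_cantilever):
    return {"sphere": sphere_cantilever, "cone": cone_cantilever,
            "pyramid": pyramid_cantilever}[request.param]
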