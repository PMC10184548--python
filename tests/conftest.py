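import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cube(side=10.0, origin=(0.0, 0.0, 0.0)):
    """Axis-aligned cube as 12 outward-oriented triangles."""
    from paleoneuro import TriangleMesh

    o = np.asarray(origin, dtype=float)
    s = float(side)
    v = o + s * np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
    )
    f = np.array(
        [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
         [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
         [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
    )
    return TriangleMesh(v, f, name="cube")


@pytest.fixture
def cube():
    return make_cube()


@pytest.fixture
def baryonyx():
    """Full measurement set for the Baryonyx holotype endocast."""
    from paleoneuro import SpecimenMeasurements

    return SpecimenMeasurements(
        taxon="Baryonyx",
        specimen_id="NHMUK PV R9951",
        endocast_volume_cm3=150.487,
        femoral_circumference_mm=350.0,
        ecd_mm=19.6,
        bcl_mm=104.5,
        midbrain_length_mm=61.6,
        medulla_length_mm=46.9,
    )
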