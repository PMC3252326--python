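import numpy as np
import pytest

from petalia.geometry import LandmarkSet


@pytest.fixture
def worked_specimen() -> LandmarkSet:
    """Hand-checkable specimen: axis-aligned frame, known component values.

    Frame: anterior=(0,1,0), origin=(0,-20,0), superior=(0,0,1), right=(1,0,0).
    Components: frontal (ap, vert, lat) = (+2, -2, +2) mm,
    occipital (ap, vert, lat) = (-5, 0, 0) mm; pole positions 29 / 20 mm.
    """
    return LandmarkSet(
        specimen_id="worked",
        G=(0, 100, 0),
        I=(0, -100, 0),
        B=(0, -20, -60),
        RFP=(30, 80, 10),
        LFP=(-28, 78, 12),
        ROP=(20, -90, 5),
        LOP=(-20, -95, 5),
        EV=1400.0,
        group="demo",
    )


def random_rigid_motion(rng: np.random.Generator, scale: float = 100.0):
    """A Haar-uniform rotation and a random translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.normal(scale=scale, size=3)
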