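import numpy as np
import pytest

from canopylight.leaf import BilateralLRCParams
from canopylight.scene import (
    ExperimentCondition,
    LampSpec,
    OpticalProperties,
    build_scene,
)

#: one representative bilateral truth (18-DAS third leaf class) used across tests
TRUTH = BilateralLRCParams(
    phi_ad=0.055,
    phi_ab=0.042,
    p_max=53.7,
    theta_ad=0.75,
    theta_ab=0.55,
    rd=-1.7,
)

BLACK = OpticalProperties((0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def truth_params() -> BilateralLRCParams:
    return TRUTH


def empty_scene(lamps, absorbing=True, p_dw=100.0):
    """A plant-free cultivation scene with custom lamps.

    With ``absorbing=True`` every non-mirror surface is a perfect absorber,
    so photons terminate on first contact (direct-illumination mode).
    """
    cond = ExperimentCondition(lai=1.0, phi_lamps=sum(l.ppf for l in lamps), p_dw=p_dw)
    scene = build_scene(cond, with_plants=False)
    scene.lamps = list(lamps)
    if absorbing:
        scene.materials = {k: BLACK for k in scene.materials}
    return scene


def one_triangle_scene(tri, lamps, absorbing=True, rank=3):
    """A scene holding a single leaf triangle (plus the structural surfaces)."""
    scene = empty_scene(lamps, absorbing=absorbing)
    scene.blade_tris = np.asarray(tri, dtype=float).reshape(1, 3, 3)
    scene.blade_plant = np.zeros(1, dtype=np.int32)
    scene.blade_rank = np.full(1, rank, dtype=np.int32)
    return scene


def horizontal_triangle(cx, cy, z, leg):
    """Right triangle in a horizontal plane with upward (adaxial) normal."""
    return np.array(
        [[[cx, cy, z], [cx + leg, cy, z], [cx, cy + leg, z]]], dtype=float
    )


def downward_lamp(ppf, x=0.0, y=0.0, z=0.40):
    return LampSpec(kind="downward", center=(x, y, z), ppf=ppf)


def upward_lamp(ppf, x=0.0, y=0.0, z=0.10):
    return LampSpec(kind="upward", center=(x, y, z), ppf=ppf)
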