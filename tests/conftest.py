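import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from microsolv.structures import Atom, Conformer, Ensemble
from microsolv.synthetic import rigid_water


def make_water(origin, fragment_id=1, direction=None):
    """Rigid water with O at ``origin``; if ``direction`` is given the first
    O-H bond points along it (unit vector)."""
    atoms = rigid_water(np.asarray(origin, dtype=float))
    if direction is not None:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        # rotate so the first O-H (currently +x) points along d
        x = np.array([1.0, 0.0, 0.0])
        v = np.cross(x, d)
        c = float(np.dot(x, d))
        if np.linalg.norm(v) < 1e-12:
            rot = np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx * (1 / (1 + c))
        o = atoms[0].position
        for a in atoms:
            a.position = o + rot @ (a.position - o)
    for a in atoms:
        a.fragment_id = fragment_id
    return atoms


def apply_rigid_motion(conformer, rotation, translation):
    """Return a copy with every atom moved by the same rigid motion."""
    out = conformer.copy()
    for a in out.atoms:
        a.position = rotation @ a.position + np.asarray(translation, dtype=float)
    return out


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


@pytest.fixture
def two_water_conformer():
    """Solute of 3 heavy atoms plus two waters, fragments tagged."""
    from microsolv.structures import AMINE_N10, PHOSPHATE_O

    solute = [
        Atom("N", [-4.0, 0.0, 0.0], 0, AMINE_N10),
        Atom("O", [4.0, 0.0, 0.0], 0, PHOSPHATE_O),
        Atom("C", [0.0, 2.0, 0.0], 0),
    ]
    w1 = make_water([-6.8, 0.0, 0.0], 1, direction=[1.0, 0.0, 0.0])
    w2 = make_water([6.8, 0.0, 0.0], 2, direction=[-1.0, 0.0, 0.0])
    return Conformer("fix-2w", solute + w1 + w2, total_charge=-2)
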