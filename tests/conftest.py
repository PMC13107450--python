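import numpy as np
import pytest

from cidnpkit.geometry import LabeledFrame
from cidnpkit.kinetics import KineticParameters, PulseTiming


@pytest.fixture
def params():
    """Representative kinetic parameters (short-linker dyad, W protons)."""
    return KineticParameters(kt_R0=1e5, T1=500e-6)


@pytest.fixture
def pulse():
    return PulseTiming(4e-6)


def make_two_ring_frame(distance=5.0, tilt_deg=10.0, omegas=(180.0,)):
    """Minimal dyad frame: two hexagons at given center distance and
    inter-plane tilt, an N-H...O=C candidate and omega quadruples."""
    from cidnpkit.synthetic import _hexagon, _omega_quad_coords, _rotation

    f_ring = _hexagon()
    c_at = np.array([2.8, 0.0, 0.0])
    o_at = np.array([4.0, 0.0, 0.0])
    R = _rotation([1.0, 0.0, 0.0], tilt_deg)
    w_ring = _hexagon() @ R.T + np.array([0.0, 0.0, distance])
    n_at = np.array([0.0, 0.0, distance + 2.0])
    h_at = n_at + np.array([0.0, 0.0, 1.0])
    quads, quad_coords = [], []
    base = 16
    for i, om in enumerate(omegas):
        quad_coords.append(_omega_quad_coords(om) + np.array([4.0 * i, -8.0, 0.0]))
        quads.append(tuple(range(base + 4 * i, base + 4 * i + 4)))
    coords = np.vstack([f_ring, c_at, o_at, w_ring, n_at, h_at] + quad_coords)
    n_pro = len(omegas)
    names = (
        [f"F{i+1}" for i in range(6)] + ["FC", "FO"]
        + [f"W{i+1}" for i in range(6)] + ["WN", "WH"]
        + [f"P{i+1}{a}" for i in range(n_pro) for a in ("CA", "C", "N", "CB")]
    )
    residues = ["FLV"] * 8 + ["TRP"] * 8 + [f"PRO{i+1}" for i in range(n_pro) for _ in range(4)]
    return LabeledFrame(
        atom_names=names,
        residue_labels=residues,
        coordinates=coords,
        moiety_masks={"F": np.arange(6), "W": np.arange(8, 14)},
        donor_quads=[(14, 15, 7, 6)],
        omega_atom_quads=quads,
    )


@pytest.fixture
def two_ring_frame():
    return make_two_ring_frame()
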