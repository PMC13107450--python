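"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here under a
seeded random stream, with the generating parameters returned alongside
the data:

* noisy kinetic traces from the cyclic-photoreaction model at the two
  experimental delay designs (three delays 0/3/100 us with a 4 us
  detection pulse, or ten delays spanning 0-100 us with a 2 us pulse);
* field-cycling profiles on the 30-point logarithmic grid from 1 mT to
  9.4 T carrying a J-resonance, delta-g or low-field-hyperfine signature
  (the peak and onset shapes -- a log-normal bump and a logistic onset --
  are generator conventions chosen for classifier testing; the sign
  structure and field scales are the physically meaningful content);
* conformer ensembles of a synthetic two-ring dyad with prescribed
  stacked / hydrogen-bonded / extended fractions and per-proline
  cis-trans labels realized through actual omega dihedrals;
* Stejskal-Tanner diffusion decays on the experimental gradient design.

Determinism: identical spec + seed give bit-identical output; every
generator draws from its own ``numpy.random.Generator`` and never touches
global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diffusion import GYROMAGNETIC_RATIO_1H, DiffusionDecay, gradient_to_si
from .errors import ValidationError
from .geometry import GeometryCriteria, LabeledFrame
from .kinetics import (
    KineticParameters,
    KineticTrace,
    PulseTiming,
    simulate_observed_kinetics,
)
from .spin import FieldProfile, MechanismLabel

__all__ = [
    "DELAYS_THREE_POINT",
    "PULSE_THREE_POINT",
    "DELAYS_TEN_POINT",
    "PULSE_TEN_POINT",
    "default_field_grid",
    "default_gradient_design",
    "gen_kinetic_trace",
    "gen_field_profiles",
    "gen_conformer_ensemble",
    "gen_diffusion_decay",
]

# experimental delay designs
DELAYS_THREE_POINT = np.array([0.0, 3e-6, 100e-6])
PULSE_THREE_POINT = PulseTiming(4e-6)
DELAYS_TEN_POINT = np.linspace(0.0, 100e-6, 10)
PULSE_TEN_POINT = PulseTiming(2e-6)

DEFAULT_KINETIC_NOISE = 0.05     # relative Gaussian
DEFAULT_DIFFUSION_NOISE = 0.01


def default_field_grid(n_points: int = 30, b_min: float = 1e-3, b_max: float = 9.4):
    """Logarithmic field grid of the field-cycling experiment (tesla)."""
    return np.geomspace(b_min, b_max, n_points)


def default_gradient_design():
    """Sixteen gradients linearly spanning 2-95% of 50 G/cm, in T/m."""
    return gradient_to_si(np.linspace(0.02, 0.95, 16) * 50.0, "G/cm")


# --------------------------------------------------------------------------
# kinetic traces
# --------------------------------------------------------------------------

def gen_kinetic_trace(
    params: KineticParameters,
    delays=None,
    pulse: PulseTiming | None = None,
    noise_level: float = DEFAULT_KINETIC_NOISE,
    noise_model: str = "gaussian_relative",
    proton_label: str = "sim",
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[KineticTrace, dict]:
    """Noisy observable trace plus its truth record.

    ``gaussian_relative`` perturbs each point by ``noise_level`` times the
    noise-free model value; ``gaussian_absolute`` adds ``noise_level`` in
    intensity units.  The per-point noise scale is stored in the trace's
    ``sigma`` so that fits can weight accordingly.
    """
    delays = DELAYS_THREE_POINT if delays is None else np.asarray(delays, float)
    pulse = PULSE_THREE_POINT if pulse is None else pulse
    if noise_model not in ("gaussian_relative", "gaussian_absolute"):
        raise ValidationError(f"unknown noise model {noise_model!r}")
    if noise_level < 0:
        raise ValidationError("noise_level must be >= 0")

    clean = simulate_observed_kinetics(params, delays, pulse, proton_label)
    rng = np.random.default_rng(seed)
    if noise_model == "gaussian_relative":
        sigma = noise_level * np.abs(clean.intensities)
    else:
        sigma = np.full_like(clean.intensities, noise_level)
    noisy = clean.intensities + sigma * rng.standard_normal(clean.intensities.size)
    trace = KineticTrace(
        proton_label=proton_label,
        times=clean.times,
        intensities=noisy,
        sigma=sigma.copy(),
    )
    truth = {
        "kind": "kinetic_trace",
        "kt_R0": params.kt_R0,
        "T1": params.T1,
        "P_G": params.P_G,
        "gamma": params.gamma,
        "scale": params.scale,
        "pulse_us": pulse.rf_pulse_duration * 1e6,
        "noise_model": noise_model,
        "noise_level": noise_level,
    }
    return trace, truth


# --------------------------------------------------------------------------
# field profiles
# --------------------------------------------------------------------------

def _lognormal_bump(B, center, log_width):
    return np.exp(-0.5 * (np.log(B / center) / log_width) ** 2)


def gen_field_profiles(
    mechanism: MechanismLabel | str,
    proton_labels: Sequence[str],
    peak_field: float = 13e-3,
    log_width: float = 0.4,
    onset_field: float = 1.5,
    lowfield_center: float = 2e-3,
    amplitudes: Sequence[float] | None = None,
    signs: Sequence[int] | None = None,
    snr: float = 10.0,
    fields=None,
    conformer_class: str = "unassigned",
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[list[FieldProfile], dict]:
    """Synthetic field-cycling profile set with a known mechanism.

    J_BIRADICAL: every proton carries an emissive log-normal peak at
    ``peak_field`` with a negligible high-field tail.  DG_INTERMOLECULAR:
    logistic onset above ``onset_field`` with per-proton ``signs`` (mixed
    by default).  LOWFIELD_HFC: per-proton signed log-normal features at
    ``lowfield_center``, below the J window.  NONE: pure noise.  The noise
    standard deviation is (profile amplitude)/snr.
    """
    mech = MechanismLabel(mechanism) if not isinstance(mechanism, MechanismLabel) else mechanism
    B = default_field_grid() if fields is None else np.asarray(fields, float)
    labels = list(proton_labels)
    if amplitudes is None:
        amplitudes = np.ones(len(labels))
    amplitudes = np.asarray(amplitudes, float)
    if amplitudes.size != len(labels):
        raise ValidationError("amplitudes must match proton_labels")
    if signs is None:
        signs = [(-1) ** i for i in range(len(labels))]
    signs = np.asarray(signs, int)
    if signs.size != len(labels):
        raise ValidationError("signs must match proton_labels")
    if snr <= 0:
        raise ValidationError("snr must be positive")

    if mech is MechanismLabel.J_BIRADICAL and not (B[0] <= peak_field <= B[-1]):
        raise ValidationError(
            f"peak field {peak_field} T lies outside the field grid"
        )

    rng = np.random.default_rng(seed)
    profiles = []
    for lab, amp, sgn in zip(labels, amplitudes, signs):
        if mech is MechanismLabel.J_BIRADICAL:
            clean = -amp * _lognormal_bump(B, peak_field, log_width)
        elif mech is MechanismLabel.DG_INTERMOLECULAR:
            clean = sgn * amp / (1.0 + np.exp(-np.log(B / onset_field) / 0.3))
        elif mech is MechanismLabel.LOWFIELD_HFC:
            clean = sgn * amp * _lognormal_bump(B, lowfield_center, 0.35)
        else:
            clean = np.zeros_like(B)
        noisy = clean + (amp / snr) * rng.standard_normal(B.size)
        profiles.append(
            FieldProfile(
                proton_label=lab,
                fields=B.copy(),
                intensities=noisy,
                conformer_class=conformer_class,
            )
        )
    truth = {
        "kind": "field_profiles",
        "mechanism": mech.value,
        "peak_field": peak_field if mech is MechanismLabel.J_BIRADICAL else None,
        "snr": snr,
        "signs": signs.tolist(),
        "note": "peak/onset line shapes are generator conventions, not a "
        "physical model of the polarization amplitude",
    }
    return profiles, truth


# --------------------------------------------------------------------------
# conformer ensembles
# --------------------------------------------------------------------------

def _hexagon(radius=1.4):
    ang = np.arange(6) * np.pi / 3.0
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)


def _rotation(axis, angle_deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def _omega_quad_coords(omega_deg):
    """Four atoms whose dihedral equals ``omega_deg`` (standard convention)."""
    p1 = np.array([-0.5, 1.2, 0.0])
    p2 = np.array([0.0, 0.0, 0.0])
    p3 = np.array([1.5, 0.0, 0.0])
    base = np.array([0.0, 1.2, 0.0])  # direction of p4 offset for omega = 0
    rot = _rotation([1.0, 0.0, 0.0], omega_deg)
    p4 = p3 + rot @ base
    return np.stack([p1, p2, p3, p4])


@dataclass(frozen=True)
class EnsembleTruth:
    stacked_fraction: float
    hbond_fraction: float
    label_distribution: dict[str, float]
    n_frames: int


def gen_conformer_ensemble(
    n_frames: int,
    stacked_fraction: float = 0.20,
    hbond_fraction: float = 0.05,
    label_distribution: dict[str, float] | None = None,
    extended_distance: tuple[float, float] = (12.0, 1.5),
    omega_spread: float = 10.0,
    criteria: GeometryCriteria | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[list[LabeledFrame], EnsembleTruth]:
    """Labeled frames of a synthetic two-ring dyad.

    Each frame is drawn into exactly one geometry class -- stacked,
    hydrogen-bonded, or extended -- with the given probabilities
    (exclusive classes; their sum must not exceed 1).  Stacked frames
    satisfy the stacking criterion by construction (center distance within
    the band, plane angle in the parallel wings); H-bonded frames realize
    an N-H...O=C contact satisfying the distance and both angle cutoffs
    while remaining unstacked (perpendicular rings); extended frames place
    the rings around ``extended_distance`` = (mean, sd) angstrom apart.
    Proline states are realized through actual omega dihedrals drawn
    around 0 (cis) or 180 (trans) degrees with ``omega_spread`` sd.

    ``label_distribution`` maps cis/trans codes (e.g. ``"CTT"``) to
    probabilities; default is all-trans ``"TTT"``.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    if not (0 <= stacked_fraction <= 1 and 0 <= hbond_fraction <= 1):
        raise ValidationError("fractions must lie in [0, 1]")
    if stacked_fraction + hbond_fraction > 1:
        raise ValidationError(
            "stacked_fraction + hbond_fraction exceed 1 in exclusive mode"
        )
    crit = criteria or GeometryCriteria()
    label_distribution = dict(label_distribution or {"TTT": 1.0})
    codes = list(label_distribution)
    probs = np.array([label_distribution[c] for c in codes], float)
    if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
        raise ValidationError("label_distribution probabilities must sum to 1")
    n_pro = len(codes[0])
    if any(len(c) != n_pro for c in codes):
        raise ValidationError("all conformer codes must have equal length")

    rng = np.random.default_rng(seed)
    hex_f = _hexagon()
    hex_w = _hexagon()
    frames = []
    for _ in range(n_frames):
        u = rng.random()
        if u < stacked_fraction:
            mode = "stacked"
        elif u < stacked_fraction + hbond_fraction:
            mode = "hbond"
        else:
            mode = "extended"

        # flavin ring in the z=0 plane; carbonyl C-O on its rim
        f_ring = hex_f.copy()
        c_at = np.array([2.8, 0.0, 0.0])
        o_at = np.array([4.0, 0.0, 0.0])

        if mode == "stacked":
            d = rng.uniform(crit.stack_dmin + 0.2, crit.stack_dmax - 0.5)
            tilt = rng.uniform(0.0, crit.stack_angle_lo - 5.0)
            if rng.random() < 0.5:
                tilt = 180.0 - tilt
            normal_dir = np.array([0.0, 0.0, 1.0])
            center_w = d * normal_dir
            R = _rotation([1.0, 0.0, 0.0], tilt)
            w_ring = hex_w @ R.T + center_w
            # donor far from the acceptor oxygen, on the outer face
            n_at = center_w + R @ np.array([-2.5, 0.0, 0.0])
            h_at = n_at + R @ np.array([-1.0, 0.0, 0.0])
        elif mode == "hbond":
            # place H 1.8-2.6 A from O, anti to the C=O bond; N-H-O linear
            d_ho = rng.uniform(1.8, min(2.6, crit.hbond_dmax - 0.2))
            u_oc = (c_at - o_at) / np.linalg.norm(c_at - o_at)
            h_at = o_at - d_ho * u_oc
            n_at = h_at - 1.0 * u_oc
            # tryptophan ring perpendicular to the flavin plane, attached to N
            R = _rotation([0.0, 1.0, 0.0], 90.0)
            center_w = n_at + np.array([2.0, 0.0, 0.0])
            w_ring = hex_w @ R.T + center_w
        else:
            mean_d, sd_d = extended_distance
            d = max(rng.normal(mean_d, sd_d), crit.stack_dmax + 0.6)
            theta = rng.uniform(crit.stack_angle_lo + 5.0, crit.stack_angle_hi - 5.0)
            direction = np.array([1.0, 0.0, 0.0])
            center_w = d * direction
            R = _rotation([0.0, 1.0, 0.0], theta)
            w_ring = hex_w @ R.T + center_w
            n_at = center_w + np.array([2.0, 0.0, 0.0])
            h_at = n_at + np.array([1.0, 0.0, 0.0])

        code = codes[rng.choice(len(codes), p=probs)]
        omega_quads = []
        quad_coords = []
        base_index = 6 + 2 + 6 + 2  # F ring, C, O, W ring, N, H
        offset = np.array([0.0, -8.0, 0.0])
        for i, ch in enumerate(code):
            target = 0.0 if ch == "C" else 180.0
            omega = rng.normal(target, omega_spread)
            # keep the draw inside the basin so labels stay exact
            omega = np.clip(omega, target - 60.0, target + 60.0)
            if omega > 180.0:
                omega -= 360.0
            q = _omega_quad_coords(omega) + offset + np.array([4.0 * i, 0.0, 0.0])
            quad_coords.append(q)
            omega_quads.append(tuple(range(base_index + 4 * i, base_index + 4 * i + 4)))

        coords = np.vstack([f_ring, c_at, o_at, w_ring, n_at, h_at] + quad_coords)
        names = (
            [f"F{i+1}" for i in range(6)]
            + ["FC", "FO"]
            + [f"W{i+1}" for i in range(6)]
            + ["WN", "WH"]
            + [f"P{i+1}{a}" for i in range(n_pro) for a in ("CA", "C", "N", "CB")]
        )
        residues = (
            ["FLV"] * 8 + ["TRP"] * 8 + [f"PRO{i+1}" for i in range(n_pro) for _ in range(4)]
        )
        frame = LabeledFrame(
            atom_names=names,
            residue_labels=residues,
            coordinates=coords,
            moiety_masks={"F": np.arange(6), "W": np.arange(8, 14)},
            donor_quads=[(14, 15, 7, 6)],  # (N, H, O, C)
            omega_atom_quads=omega_quads,
        )
        frames.append(frame)

    truth = EnsembleTruth(
        stacked_fraction=stacked_fraction,
        hbond_fraction=hbond_fraction,
        label_distribution=label_distribution,
        n_frames=n_frames,
    )
    return frames, truth


# --------------------------------------------------------------------------
# diffusion decays
# --------------------------------------------------------------------------

def gen_diffusion_decay(
    D: float,
    gradients=None,
    big_delta: float = 50e-3,
    little_delta: float = 2e-3,
    I0: float = 1.0,
    noise_level: float = DEFAULT_DIFFUSION_NOISE,
    gyromagnetic_ratio: float = GYROMAGNETIC_RATIO_1H,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[DiffusionDecay, dict]:
    """Stejskal-Tanner decay with known diffusion coefficient.

    Default design: 16 gradients linearly spanning 2-95% of 50 G/cm,
    Delta = 50 ms, delta = 2 ms.  Relative Gaussian noise of
    ``noise_level`` is applied to each point.
    """
    if D <= 0:
        raise ValidationError("D must be positive")
    g = default_gradient_design() if gradients is None else np.asarray(gradients, float)
    decay = DiffusionDecay(
        gradients=g,
        intensities=np.ones_like(g),
        big_delta=big_delta,
        little_delta=little_delta,
        gyromagnetic_ratio=gyromagnetic_ratio,
    )
    clean = I0 * np.exp(-D * decay.b_factors)
    rng = np.random.default_rng(seed)
    noisy = clean * (1.0 + noise_level * rng.standard_normal(clean.size))
    decay = DiffusionDecay(
        gradients=g,
        intensities=noisy,
        big_delta=big_delta,
        little_delta=little_delta,
        gyromagnetic_ratio=gyromagnetic_ratio,
    )
    truth = {
        "kind": "diffusion_decay",
        "D": D,
        "I0": I0,
        "big_delta": big_delta,
        "little_delta": little_delta,
        "noise_level": noise_level,
    }
    return decay, truth
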