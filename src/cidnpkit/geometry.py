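"""Geometric analysis of donor-acceptor conformer ensembles.

Operates on annotated multi-frame coordinate sets of a flavin (F) /
tryptophan (W) dyad joined by an oligoproline linker:

* proline cis/trans state from the peptide-bond dihedral omega
  (|omega| < 90 deg = cis), giving per-frame labels such as ``"CTT"``
  ordered from the proline closest to the flavin;
* distance between the geometric centers of the F and W ring systems and
  the angle between their best-fit plane normals;
* pi-pi stacking classification: center distance within 3-6.5 A and
  inter-plane angle below 45 deg or above 135 deg;
* hydrogen-bond classification: H...O below 3 A with both the N-H...O and
  H...O-C angles above 130 deg;
* per-label (conditional) stacking / H-bond probabilities and
  distance/angle distributions, pooled into a population-weighted "Sum".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "LabeledFrame",
    "ConformerLabel",
    "GeometryCriteria",
    "EnsembleStatistics",
    "omega_dihedral",
    "classify_cis_trans",
    "label_frame",
    "moiety_center_distance",
    "interplane_angle",
    "is_stacked",
    "is_hbond",
    "ensemble_statistics",
    "per_atom_energy_difference",
]

_COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class GeometryCriteria:
    """Thresholds of the geometric classifiers.

    Distances in angstrom, angles in degrees.  The stacking distance band
    is inclusive at both ends; the angle bounds are strict (< 45 or > 135),
    and the criterion treats theta and 180-theta symmetrically because the
    two plane normals have no preferred orientation.
    """

    stack_dmin: float = 3.0
    stack_dmax: float = 6.5
    stack_angle_lo: float = 45.0
    stack_angle_hi: float = 135.0
    hbond_dmax: float = 3.0
    hbond_angle_min: float = 130.0
    cis_cut: float = 90.0

    def __post_init__(self):
        if not (0 < self.stack_dmin < self.stack_dmax):
            raise ValidationError("need 0 < stack_dmin < stack_dmax")
        if not (0 < self.stack_angle_lo < self.stack_angle_hi < 180):
            raise ValidationError("need 0 < stack_angle_lo < stack_angle_hi < 180")
        if not (self.hbond_dmax > 0 and 0 < self.hbond_angle_min < 180):
            raise ValidationError("invalid hydrogen-bond thresholds")
        if not (0 < self.cis_cut <= 180):
            raise ValidationError("cis_cut must lie in (0, 180]")


@dataclass(frozen=True)
class ConformerLabel:
    """Cis/trans code of the proline linker, e.g. ``"CTT"``.

    Position 1 is the proline closest to the flavin.
    """

    code: str

    def __post_init__(self):
        if not self.code or any(c not in "TC" for c in self.code):
            raise ValidationError(
                f"conformer code must be a nonempty string over {{T, C}}, got {self.code!r}"
            )

    def __str__(self) -> str:
        return self.code


@dataclass
class LabeledFrame:
    """One annotated coordinate frame of the dyad.

    Attributes
    ----------
    atom_names, residue_labels : lists of str, one entry per atom.
    coordinates : (n_atoms, 3) float array, angstrom.
    moiety_masks : dict with integer index arrays under ``"F"`` (flavin ring
        system) and ``"W"`` (tryptophan indole).
    donor_quads : candidate hydrogen bonds as (N, H, O, C) atom indices,
        where C is the carbon bonded to the acceptor oxygen.
    omega_atom_quads : per proline, the four atom indices defining the
        peptide-bond dihedral omega, ordered flavin-first.
    """

    atom_names: list[str]
    residue_labels: list[str]
    coordinates: np.ndarray
    moiety_masks: dict[str, np.ndarray]
    donor_quads: list[tuple[int, int, int, int]] = field(default_factory=list)
    omega_atom_quads: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = self.coordinates.shape[0]
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValidationError("coordinates must have shape (n_atoms, 3)")
        if len(self.atom_names) != n or len(self.residue_labels) != n:
            raise ValidationError("atom_names/residue_labels length must match coordinates")
        for key in ("F", "W"):
            if key not in self.moiety_masks:
                raise ValidationError(f"moiety_masks must define {key!r}")
            self.moiety_masks[key] = idx = np.asarray(self.moiety_masks[key], dtype=int)
            if idx.size < 3:
                raise ValidationError(f"moiety mask {key!r} needs >= 3 atoms to span a plane")
            if idx.min() < 0 or idx.max() >= n:
                raise ValidationError(f"moiety mask {key!r} has out-of-range indices")
        if np.intersect1d(self.moiety_masks["F"], self.moiety_masks["W"]).size:
            raise ValidationError("F and W moiety masks must be disjoint")
        for quad in list(self.donor_quads) + list(self.omega_atom_quads):
            if len(quad) != 4 or min(quad) < 0 or max(quad) >= n:
                raise ValidationError(f"invalid atom quadruple {quad!r}")


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees, in (-180, 180] (IUPAC sign convention)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < _COLLINEAR_TOL:
        raise DegenerateGeometryError("central dihedral atoms coincide")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < _COLLINEAR_TOL or np.linalg.norm(w) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("collinear atoms leave the dihedral undefined")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


def omega_dihedral(frame: LabeledFrame, proline_index: int) -> float:
    """Peptide-bond dihedral omega of one proline, degrees in (-180, 180]."""
    try:
        quad = frame.omega_atom_quads[proline_index]
    except IndexError:
        raise ValidationError(
            f"frame defines {len(frame.omega_atom_quads)} omega quadruples; "
            f"index {proline_index} out of range"
        ) from None
    p = frame.coordinates[list(quad)]
    return _dihedral(p[0], p[1], p[2], p[3])


def classify_cis_trans(omega: float, criteria: GeometryCriteria | None = None) -> str:
    """``"C"`` (cis) if |omega| < cis_cut else ``"T"`` (trans).

    The boundary |omega| == cis_cut is assigned trans.
    """
    c = criteria or GeometryCriteria()
    if not -180.0 <= omega <= 180.0:
        raise ValidationError(f"omega must lie in [-180, 180], got {omega}")
    return "C" if abs(omega) < c.cis_cut else "T"


def label_frame(frame: LabeledFrame, criteria: GeometryCriteria | None = None) -> ConformerLabel:
    """Cis/trans code over all prolines of the frame, flavin-first."""
    if not frame.omega_atom_quads:
        raise ValidationError("frame defines no omega quadruples to label")
    code = "".join(
        classify_cis_trans(omega_dihedral(frame, i), criteria)
        for i in range(len(frame.omega_atom_quads))
    )
    return ConformerLabel(code)


def _centroid(frame: LabeledFrame, key: str) -> np.ndarray:
    return frame.coordinates[frame.moiety_masks[key]].mean(axis=0)


def moiety_center_distance(frame: LabeledFrame) -> float:
    """Distance between the unweighted centroids of the F and W masks, angstrom."""
    return float(np.linalg.norm(_centroid(frame, "F") - _centroid(frame, "W")))


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the total-least-squares plane through ``points``."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < _COLLINEAR_TOL:
        raise DegenerateGeometryError("mask atoms are collinear; no plane defined")
    return vt[2]


def interplane_angle(frame: LabeledFrame) -> float:
    """Angle between the F and W best-fit plane normals, degrees in [0, 180].

    The normals come from a total-least-squares plane fit (the smallest
    principal direction of the centered mask coordinates).  Because an SVD
    normal has arbitrary orientation, 0 and 180 degrees are physically the
    same "parallel" arrangement; downstream stacking criteria treat the two
    symmetrically.
    """
    nf = _plane_normal(frame.coordinates[frame.moiety_masks["F"]])
    nw = _plane_normal(frame.coordinates[frame.moiety_masks["W"]])
    cosang = np.clip(np.dot(nf, nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def is_stacked(d: float, theta: float, criteria: GeometryCriteria | None = None) -> bool:
    """Pi-pi stacking test on a center distance (A) and plane angle (deg)."""
    c = criteria or GeometryCriteria()
    if d < 0:
        raise ValidationError("distance must be >= 0")
    if not 0 <= theta <= 180:
        raise ValidationError("theta must lie in [0, 180]")
    return bool(
        c.stack_dmin <= d <= c.stack_dmax
        and (theta < c.stack_angle_lo or theta > c.stack_angle_hi)
    )


def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < _COLLINEAR_TOL or n2 < _COLLINEAR_TOL:
        raise DegenerateGeometryError("coincident atoms leave the angle undefined")
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))))


def is_hbond(
    frame: LabeledFrame,
    quad: tuple[int, int, int, int],
    criteria: GeometryCriteria | None = None,
) -> bool:
    """Hydrogen-bond test for one (N, H, O, C) candidate quadruple.

    True iff the H...O distance is below ``hbond_dmax`` and both the
    N-H...O angle (vertex H) and the H...O-C angle (vertex O) exceed
    ``hbond_angle_min``.
    """
    c = criteria or GeometryCriteria()
    if len(quad) != 4:
        raise ValidationError("hydrogen-bond candidate must be an (N, H, O, C) quadruple")
    n_i, h_i, o_i, c_i = quad
    coords = frame.coordinates
    for i in quad:
        if not 0 <= i < coords.shape[0]:
            raise ValidationError(f"atom index {i} out of range")
    if not np.all(np.isfinite(coords[h_i])):
        raise ValidationError("hydrogen coordinates are missing or non-finite")
    N, H, O, C = coords[n_i], coords[h_i], coords[o_i], coords[c_i]
    d_ho = float(np.linalg.norm(H - O))
    if d_ho >= c.hbond_dmax:
        return False
    if _angle(N, H, O) <= c.hbond_angle_min:
        return False
    if _angle(H, O, C) <= c.hbond_angle_min:
        return False
    return True


def frame_has_hbond(frame: LabeledFrame, criteria: GeometryCriteria | None = None) -> bool:
    """True if any declared donor quadruple of the frame forms a hydrogen bond."""
    return any(is_hbond(frame, q, criteria) for q in frame.donor_quads)


@dataclass
class LabelStatistics:
    """Per-conformer-label summary of an ensemble."""

    n_frames: int
    p_stacked: float
    p_hbond: float
    distance_hist: tuple[np.ndarray, np.ndarray]  # (density, bin_edges)
    angle_hist: tuple[np.ndarray, np.ndarray]
    distances: np.ndarray
    angles: np.ndarray


@dataclass
class EnsembleStatistics:
    """Conditional and pooled geometric statistics of a labeled ensemble."""

    per_label: dict[str, LabelStatistics]
    pooled: LabelStatistics
    label_fractions: dict[str, float]


def _hist(values: np.ndarray, bins) -> tuple[np.ndarray, np.ndarray]:
    if values.size == 0:
        return np.array([]), np.array([])
    if np.ptp(values) == 0:  # all identical: single unit-density bin
        edges = np.array([values[0] - 0.5, values[0] + 0.5])
        return np.array([1.0]), edges
    density, edges = np.histogram(values, bins=bins, density=True)
    return density, edges


def ensemble_statistics(
    frames: Sequence[LabeledFrame],
    criteria: GeometryCriteria | None = None,
    bins="fd",
) -> EnsembleStatistics:
    """Distance/angle distributions and conditional stacking / H-bond
    probabilities per conformer label, plus the pooled ("Sum") statistics.

    Histograms use Freedman-Diaconis binning by default and are normalized
    to unit integral.  Conditional probabilities are straight per-label
    frame counts, so the pooled probability equals the label-fraction
    weighted mixture of the conditionals.
    """
    frames = list(frames)
    if not frames:
        raise ValidationError("ensemble_statistics requires at least one frame")
    c = criteria or GeometryCriteria()

    labels, dists, angs, stacked, hbonded = [], [], [], [], []
    for fr in frames:
        labels.append(str(label_frame(fr, c)))
        d = moiety_center_distance(fr)
        th = interplane_angle(fr)
        dists.append(d)
        angs.append(th)
        stacked.append(is_stacked(d, th, c))
        hbonded.append(frame_has_hbond(fr, c))
    labels = np.array(labels)
    dists = np.array(dists)
    angs = np.array(angs)
    stacked = np.array(stacked)
    hbonded = np.array(hbonded)

    def make(mask: np.ndarray) -> LabelStatistics:
        return LabelStatistics(
            n_frames=int(mask.sum()),
            p_stacked=float(stacked[mask].mean()),
            p_hbond=float(hbonded[mask].mean()),
            distance_hist=_hist(dists[mask], bins),
            angle_hist=_hist(angs[mask], bins),
            distances=dists[mask],
            angles=angs[mask],
        )

    per_label = {lab: make(labels == lab) for lab in sorted(set(labels))}
    pooled = make(np.ones(len(frames), dtype=bool))
    fractions = {lab: st.n_frames / len(frames) for lab, st in per_label.items()}
    return EnsembleStatistics(per_label=per_label, pooled=pooled, label_fractions=fractions)


def per_atom_energy_difference(mean_a: float, mean_b: float, n_atoms: int) -> float:
    """|mean_a - mean_b| / n_atoms, kcal/mol per atom.

    Used to express the spread of conformer mean energies on a size-independent
    scale (e.g. 26 kcal/mol over 108 atoms is about 0.24 kcal/mol per atom).
    """
    if n_atoms is None or n_atoms <= 0:
        raise ValidationError("n_atoms must be a positive integer")
    return abs(float(mean_a) - float(mean_b)) / n_atoms
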