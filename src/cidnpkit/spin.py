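"""Radical-pair sign rules, level-anticrossing fields and the
field-cycling mechanism classifier.

The sign of photo-CIDNP polarization of a nucleus formed in a
spin-correlated radical pair depends on the field regime:

* **High field** (Zeeman splitting dominates): the classic Kaptein product
  rule, ``gamma = sgn(dg) * sgn(a) * mu * eps``, where ``dg`` is the
  difference of electron g-factors, ``a`` the hyperfine coupling of the
  nucleus, ``mu`` the precursor multiplicity (+1 triplet, -1 singlet) and
  ``eps`` the exit channel (+1 geminate recombination, -1 escape).  The
  sign is nucleus-specific through ``sgn(a)``.
* **Exchange-dominated regime** (level anticrossing of S with T+ or T- in
  a biradical at restricted distance): ``gamma = sgn(J_ex) * mu * eps``.
  The hyperfine coupling drops out, so *every* nucleus acquires the same
  sign -- the key experimental fingerprint of intramolecular biradical
  recombination.

The level anticrossing occurs where the electron Zeeman splitting matches
the exchange interaction, ``B_LAC ~ |J_ex| / (g mu_B)``.

:func:`classify_mechanism` turns these rules into a decision procedure for
measured (or synthetic) field profiles: uniform-sign mid-field maxima with
a silent high field indicate an intramolecular biradical (J-resonance);
nucleus-specific signs confined to high field indicate intermolecular
encounters polarized by the delta-g mechanism; nucleus-specific signs at
fields comparable to the hyperfine couplings indicate the low-field
hyperfine regime.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.constants import h as PLANCK_H
from scipy.constants import physical_constants

from .errors import (
    InsufficientEvidenceError,
    NormalizationError,
    NotApplicableError,
    UnitError,
    ValidationError,
)

BOHR_MAGNETON = physical_constants["Bohr magneton"][0]  # J/T
FREE_ELECTRON_G = 2.0023

__all__ = [
    "RadicalPairConfig",
    "FieldProfile",
    "MechanismCall",
    "MechanismLabel",
    "FieldRegime",
    "ClassifierThresholds",
    "kaptein_high_field_sign",
    "j_resonance_sign",
    "lac_field",
    "j_from_field",
    "classify_field_regime",
    "normalize_profiles",
    "classify_mechanism",
    "MechanismClassifier",
]


@dataclass(frozen=True)
class RadicalPairConfig:
    """Signs and magnitudes characterizing one spin-correlated radical pair.

    Parameters
    ----------
    sgn_delta_g : int
        Sign (+1/-1) of the electron g-factor difference of the two radicals.
    sgn_a : int
        Sign of the isotropic hyperfine coupling of the observed nucleus.
    mu : int
        +1 for a triplet precursor, -1 for a singlet precursor.
    eps : int
        +1 for geminate recombination products, -1 for escape products.
    sgn_J : int
        Sign of the exchange interaction J_ex; 0 when unknown/not applicable.
    J_abs : float, optional
        Magnitude of J_ex, in the unit named by ``J_unit``.
    J_unit : str
        ``"J"`` (energy) or ``"Hz"`` (frequency, converted via Planck's h).
    g : float
        Mean electron g-factor used for field conversions.
    """

    sgn_delta_g: int
    sgn_a: int
    mu: int
    eps: int
    sgn_J: int = 0
    J_abs: float | None = None
    J_unit: str = "J"
    g: float = FREE_ELECTRON_G

    def __post_init__(self):
        for name in ("sgn_delta_g", "sgn_a", "mu", "eps"):
            if getattr(self, name) not in (-1, +1):
                raise ValidationError(f"{name} must be +1 or -1, got {getattr(self, name)!r}")
        if self.sgn_J not in (-1, 0, +1):
            raise ValidationError(f"sgn_J must be -1, 0 or +1, got {self.sgn_J!r}")
        if self.J_abs is not None and not (self.J_abs >= 0):
            raise ValidationError(f"J_abs must be >= 0, got {self.J_abs!r}")
        if self.J_unit not in ("J", "Hz"):
            raise UnitError(f"J_unit must be 'J' or 'Hz', got {self.J_unit!r}")
        if not (self.g > 0):
            raise ValidationError("g must be positive")


def kaptein_high_field_sign(config: RadicalPairConfig) -> int:
    """Kaptein net-effect sign in the high-field delta-g regime.

    Returns ``sgn(dg) * sgn(a) * mu * eps``: +1 absorptive, -1 emissive.
    """
    return config.sgn_delta_g * config.sgn_a * config.mu * config.eps


def j_resonance_sign(config: RadicalPairConfig) -> int:
    """Polarization sign at the S/T+- level anticrossing of a biradical.

    Returns ``sgn(J_ex) * mu * eps``.  Independent of the hyperfine sign,
    hence identical for all nuclei of the pair.
    """
    if config.sgn_J == 0:
        raise NotApplicableError(
            "j_resonance_sign requires a nonzero exchange interaction sign"
        )
    return config.sgn_J * config.mu * config.eps


def _j_to_joule(J_abs: float, unit: str) -> float:
    if unit == "J":
        return float(J_abs)
    if unit == "Hz":
        return float(J_abs) * PLANCK_H
    raise UnitError(f"unknown exchange-interaction unit {unit!r}; use 'J' or 'Hz'")


def lac_field(J_abs: float, unit: str = "J", g: float = FREE_ELECTRON_G) -> float:
    """Level-anticrossing field ``B_LAC = |J_ex| / (g mu_B)`` in tesla.

    ``unit`` declares how ``J_abs`` is expressed: ``"J"`` for an energy or
    ``"Hz"`` for a frequency (|J_ex|/h), converted through Planck's constant.
    """
    if J_abs < 0:
        raise ValidationError("J_abs must be >= 0")
    return _j_to_joule(J_abs, unit) / (g * BOHR_MAGNETON)


def j_from_field(B_lac: float, unit: str = "J", g: float = FREE_ELECTRON_G) -> float:
    """Exact inverse of :func:`lac_field`: exchange magnitude from B_LAC."""
    if B_lac < 0:
        raise ValidationError("B_lac must be >= 0")
    joule = B_lac * g * BOHR_MAGNETON
    if unit == "J":
        return joule
    if unit == "Hz":
        return joule / PLANCK_H
    raise UnitError(f"unknown exchange-interaction unit {unit!r}; use 'J' or 'Hz'")


class FieldRegime(enum.Enum):
    LOW_HFC = "LOW_HFC"
    INTERMEDIATE_J = "INTERMEDIATE_J"
    GAP = "GAP"
    HIGH_DG = "HIGH_DG"


def classify_field_regime(
    B: float,
    a_scale: float,
    J_field: float,
    similar_factor: float = 3.0,
    dominant_factor: float = 10.0,
    delta_g_rel: float = 1e-3,
) -> FieldRegime:
    """Assign a magnetic field to one of the four CIDNP field regimes.

    The qualitative conditions "B comparable to the hyperfine field" and
    "electron Zeeman splitting matching |J_ex|" are quantified by two
    documented constants: *comparable* means within ``similar_factor``
    (default 3) and *much greater* means at least ``dominant_factor``
    (default 10) times larger.  The delta-g pathway switches on only once
    the Zeeman *difference* of the two radicals competes with the
    hyperfine mixing, i.e. above ``a_scale / delta_g_rel`` (about 1 T for
    millitesla hyperfine fields and a typical organic-radical g-factor
    difference of 1e-3); between the exchange window and that onset lies
    the gap where no pathway is effective.

    Parameters
    ----------
    B : float
        Field to classify, tesla.
    a_scale : float
        Typical hyperfine coupling expressed as a field, tesla.
    J_field : float
        ``|J_ex| / (g mu_B)``, tesla.
    delta_g_rel : float
        Relative electron g-factor difference of the radical pair.
    """
    if not (B > 0 and a_scale > 0 and J_field > 0 and delta_g_rel > 0):
        raise ValidationError("B, a_scale, J_field and delta_g_rel must be positive")
    if B <= similar_factor * a_scale:
        return FieldRegime.LOW_HFC
    if (
        J_field / similar_factor <= B <= J_field * similar_factor
        and B >= dominant_factor * a_scale
    ):
        return FieldRegime.INTERMEDIATE_J
    if B >= a_scale / delta_g_rel and B >= dominant_factor * J_field:
        return FieldRegime.HIGH_DG
    return FieldRegime.GAP


@dataclass
class FieldProfile:
    """CIDNP intensity of one proton versus magnetic field.

    ``fields`` are in tesla, strictly ascending and positive; intensities
    are signed, in arbitrary (but common within a set) units.
    """

    proton_label: str
    fields: np.ndarray
    intensities: np.ndarray
    conformer_class: str = "unassigned"

    def __post_init__(self):
        self.fields = np.asarray(self.fields, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.conformer_class not in ("major", "minor", "unassigned"):
            raise ValidationError(
                f"conformer_class must be major/minor/unassigned, got {self.conformer_class!r}"
            )
        if self.fields.ndim != 1 or self.fields.size < 2:
            raise ValidationError("fields must be a 1-D array with >= 2 points")
        if self.fields.shape != self.intensities.shape:
            raise ValidationError("fields and intensities must have equal length")
        if not np.all(self.fields > 0):
            raise ValidationError("all fields must be > 0")
        if not np.all(np.diff(self.fields) > 0):
            raise ValidationError("fields must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")


class MechanismLabel(enum.Enum):
    J_BIRADICAL = "J_BIRADICAL"
    DG_INTERMOLECULAR = "DG_INTERMOLECULAR"
    LOWFIELD_HFC = "LOWFIELD_HFC"
    NONE = "NONE"


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision constants of :func:`classify_mechanism`.

    All comparisons of "significant" intensity are made against a per-proton
    noise floor estimated as ``noise_floor_k`` times the robust standard
    deviation (1.4826 * MAD) of the profile inside the null window -- the
    field interval where neither the exchange nor the delta-g pathway is
    effective, so that any variation there is noise.
    """

    window: tuple[float, float] = (5e-3, 20e-3)  # J-resonance search window, T
    sign_uniformity: float = 1.0
    highfield_ratio: float = 3.0
    noise_floor_k: float = 3.0
    null_window: tuple[float, float] = (0.1, 1.0)  # T
    highfield_min: float = 1.0  # T; start of the delta-g dominated regime
    lowfield_max: float = 5e-3  # T; upper end of the hyperfine regime
    # A mid-field feature vetoes the intermolecular call only when it is at
    # least this large relative to the high-field response (a J-like feature
    # comparable to the delta-g feature); smaller bumps are treated as noise.
    dg_midfield_veto_ratio: float = 1.0
    # A feature counts as real only when its strongest point reaches
    # feature_factor times the noise floor (with >= 2 supporting points
    # above the floor); this buys a wide margin against the sampling
    # variability of the floor estimate itself.
    feature_factor: float = 1.5


def normalize_profiles(
    profiles: Sequence[FieldProfile],
    reference_field: float = 10e-3,
    min_reference_intensity: float = 1e-12,
) -> list[FieldProfile]:
    """Rescale each profile by its |intensity| at ``reference_field``.

    The reference intensity is interpolated linearly in log(B) between the
    two bracketing grid points; after normalization it equals +-1, making
    profile sets recorded at different concentrations comparable.  The
    operation is idempotent.
    """
    out = []
    for p in profiles:
        if not (p.fields[0] <= reference_field <= p.fields[-1]):
            raise ValidationError(
                f"profile {p.proton_label!r}: reference field {reference_field} T "
                f"outside measured range [{p.fields[0]}, {p.fields[-1]}] T"
            )
        ref = float(np.interp(math.log(reference_field), np.log(p.fields), p.intensities))
        if abs(ref) < min_reference_intensity:
            raise NormalizationError(
                f"profile {p.proton_label!r}: intensity at the reference field is "
                f"{ref:g}, too close to zero to normalize"
            )
        out.append(
            FieldProfile(
                proton_label=p.proton_label,
                fields=p.fields.copy(),
                intensities=p.intensities / abs(ref),
                conformer_class=p.conformer_class,
            )
        )
    return out


@dataclass
class MechanismCall:
    """Verdict of the field-profile mechanism classifier with its evidence."""

    label: MechanismLabel
    peak_field: float | None
    sign_uniformity: float
    highfield_ratio: float
    evidence_notes: str = ""


def _pooled_noise_floor(profiles, thr: ClassifierThresholds) -> float:
    """Noise floor from the null window of *all* profiles pooled.

    The null window (default 0.1-1 T) carries no polarization from either
    the exchange or the delta-g pathway, so its scatter estimates the
    measurement noise.  A per-proton scale estimate from the handful of
    points there is far too variable; the deviations of all protons (each
    centred on its own median) are pooled, and -- because the window is
    signal-free by construction -- the efficient root-mean-square scale is
    used rather than a robust one."""
    devs = []
    for p in profiles:
        lo, hi = thr.null_window
        mask = (p.fields >= lo) & (p.fields <= hi)
        vals = p.intensities[mask]
        if vals.size < 3:  # fall back to the full profile
            vals = p.intensities
        devs.append(vals - np.median(vals))
    devs = np.concatenate(devs)
    scale = float(np.sqrt(np.mean(devs**2)))
    return thr.noise_floor_k * scale


def _grid_log_step(fields: np.ndarray) -> float:
    return float(np.median(np.diff(np.log(fields))))


def _window_extremum(p: FieldProfile, thr: ClassifierThresholds, floor: float = 0.0):
    """Strongest interior three-point local extremum of |I| whose field
    falls in the search window, widened by one grid step on each side
    (at finite signal-to-noise the grid argmax jitters by a step, so the
    extremum cannot be located more precisely than the grid resolution).

    Returns (field, signed value) or None.
    """
    absI = np.abs(p.intensities)
    step = _grid_log_step(p.fields)
    lo = thr.window[0] * math.exp(-step)
    hi = thr.window[1] * math.exp(step)
    best = None
    for i in range(1, p.fields.size - 1):
        if not (lo <= p.fields[i] <= hi):
            continue
        if absI[i] >= absI[i - 1] and absI[i] >= absI[i + 1]:
            # a lone point above the floor is a noise excursion, not a
            # resonance: require a significant shoulder on either side
            if max(absI[i - 1], absI[i + 1]) < floor:
                continue
            if best is None or absI[i] > abs(best[1]):
                best = (float(p.fields[i]), float(p.intensities[i]))
    return best


def classify_mechanism(
    profiles: Sequence[FieldProfile],
    thresholds: ClassifierThresholds | None = None,
) -> MechanismCall:
    """Classify a set of field profiles (one conformer class) by mechanism.

    The three biradical criteria are, in the order tested:

    1. every proton with a significant mid-field feature carries the *same*
       polarization sign (sign uniformity >= ``thresholds.sign_uniformity``),
    2. an interior extremum of |intensity| lies inside the J-resonance
       window (default 5-20 mT), significant against the noise floor,
    3. the high-field (>= 1 T) response is weak: the mid-field extremum
       exceeds it by at least ``thresholds.highfield_ratio``.

    Failing that, significant high-field intensities with nucleus-specific
    (mixed) signs and no comparable mid-field feature give the
    intermolecular delta-g call; significant nucleus-specific signals
    confined below the hyperfine field scale give the low-field hyperfine
    call; anything else is NONE.
    """
    thr = thresholds or ClassifierThresholds()
    profiles = list(profiles)
    if len(profiles) < 2:
        raise InsufficientEvidenceError(
            "mechanism classification requires at least two proton profiles"
        )

    floor = _pooled_noise_floor(profiles, thr)
    floors = [floor] * len(profiles)
    log_step = _grid_log_step(profiles[0].fields)

    strong = thr.feature_factor * floor

    # --- mid-field (J window) features ---
    peaks = []  # (field, signed value) per qualifying proton
    for p, f in zip(profiles, floors):
        ext = _window_extremum(p, thr, floor=f)
        if ext is not None and abs(ext[1]) >= strong:
            peaks.append(ext)
    if peaks:
        k = int(np.argmax([abs(v) for _, v in peaks]))
        peak_field, peak_value = peaks[k]
        # the anticrossing field is a molecular property: only peaks at a
        # consistent field (within 1.5 grid steps of the strongest) count
        peaks = [
            (b, v) for b, v in peaks if abs(math.log(b / peak_field)) <= 1.5 * log_step
        ]
        signs = np.sign([v for _, v in peaks])
        n_modal = max(np.sum(signs == +1), np.sum(signs == -1))
        sign_uniformity = float(n_modal) / len(peaks)
    else:
        sign_uniformity = 0.0
        peak_field, peak_value = None, 0.0

    # --- high-field response (delta-g regime) ---
    # a proton responds at high field only when the response is sustained:
    # the strongest point reaches feature_factor * floor and a second
    # point confirms it; the reported response is the second-largest
    # |intensity| so that one noise excursion cannot dominate the ratio
    hf_vals = []  # signed sustained response per proton
    for p, f in zip(profiles, floors):
        mask = p.fields >= thr.highfield_min
        if not mask.any():
            continue
        vals = p.intensities[mask]
        absv = np.abs(vals)
        if absv.max() < strong or np.sum(absv >= f) < 2:
            continue
        second = float(np.sort(absv)[-2])
        hf_vals.append(math.copysign(second, vals[np.argmax(absv)]))
    hf_max = max((abs(v) for v in hf_vals), default=0.0)

    if abs(peak_value) > 0 and hf_max == 0.0:
        highfield_ratio = math.inf
    elif hf_max > 0:
        highfield_ratio = abs(peak_value) / hf_max
    else:
        highfield_ratio = 0.0

    # --- low-field (hyperfine regime) signals: same sustained-feature rule ---
    lf_signs = []
    for p, f in zip(profiles, floors):
        mask = p.fields <= thr.lowfield_max
        if not mask.any():
            continue
        vals = p.intensities[mask]
        absv = np.abs(vals)
        if absv.max() < strong or np.sum(absv >= f) < 2:
            continue
        lf_signs.append(np.sign(vals[np.argmax(absv)]))

    # --- decision ---
    if (
        len(peaks) >= 2
        and sign_uniformity >= thr.sign_uniformity
        and highfield_ratio >= thr.highfield_ratio
    ):
        return MechanismCall(
            MechanismLabel.J_BIRADICAL,
            peak_field,
            sign_uniformity,
            highfield_ratio,
            f"{len(peaks)} protons with uniform-sign extremum at "
            f"{peak_field * 1e3:.1f} mT; high-field response "
            f"{'absent' if not math.isfinite(highfield_ratio) else f'{highfield_ratio:.1f}x weaker'}",
        )
    if (
        len(hf_vals) >= 2
        and len(set(np.sign(hf_vals))) > 1
        and abs(peak_value) < thr.dg_midfield_veto_ratio * hf_max
    ):
        return MechanismCall(
            MechanismLabel.DG_INTERMOLECULAR,
            None,
            sign_uniformity,
            highfield_ratio,
            f"{len(hf_vals)} protons respond above {thr.highfield_min} T with "
            "mixed signs and no comparable mid-field feature",
        )
    if len(lf_signs) >= 2 and len(set(lf_signs)) > 1:
        return MechanismCall(
            MechanismLabel.LOWFIELD_HFC,
            None,
            sign_uniformity,
            highfield_ratio,
            f"nucleus-specific signs below {thr.lowfield_max * 1e3:.0f} mT "
            "with no exchange or delta-g signature",
        )
    return MechanismCall(
        MechanismLabel.NONE,
        None,
        sign_uniformity,
        highfield_ratio,
        "no significant mechanism signature above the noise floor",
    )


class MechanismClassifier:
    """Scikit-learn style facade over :func:`classify_mechanism`.

    A rule-based classifier: ``fit`` is a no-op provided for pipeline
    compatibility, ``predict`` maps each profile set to a mechanism label
    string.  Threshold constants are estimator parameters, so the classifier
    composes with ``sklearn.model_selection`` utilities when needed.
    """

    def __init__(self, **threshold_kwargs):
        self.threshold_kwargs = threshold_kwargs

    def get_params(self, deep=True):
        return dict(self.threshold_kwargs)

    def set_params(self, **params):
        self.threshold_kwargs.update(params)
        return self

    def fit(self, X=None, y=None):
        self.thresholds_ = ClassifierThresholds(**self.threshold_kwargs)
        return self

    def predict(self, profile_sets):
        if not hasattr(self, "thresholds_"):
            self.fit()
        return [
            classify_mechanism(ps, self.thresholds_).label.value
            for ps in profile_sets
        ]

    def decision_calls(self, profile_sets):
        """Full :class:`MechanismCall` evidence per profile set."""
        if not hasattr(self, "thresholds_"):
            self.fit()
        return [classify_mechanism(ps, self.thresholds_) for ps in profile_sets]
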