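"""Cyclic-photoreaction model for time-resolved CIDNP kinetics.

After a laser flash creates a triplet precursor, bimolecular quenching
yields pairs of radicals (concentration R of each kind) that disappear by
second-order cross-termination:

    dR/dt = -k_t R^2          =>   R(t) = R0 / (1 + k_t R0 t)

Nuclear polarization is tracked in two pools: P_R in the surviving
radicals and P in diamagnetic recombination products,

    dP_R/dt = -k_t P_R R - k_t beta R^2 - P_R / T1
    dP/dt   = +k_t P_R R + k_t beta R^2

where T1 is the nuclear paramagnetic relaxation time in the radical and
beta = gamma * P_G / R0 is the polarization created per random-encounter
(F-pair) recombination, expressed through the geminate polarization P_G
and the F-pair-to-geminate ratio gamma (3 for an ideal triplet precursor;
2.8 accounts for incomplete reversibility of the photoreaction).

In this relative formulation everything depends on the products
``kt_R0 = k_t * R0`` and ``gamma * P_G`` only, which is also the maximal
parameter set identifiable from a CIDNP trace; absolute R0 is accepted
purely for simulating concentrations.

Two classic limits anchor the model (and the test suite).  Because the
F-pair term moves polarization from the radical pool into the products
while the recombination term returns the escaped anti-polarization, the
total P + P_R changes only through T1 relaxation.  Hence with T1 -> 0 the
escaped polarization dies before any recombination and
P(inf) = (1 + gamma) * P_G, while with T1 -> infinity everything returns
and cancels, P(inf) = P(0) + P_R(0) (zero for the default spin-sorting
initial conditions) -- the textbook statement that a fully reversible
cyclic reaction yields no net CIDNP without relaxation in the radicals.
The detected signal is therefore transient, with a maximum inside the
kinetic window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, IntegrationError, ValidationError

DEFAULT_GAMMA = 2.8

__all__ = [
    "KineticParameters",
    "KineticTrace",
    "PulseTiming",
    "radical_concentration",
    "integrate_polarization",
    "simulate_observed_kinetics",
    "polarization_at",
]


@dataclass(frozen=True)
class KineticParameters:
    """Parameters of the cyclic-photoreaction kinetic model.

    Parameters
    ----------
    kt_R0 : float
        Pseudo-first-order radical termination rate ``k_t * R0`` (1/s).
    T1 : float
        Nuclear paramagnetic relaxation time in the radical (s).
    P_G : float
        Geminate polarization amplitude (arbitrary polarization units).
    gamma : float
        Ratio of F-pair to geminate polarization, dimensionless, in [0, 3].
    scale : float
        Detector scaling factor applied to the product polarization.
    R0 : float, optional
        Initial radical concentration (mol/L); only used when absolute
        concentrations are simulated.  beta is never stored independently:
        ``beta * R0 == gamma * P_G`` by construction.
    """

    kt_R0: float
    T1: float
    P_G: float = 1.0
    gamma: float = DEFAULT_GAMMA
    scale: float = 1.0
    R0: float | None = None

    def __post_init__(self):
        for name in ("kt_R0", "T1"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")
        # scale = 0 is admitted as the degenerate "detector off" simulation
        # limit; fitting rejects all-zero traces separately.
        if not (np.isfinite(self.scale) and self.scale >= 0):
            raise ValidationError(f"scale must be finite and >= 0, got {self.scale!r}")
        if not np.isfinite(self.P_G):
            raise ValidationError("P_G must be finite")
        if not (0 <= self.gamma <= 3):
            raise ValidationError(f"gamma must lie in [0, 3], got {self.gamma!r}")
        if self.R0 is not None and not (np.isfinite(self.R0) and self.R0 > 0):
            raise ValidationError("R0, when given, must be finite and > 0")

    @property
    def beta_R0(self) -> float:
        """The product ``beta * R0 = gamma * P_G``."""
        return self.gamma * self.P_G


@dataclass(frozen=True)
class PulseTiming:
    """Detection RF pulse; the effective observation time of a spectrum is
    the delay plus half the pulse duration (pulse center)."""

    rf_pulse_duration: float

    def __post_init__(self):
        if not (np.isfinite(self.rf_pulse_duration) and self.rf_pulse_duration >= 0):
            raise ValidationError("rf_pulse_duration must be finite and >= 0")

    @property
    def effective_offset(self) -> float:
        return self.rf_pulse_duration / 2.0


@dataclass
class KineticTrace:
    """CIDNP intensity of one proton at a set of post-flash delays."""

    proton_label: str
    times: np.ndarray          # seconds, strictly ascending, >= 0
    intensities: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.size < 3:
            raise ValidationError("a kinetic trace needs >= 3 time points")
        if self.times.shape != self.intensities.shape:
            raise ValidationError("times and intensities must have equal length")
        if np.any(self.times < 0):
            raise ValidationError("times must be >= 0 (time zero = laser flash)")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.times.shape:
                raise ValidationError("sigma must have the same length as times")
            if np.any(self.sigma < 0):
                raise ValidationError("sigma must be >= 0")


def radical_concentration(params: KineticParameters, t) -> np.ndarray | float:
    """Relative radical concentration R(t)/R0 = 1 / (1 + kt_R0 * t).

    Multiplied by ``params.R0`` when absolute concentrations were requested.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("t must be >= 0")
    rel = 1.0 / (1.0 + params.kt_R0 * t_arr)
    if params.R0 is not None:
        rel = rel * params.R0
    return float(rel) if np.isscalar(t) or t_arr.ndim == 0 else rel


def default_initial_conditions(params: KineticParameters) -> tuple[float, float]:
    """Spin-sorting initial conditions at the end of the geminate stage:
    products carry +P_G, escaped radicals the anti-phase -P_G."""
    return (-params.P_G, params.P_G)


def integrate_polarization(
    params: KineticParameters,
    t_grid,
    initial_conditions: tuple[float, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the coupled polarization ODEs on an ascending time grid.

    Parameters
    ----------
    initial_conditions : (P_R(0), P(0))
        Defaults to the spin-sorting convention (-P_G, +P_G).

    Returns
    -------
    (P_R, P) : arrays on ``t_grid``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValidationError("t_grid must be a 1-D array")
    if t_grid[0] != 0.0:
        raise ValidationError("t_grid must start at 0 (the laser flash)")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValidationError("t_grid must be strictly ascending")

    pr0, p0 = (
        default_initial_conditions(params)
        if initial_conditions is None
        else (float(initial_conditions[0]), float(initial_conditions[1]))
    )
    if not (np.isfinite(pr0) and np.isfinite(p0)):
        raise ValidationError("initial conditions must be finite")

    K = params.kt_R0
    gPG = params.gamma * params.P_G
    invT1 = 1.0 / params.T1

    def rhs(t, y):
        r = 1.0 / (1.0 + K * t)
        src = K * gPG * r * r
        return (-K * r * y[0] - src - invT1 * y[0], K * r * y[0] + src)

    if t_grid.size == 1:  # only t = 0 requested
        return np.array([pr0]), np.array([p0])

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        [pr0, p0],
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"polarization ODE integration failed (kt_R0={K:g}, T1={params.T1:g}, "
            f"gamma={params.gamma:g}, P_G={params.P_G:g}): {sol.message}"
        )
    return sol.y[0], sol.y[1]


def polarization_at(
    params: KineticParameters,
    times,
    initial_conditions: tuple[float, float] | None = None,
    **integrate_kwargs,
) -> np.ndarray:
    """Product polarization P at arbitrary non-negative times (not
    necessarily including zero); convenience wrapper over
    :func:`integrate_polarization`."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise DomainError("times must be >= 0")
    grid = np.unique(np.concatenate([[0.0], times]))
    _, P = integrate_polarization(params, grid, initial_conditions, **integrate_kwargs)
    return np.interp(times, grid, P)


def simulate_observed_kinetics(
    params: KineticParameters,
    delays,
    pulse: PulseTiming,
    proton_label: str = "sim",
    initial_conditions: tuple[float, float] | None = None,
) -> KineticTrace:
    """Noise-free observable trace: scale * P(delay + pulse-center offset).

    The spectrometer integrates during the detection pulse; to first order
    the spectrum reports the polarization at the pulse center, so each
    nominal delay tau is evaluated at tau + duration/2.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValidationError("delays must be non-empty")
    if np.any(delays < 0):
        raise ValidationError("delays must be >= 0")
    eff = delays + pulse.effective_offset
    P = polarization_at(params, eff, initial_conditions)
    return KineticTrace(
        proton_label=proton_label,
        times=delays,
        intensities=params.scale * P,
    )
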