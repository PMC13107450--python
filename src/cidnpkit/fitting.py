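"""Least-squares fitting of the cyclic-photoreaction model to CIDNP traces.

Supports single-trace fits and global (shared-parameter) fits across any
number of traces: the termination rate ``kt_R0`` is typically shared by
all traces of one sample, nuclear relaxation times ``T1`` are per proton
or shared within declared groups, and every trace carries its own
detector scale.  Scales enter the model linearly and are therefore
profiled out exactly (variable projection), which shrinks the nonlinear
search space and removes its flattest directions.

Because three-point traces barely over-determine the remaining
parameters, the optimizer works hard for the *global* optimum: seeded
log-uniform multi-start over the bounded box, very tight convergence
tolerances, and a fast exact-per-step model evaluator
(:mod:`cidnpkit._fastmodel`).  The companion
:func:`profile_identifiability` makes the resulting (non-)identifiability
visible: it reports the residual norm as one parameter is pinned along a
grid, which is flat over wide ranges precisely when a relaxation time
exceeds the kinetic window of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from ._fastmodel import polarization_batch
from .errors import DegenerateDataError, UnderDeterminedError, ValidationError
from .kinetics import DEFAULT_GAMMA, KineticTrace, PulseTiming

__all__ = [
    "FitSpec",
    "FitResult",
    "CidnpKineticsFitter",
    "fit_kinetics",
    "profile_identifiability",
]

_DEFAULT_BOUNDS = {
    # kt_R0: diffusion-limited termination (~1e9-1e10 /M/s) at 1e-6..1e-3 M
    # radical concentrations spans ~1e3..1e7 1/s.
    "kt_R0": (1e3, 1e7),
    # nuclear paramagnetic relaxation times of protons in organic radicals
    # fall between fractions of a microsecond and about a millisecond.
    "T1": (1e-7, 1e-3),
    "scale": (1e-2, 1e2),
    "P_G": (1e-2, 1e2),
}


@dataclass(frozen=True)
class FitSpec:
    """Configuration of a (global) kinetic fit.

    Parameters
    ----------
    free_parameters : subset of {"kt_R0", "T1", "scale", "P_G"}
        ``scale`` and ``P_G`` are degenerate (both multiply the curve);
        only one of them may be freed.
    gamma : float
        F-pair-to-geminate polarization ratio; fixed (2.8 by default).
    fixed : mapping
        Values for non-free parameters (defaults: P_G = 1, scale = 1).
    bounds : mapping
        Per-parameter positive (lo, hi) intervals; applied to every
        instance of that parameter.
    shared : mapping
        Sharing declaration per parameter: ``"shared"`` (one value for all
        traces), ``"per_trace"``, or a sequence of group keys (one per
        trace; equal keys share one value).  Default: kt_R0 shared, T1 and
        scale per trace.
    n_starts : int
        Number of random log-uniform multi-start points (a deterministic
        mid-box start is always added).
    seed : int
        Seed of the multi-start generator; fits are deterministic given it.
    """

    free_parameters: tuple[str, ...] = ("kt_R0", "T1", "scale")
    gamma: float = DEFAULT_GAMMA
    fixed: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    shared: Mapping[str, object] = field(default_factory=dict)
    n_starts: int = 8
    seed: int = 0

    def __post_init__(self):
        allowed = {"kt_R0", "T1", "scale", "P_G"}
        bad = set(self.free_parameters) - allowed
        if bad:
            raise ValidationError(f"unknown free parameters {sorted(bad)}")
        if "scale" in self.free_parameters and "P_G" in self.free_parameters:
            raise ValidationError(
                "scale and P_G are degenerate; free only one of them"
            )
        if not (0 <= self.gamma <= 3):
            raise ValidationError("gamma must lie in [0, 3]")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi < np.inf):
                raise ValidationError(
                    f"bounds for {name!r} must be a finite positive interval"
                )
        if self.n_starts < 0:
            raise ValidationError("n_starts must be >= 0")

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, _DEFAULT_BOUNDS[name])

    def sharing(self, name: str, n_traces: int, labels: Sequence[str]) -> list:
        """Group key per trace for parameter ``name``."""
        default = "shared" if name == "kt_R0" else "per_trace"
        spec = self.shared.get(name, default)
        if spec == "shared":
            return [name] * n_traces
        if spec == "per_trace":
            return [f"{name}[{lab}]" for lab in labels]
        keys = list(spec)
        if len(keys) != n_traces:
            raise ValidationError(
                f"sharing map for {name!r} lists {len(keys)} keys for {n_traces} traces"
            )
        return [f"{name}[{k}]" for k in keys]


@dataclass
class FitResult:
    """Outcome of :func:`fit_kinetics`."""

    estimates: dict[str, float]
    stderr: dict[str, float]
    residual_norm: float
    n_points: int
    n_free: int
    converged: bool
    start_points_used: int

    def __getitem__(self, key: str) -> float:
        return self.estimates[key]


class _Layout:
    """Maps traces onto shared parameter instances and model batches."""

    def __init__(self, traces, pulse, spec):
        self.traces = traces
        self.spec = spec
        labels = []
        seen = {}
        for tr in traces:
            lab = tr.proton_label
            seen[lab] = seen.get(lab, 0) + 1
            labels.append(lab if seen[lab] == 1 else f"{lab}#{seen[lab]}")
        self.labels = labels
        n = len(traces)

        def instances(name):
            keys = spec.sharing(name, n, labels)
            uniq = list(dict.fromkeys(keys))
            return uniq, np.array([uniq.index(k) for k in keys])

        self.k_names, self.k_of_trace = instances("kt_R0")
        self.t1_names, self.t1_of_trace = instances("T1")
        amp = "P_G" if "P_G" in spec.free_parameters else "scale"
        self.amp_param = amp
        self.amp_names, self.amp_of_trace = instances(amp)

        self.eff_times = [
            np.asarray(tr.times, float) + pulse.effective_offset for tr in traces
        ]
        self.y = [np.asarray(tr.intensities, float) for tr in traces]
        if all(tr.sigma is not None for tr in traces):
            self.w = [1.0 / np.where(tr.sigma > 0, tr.sigma, np.inf) for tr in traces]
        else:
            self.w = [np.ones_like(yy) for yy in self.y]

        # batches: traces sharing (kt_R0 instance, time grid) evaluate
        # together, each distinct T1 instance integrated once
        groups = {}
        for i in range(n):
            key = (self.k_of_trace[i], tuple(self.eff_times[i]))
            groups.setdefault(key, []).append(i)
        self.batches = []
        for (kidx, times), idxs in groups.items():
            t1_idx = np.array([self.t1_of_trace[i] for i in idxs])
            uniq, inverse = np.unique(t1_idx, return_inverse=True)
            self.batches.append((kidx, np.asarray(times), idxs, uniq, inverse))

    def curves(self, k_values, t1_values, n_per_decade=40):
        """Model polarization curve per trace (unit amplitude)."""
        out = [None] * len(self.traces)
        amp_is_pg = self.amp_param == "P_G"
        for kidx, times, idxs, uniq, inverse in self.batches:
            _, P = polarization_batch(
                k_values[kidx],
                t1_values[uniq],
                times,
                gamma=self.spec.gamma,
                P_G=1.0,
                n_per_decade=n_per_decade,
            )
            for row, i in zip(inverse, idxs):
                out[i] = P[row]
        if not amp_is_pg:
            # amplitude parameter is the detector scale; P_G enters fixed
            pg = float(self.spec.fixed.get("P_G", 1.0))
            out = [c * pg for c in out]
        return out


def _profiled_amplitudes(layout, curves):
    """Exact least-squares amplitude per sharing group (variable projection)."""
    n_amp = len(layout.amp_names)
    num = np.zeros(n_amp)
    den = np.zeros(n_amp)
    for i, c in enumerate(curves):
        g = layout.amp_of_trace[i]
        w2 = layout.w[i] ** 2
        num[g] += float(np.sum(w2 * layout.y[i] * c))
        den[g] += float(np.sum(w2 * c * c))
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(den > 0, num / den, 0.0)
    return amp


def fit_kinetics(
    traces: KineticTrace | Sequence[KineticTrace],
    pulse: PulseTiming,
    spec: FitSpec | None = None,
) -> FitResult:
    """Bounded least-squares fit of the kinetic model to one or more traces.

    Returns the joint optimum over all traces under the sharing
    declarations of ``spec``; deterministic given ``spec.seed``.
    """
    fitter = CidnpKineticsFitter(pulse=pulse, spec=spec or FitSpec())
    fitter.fit(traces)
    return fitter.result_


class CidnpKineticsFitter(BaseEstimator):
    """Scikit-learn style estimator around the global kinetic fit.

    Parameters are a :class:`PulseTiming` and a :class:`FitSpec`; ``fit``
    accepts one trace or a sequence of traces.  Fitted attributes:

    ``result_`` : the full :class:`FitResult`;
    ``estimates_``, ``stderr_`` : dicts keyed by parameter instance name;
    ``residual_norm_`` : float.
    """

    def __init__(self, pulse: PulseTiming | None = None, spec: FitSpec | None = None):
        self.pulse = pulse
        self.spec = spec

    # -- internal ----------------------------------------------------------
    def _resid_factory(self, layout, free_k, free_t1, fixed_k, fixed_t1):
        nk = len(layout.k_names)
        nt1 = len(layout.t1_names)
        amp_free = layout.amp_param in (self.spec or FitSpec()).free_parameters

        def split(x):
            kv = np.array(fixed_k, float)
            tv = np.array(fixed_t1, float)
            j = 0
            for i in range(nk):
                if free_k[i]:
                    kv[i] = 10.0 ** x[j]
                    j += 1
            for i in range(nt1):
                if free_t1[i]:
                    tv[i] = 10.0 ** x[j]
                    j += 1
            return kv, tv

        def resid(x):
            kv, tv = split(x)
            curves = layout.curves(kv, tv)
            if amp_free:
                amp = _profiled_amplitudes(layout, curves)
            else:
                spec = self.spec or FitSpec()
                amp = np.full(
                    len(layout.amp_names),
                    float(spec.fixed.get(layout.amp_param, 1.0)),
                )
            res = [
                layout.w[i] * (layout.y[i] - amp[layout.amp_of_trace[i]] * c)
                for i, c in enumerate(curves)
            ]
            return np.concatenate(res)

        return resid, split

    def fit(self, traces, y=None):
        spec = self.spec or FitSpec()
        pulse = self.pulse or PulseTiming(0.0)
        if isinstance(traces, KineticTrace):
            traces = [traces]
        traces = list(traces)
        if not traces:
            raise ValidationError("fit requires at least one trace")
        for tr in traces:
            if not np.any(np.asarray(tr.intensities) != 0):
                raise DegenerateDataError(
                    f"trace {tr.proton_label!r} is identically zero; "
                    "its amplitude cannot be determined"
                )

        layout = _Layout(traces, pulse, spec)

        free_k = [("kt_R0" in spec.free_parameters)] * len(layout.k_names)
        free_t1 = [("T1" in spec.free_parameters)] * len(layout.t1_names)
        fixed_k = [float(spec.fixed.get("kt_R0", 1e5))] * len(layout.k_names)
        fixed_t1 = [float(spec.fixed.get("T1", 1e-4))] * len(layout.t1_names)
        amp_free = layout.amp_param in spec.free_parameters

        n_free = sum(free_k) + sum(free_t1) + (len(layout.amp_names) if amp_free else 0)
        n_points = sum(yy.size for yy in layout.y)
        if n_points < n_free:
            raise UnderDeterminedError(
                f"{n_points} data points cannot determine {n_free} free parameters"
            )

        resid, split = self._resid_factory(layout, free_k, free_t1, fixed_k, fixed_t1)

        lo, hi = [], []
        for i, f in enumerate(free_k):
            if f:
                b = spec.bound("kt_R0")
                lo.append(np.log10(b[0]))
                hi.append(np.log10(b[1]))
        for i, f in enumerate(free_t1):
            if f:
                b = spec.bound("T1")
                lo.append(np.log10(b[0]))
                hi.append(np.log10(b[1]))
        lo = np.array(lo)
        hi = np.array(hi)

        ynorm = sum(float(np.sum((layout.w[i] * layout.y[i]) ** 2)) for i in range(len(traces)))
        rng = np.random.default_rng(spec.seed)
        best = None
        used = 0
        if lo.size == 0:
            # purely linear problem: profiled amplitudes are the exact optimum
            r = resid(np.empty(0))
            cost = 0.5 * float(np.sum(r**2))

            class _Lin:  # minimal result shim
                x = np.empty(0)
                success = True

            best = _Lin()
            best.cost = cost
            used = 1
        else:
            starts = [0.5 * (lo + hi)] + [rng.uniform(lo, hi) for _ in range(spec.n_starts)]
            for x0 in starts:
                res = least_squares(
                    resid,
                    x0,
                    bounds=(lo, hi),
                    xtol=1e-12,
                    ftol=1e-14,
                    gtol=1e-14,
                    diff_step=1e-6,
                    max_nfev=250,
                )
                used += 1
                if best is None or res.cost < best.cost:
                    best = res
                if best.cost < 1e-16 * ynorm:
                    break

        kv, tv = split(best.x)
        curves = layout.curves(kv, tv)
        if amp_free:
            amp = _profiled_amplitudes(layout, curves)
        else:
            amp = np.full(
                len(layout.amp_names), float(spec.fixed.get(layout.amp_param, 1.0))
            )

        estimates: dict[str, float] = {}
        for name, v, f in zip(layout.k_names, kv, free_k):
            if f:
                estimates[name] = float(v)
        for name, v, f in zip(layout.t1_names, tv, free_t1):
            if f:
                estimates[name] = float(v)
        if amp_free:
            for name, v in zip(layout.amp_names, amp):
                estimates[name] = float(v)

        residual_norm = 2.0 * float(best.cost)
        stderr = self._stderr(layout, kv, tv, amp, free_k, free_t1, amp_free,
                              n_points, n_free, residual_norm)

        self.result_ = FitResult(
            estimates=estimates,
            stderr=stderr,
            residual_norm=residual_norm,
            n_points=n_points,
            n_free=n_free,
            converged=bool(getattr(best, "success", True)),
            start_points_used=used,
        )
        self.estimates_ = estimates
        self.stderr_ = stderr
        self.residual_norm_ = residual_norm
        self._layout = layout
        self._kv, self._tv, self._amp = kv, tv, amp
        return self

    def _stderr(self, layout, kv, tv, amp, free_k, free_t1, amp_free,
                n_points, n_free, residual_norm):
        """Asymptotic standard errors from a numeric Jacobian over all free
        parameters (including profiled amplitudes) in natural-log space."""
        names, values = [], []
        for name, v, f in zip(layout.k_names, kv, free_k):
            if f:
                names.append(name)
                values.append(v)
        for name, v, f in zip(layout.t1_names, tv, free_t1):
            if f:
                names.append(name)
                values.append(v)
        if amp_free:
            for name, v in zip(layout.amp_names, amp):
                names.append(name)
                values.append(v)
        if not names:
            return {}
        values = np.array(values, float)
        if np.any(values == 0):  # degenerate amplitude: no sensible log step
            return {n: float("nan") for n in names}

        def full_resid(theta):
            kvv = np.array(kv, float)
            tvv = np.array(tv, float)
            av = np.array(amp, float)
            j = 0
            for i, f in enumerate(free_k):
                if f:
                    kvv[i] = theta[j]
                    j += 1
            for i, f in enumerate(free_t1):
                if f:
                    tvv[i] = theta[j]
                    j += 1
            if amp_free:
                for i in range(len(av)):
                    av[i] = theta[j]
                    j += 1
            curves = layout.curves(kvv, tvv)
            return np.concatenate(
                [
                    layout.w[i] * (layout.y[i] - av[layout.amp_of_trace[i]] * c)
                    for i, c in enumerate(curves)
                ]
            )

        base = full_resid(values)
        J = np.empty((base.size, values.size))
        for j in range(values.size):
            step = 1e-6 * abs(values[j])
            up = values.copy()
            dn = values.copy()
            up[j] += step
            dn[j] -= step
            J[:, j] = (full_resid(up) - full_resid(dn)) / (2 * step)
        dof = max(n_points - n_free, 1)
        s2 = residual_norm / dof
        try:
            cov = s2 * np.linalg.pinv(J.T @ J)
            sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            sd = np.full(values.size, np.nan)
        return {n: float(s) for n, s in zip(names, sd)}

    def predict(self, delays, trace_index: int = 0):
        """Fitted model curve of one trace at new delays."""
        if not hasattr(self, "result_"):
            raise ValidationError("fitter is not fitted yet")
        layout = self._layout
        pulse = self.pulse or PulseTiming(0.0)
        delays = np.asarray(delays, float)
        times = delays + pulse.effective_offset
        order = np.argsort(times)
        _, P = polarization_batch(
            self._kv[layout.k_of_trace[trace_index]],
            [self._tv[layout.t1_of_trace[trace_index]]],
            times[order],
            gamma=(self.spec or FitSpec()).gamma,
            P_G=1.0,
        )
        out = np.empty_like(times)
        out[order] = P[0]
        return self._amp[layout.amp_of_trace[trace_index]] * out


def profile_identifiability(
    traces,
    pulse: PulseTiming,
    spec: FitSpec,
    parameter: str,
    grid,
) -> pd.DataFrame:
    """Profile the residual norm along a grid of pinned parameter values.

    For every grid value the named parameter ("kt_R0" or "T1"; applied to
    all its instances) is fixed and the remaining free parameters refit.
    A profile that stays flat over a wide range exposes an unidentifiable
    parameter; an identifiable one shows a clear minimum at the optimum.
    """
    if parameter not in ("kt_R0", "T1"):
        raise ValidationError("profile parameter must be 'kt_R0' or 'T1'")
    grid = np.asarray(grid, float)
    rows = []
    for v in grid:
        lo, hi = spec.bound(parameter)
        if not (lo <= v <= hi):
            raise ValidationError(
                f"profile value {v:g} outside bounds [{lo:g}, {hi:g}] of {parameter!r}"
            )
        sub = replace(
            spec,
            free_parameters=tuple(p for p in spec.free_parameters if p != parameter),
            fixed={**dict(spec.fixed), parameter: float(v)},
        )
        res = fit_kinetics(traces, pulse, sub)
        rows.append(
            {"value": float(v), "residual_norm": res.residual_norm, "converged": res.converged}
        )
    return pd.DataFrame(rows, columns=["value", "residual_norm", "converged"])
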