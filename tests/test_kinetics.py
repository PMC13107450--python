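"""Cyclic-photoreaction kinetic model: closed forms, limits, observables."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cidnpkit.errors import DomainError, ValidationError
from cidnpkit.kinetics import (
    KineticParameters,
    KineticTrace,
    PulseTiming,
    integrate_polarization,
    polarization_at,
    radical_concentration,
    simulate_observed_kinetics,
)
from cidnpkit._fastmodel import polarization_batch


class TestRadicalConcentration:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.0, 1.0), (10e-6, 0.5), (30e-6, 0.25)],
    )
    def test_closed_form_values(self, t, expected):
        p = KineticParameters(kt_R0=1e5, T1=1e-4)
        assert radical_concentration(p, t) == pytest.approx(expected)

    def test_negative_time_rejected(self, params):
        with pytest.raises(DomainError):
            radical_concentration(params, -1e-9)

    def test_monotone_nonincreasing_and_bounded(self, params):
        t = np.linspace(0, 1e-3, 300)
        r = radical_concentration(params, t)
        assert np.all(np.diff(r) <= 0)
        assert np.all((r > 0) & (r <= 1))

    def test_matches_numerical_integration_of_rate_law(self, params):
        """dR/dt = -kt R^2 integrated numerically reproduces the closed form
        to 1e-8 relative on [0, 1 ms]."""
        t = np.linspace(0, 1e-3, 50)
        sol = solve_ivp(
            lambda _, y: [-params.kt_R0 * y[0] ** 2],
            (0, 1e-3),
            [1.0],
            t_eval=t,
            rtol=1e-11,
            atol=1e-14,
            method="LSODA",
        )
        closed = radical_concentration(params, t)
        assert np.max(np.abs(sol.y[0] - closed) / closed) < 1e-8

    def test_absolute_concentration_scaling(self):
        p = KineticParameters(kt_R0=1e5, T1=1e-4, R0=2e-4)
        assert radical_concentration(p, 0.0) == pytest.approx(2e-4)


class TestPolarizationODEs:
    def test_no_recombination_limit_decouples(self):
        """With a negligible termination rate the product pool freezes and
        the radical polarization decays as exp(-t/T1)."""
        p = KineticParameters(kt_R0=1e-6, T1=50e-6)
        t = np.linspace(0, 200e-6, 30)
        PR, P = integrate_polarization(p, t)
        assert np.allclose(P, p.P_G, rtol=1e-6)
        assert np.allclose(PR, -p.P_G * np.exp(-t / p.T1), rtol=1e-6, atol=1e-9)

    def test_total_polarization_conserved_without_relaxation(self):
        """The F-pair term moves polarization between pools and the
        recombination term returns it, so P + P_R changes only through T1."""
        p = KineticParameters(kt_R0=1e5, T1=1e9)
        t = np.linspace(0, 1e-3, 50)
        PR, P = integrate_polarization(p, t, rtol=1e-10, atol=1e-14)
        assert np.allclose(P + PR, 0.0, atol=1e-7)

    def test_fast_relaxation_limit(self):
        """T1 -> 0: escaped anti-polarization dies before recombination and
        the product pool ends at (1 + gamma) * P_G."""
        p = KineticParameters(kt_R0=1e5, T1=1e-9)
        P = polarization_at(p, [1.0], rtol=1e-10, atol=1e-14)
        assert P[0] == pytest.approx((1 + p.gamma) * p.P_G, rel=1e-4)

    def test_slow_relaxation_limit_cancels(self):
        """T1 -> infinity: every escaped spin returns and cancels; the
        asymptotic product polarization is P(0) + P_R(0)."""
        p = KineticParameters(kt_R0=1e5, T1=1e9)
        # analytic solution of the relaxation-free system:
        # P(t) = (P_G + gamma P_G ln u) / u with u = 1 + kt_R0 t
        t = np.array([1e-4, 1e-2, 1.0])
        P = polarization_at(p, t, rtol=1e-10, atol=1e-14)
        u = 1 + p.kt_R0 * t
        expect = (p.P_G + p.gamma * p.P_G * np.log(u)) / u
        assert np.allclose(P, expect, rtol=1e-5)
        assert abs(P[-1]) < 5e-4  # -> P(0) + P_R(0) = 0

    def test_longer_T1_decreases_final_polarization(self):
        """Nuclear relaxation in the radicals is what rescues net CIDNP in a
        cyclic reaction: the escaped anti-polarization (and the F-pair
        anti-polarization accumulating in the radical pool) can only return
        and cancel if it survives.  Hence the asymptotic product
        polarization decreases monotonically with T1, from (1 + gamma) P_G
        down to zero."""
        finals = []
        for T1 in [1e-8, 1e-6, 1e-5, 1e-4, 1e-3, 1e-1]:
            p = KineticParameters(kt_R0=1e5, T1=T1)
            finals.append(polarization_at(p, [1.0], rtol=1e-9, atol=1e-13)[0])
        assert np.all(np.diff(finals) < 0)
        assert finals[0] < (1 + 2.8) * 1.0 + 1e-3
        assert finals[-1] > -1e-3

    def test_grid_validation(self, params):
        with pytest.raises(ValidationError):
            integrate_polarization(params, [1e-6, 2e-6])  # does not start at 0
        with pytest.raises(ValidationError):
            integrate_polarization(params, [0.0, 2e-6, 1e-6])
        with pytest.raises(ValidationError):
            integrate_polarization(params, [0.0, 1e-6], initial_conditions=(np.nan, 0.0))


class TestFastModel:
    @pytest.mark.parametrize("kt_R0", [1e3, 1e5, 4.2e5])
    @pytest.mark.parametrize("T1", [1e-6, 2.9e-5, 1.2e-4, 5e-4])
    def test_matches_reference_integrator(self, kt_R0, T1):
        """The exponential-integrator fast path agrees with the adaptive
        reference integration to a few parts in 1e4."""
        p = KineticParameters(kt_R0=kt_R0, T1=T1)
        times = np.array([2e-6, 5e-6, 5e-5, 1.02e-4])
        ref = polarization_at(p, times, rtol=1e-11, atol=1e-14)
        _, P = polarization_batch(kt_R0, [T1], times)
        assert np.allclose(P[0], ref, rtol=3e-4)


class TestObservedKinetics:
    def test_pulse_center_offsets(self, params):
        """A 4 us detection pulse shifts the effective times to delay + 2 us."""
        pulse = PulseTiming(4e-6)
        assert pulse.effective_offset == 2e-6
        delays = np.array([0.0, 3e-6, 100e-6])
        tr = simulate_observed_kinetics(params, delays, pulse)
        expect = params.scale * polarization_at(params, delays + 2e-6)
        assert np.allclose(tr.intensities, expect, rtol=1e-9)

    def test_zero_scale_gives_zero_trace(self):
        p = KineticParameters(kt_R0=1e5, T1=1e-4, scale=0.0)
        tr = simulate_observed_kinetics(p, [0.0, 3e-6, 100e-6], PulseTiming(4e-6))
        assert np.all(tr.intensities == 0)

    def test_interior_maximum_in_kinetic_window(self):
        """Donor kinetics with slow relaxation rise to a distinct maximum
        inside 0-100 us before decaying."""
        p = KineticParameters(kt_R0=1e5, T1=500e-6)
        delays = np.linspace(0, 100e-6, 200)
        tr = simulate_observed_kinetics(p, delays, PulseTiming(4e-6))
        i = int(np.argmax(tr.intensities))
        assert 0 < i < delays.size - 1
        assert tr.intensities[i] > tr.intensities[0]
        assert tr.intensities[i] > tr.intensities[-1]

    def test_joint_rescaling_invariance(self, pulse):
        """P_G -> c P_G with scale -> scale/c leaves the observable fixed."""
        delays = np.array([0.0, 3e-6, 100e-6])
        a = KineticParameters(kt_R0=1e5, T1=1e-4, P_G=1.0, scale=2.0)
        b = KineticParameters(kt_R0=1e5, T1=1e-4, P_G=4.0, scale=0.5)
        ta = simulate_observed_kinetics(a, delays, pulse)
        tb = simulate_observed_kinetics(b, delays, pulse)
        assert np.allclose(ta.intensities, tb.intensities, rtol=1e-9)

    def test_empty_delays_rejected(self, params, pulse):
        with pytest.raises(ValidationError):
            simulate_observed_kinetics(params, [], pulse)


class TestDomainTypes:
    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            KineticParameters(kt_R0=-1.0, T1=1e-4)
        with pytest.raises(ValidationError):
            KineticParameters(kt_R0=1e5, T1=0.0)
        with pytest.raises(ValidationError):
            KineticParameters(kt_R0=1e5, T1=1e-4, gamma=3.5)

    def test_beta_relation_held_by_construction(self):
        p = KineticParameters(kt_R0=1e5, T1=1e-4, P_G=2.0, gamma=2.8)
        assert p.beta_R0 == pytest.approx(2.8 * 2.0)

    def test_trace_validation(self):
        with pytest.raises(ValidationError):
            KineticTrace("x", [0.0, 1e-6], [1.0, 2.0])  # too short
        with pytest.raises(ValidationError):
            KineticTrace("x", [0.0, 2e-6, 1e-6], [1, 2, 3])
        with pytest.raises(ValidationError):
            KineticTrace("x", [-1e-6, 0.0, 1e-6], [1, 2, 3])
        with pytest.raises(ValidationError):
            KineticTrace("x", [0.0, 1e-6, 2e-6], [1, 2, 3], sigma=[0.1, 0.1])
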