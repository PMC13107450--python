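"""Sign rules, LAC fields, regime taxonomy, normalization, classifier."""

import itertools
import math

import numpy as np
import pytest

from cidnpkit.errors import (
    InsufficientEvidenceError,
    NormalizationError,
    NotApplicableError,
    UnitError,
    ValidationError,
)
from cidnpkit.spin import (
    BOHR_MAGNETON,
    ClassifierThresholds,
    FieldProfile,
    FieldRegime,
    MechanismLabel,
    RadicalPairConfig,
    classify_field_regime,
    classify_mechanism,
    j_from_field,
    j_resonance_sign,
    kaptein_high_field_sign,
    lac_field,
    normalize_profiles,
)
from cidnpkit.synthetic import default_field_grid, gen_field_profiles


class TestSignRules:
    def test_kaptein_truth_table_exhaustive(self):
        """All 16 sign combinations equal the brute-force four-factor product."""
        for dg, a, mu, eps in itertools.product((-1, 1), repeat=4):
            cfg = RadicalPairConfig(dg, a, mu, eps)
            assert kaptein_high_field_sign(cfg) == dg * a * mu * eps

    def test_kaptein_reference_cases(self):
        assert kaptein_high_field_sign(RadicalPairConfig(+1, +1, +1, +1)) == +1
        assert kaptein_high_field_sign(RadicalPairConfig(+1, +1, -1, +1)) == -1

    def test_j_resonance_truth_table_exhaustive(self):
        """All 8 combinations equal sgn(J) * mu * eps, independent of sgn(a)."""
        for sj, mu, eps in itertools.product((-1, 1), repeat=3):
            for a in (-1, 1):  # must not matter
                cfg = RadicalPairConfig(+1, a, mu, eps, sgn_J=sj)
                assert j_resonance_sign(cfg) == sj * mu * eps

    def test_j_resonance_triplet_geminate_emissive(self):
        """Negative exchange, triplet precursor, geminate products: emissive."""
        cfg = RadicalPairConfig(+1, +1, mu=+1, eps=+1, sgn_J=-1)
        assert j_resonance_sign(cfg) == -1

    def test_j_resonance_requires_nonzero_J(self):
        with pytest.raises(NotApplicableError):
            j_resonance_sign(RadicalPairConfig(+1, +1, +1, +1, sgn_J=0))

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            RadicalPairConfig(0, 1, 1, 1)
        with pytest.raises(ValidationError):
            RadicalPairConfig(1, 1, 1, 1, sgn_J=2)


class TestLacField:
    def test_zero_exchange_zero_field(self):
        assert lac_field(0.0) == 0.0

    def test_inverse_identity_at_10_mT(self):
        J = 2.0023 * BOHR_MAGNETON * 10e-3
        assert lac_field(J, "J") == pytest.approx(10e-3, rel=1e-12)

    def test_roundtrip_both_units(self):
        for unit in ("J", "Hz"):
            B = 13e-3
            assert lac_field(j_from_field(B, unit), unit) == pytest.approx(B, rel=1e-12)

    def test_280MHz_maps_into_observed_window(self):
        """An exchange of |J|/h = 280.2 MHz anticrosses near 10 mT, inside
        the experimentally observed 5-20 mT window."""
        B = lac_field(280.2e6, "Hz", g=2.0023)
        assert B == pytest.approx(10.0e-3, rel=2e-3)
        assert 5e-3 <= B <= 20e-3

    def test_unknown_unit_rejected(self):
        with pytest.raises(UnitError):
            lac_field(1.0, "eV")


class TestFieldRegime:
    @pytest.mark.parametrize(
        "B, a_scale, J_field, expected",
        [
            (1e-3, 1e-3, 10e-3, FieldRegime.LOW_HFC),
            (10e-3, 1e-4, 10e-3, FieldRegime.INTERMEDIATE_J),
            (9.4, 1e-3, 10e-3, FieldRegime.HIGH_DG),
            (0.3, 1e-3, 10e-3, FieldRegime.GAP),
        ],
    )
    def test_banding(self, B, a_scale, J_field, expected):
        assert classify_field_regime(B, a_scale, J_field) == expected

    def test_positive_inputs_required(self):
        with pytest.raises(ValidationError):
            classify_field_regime(0.0, 1e-3, 1e-2)


def _profile(fields, intensities, label="p", conformer="unassigned"):
    return FieldProfile(label, np.asarray(fields), np.asarray(intensities), conformer)


class TestNormalization:
    def test_reference_becomes_minus_one(self):
        B = default_field_grid()
        I = np.full(B.size, -4.0)
        (out,) = normalize_profiles([_profile(B, I)], reference_field=10e-3)
        ref = np.interp(math.log(10e-3), np.log(B), out.intensities)
        assert ref == pytest.approx(-1.0)
        assert np.allclose(out.intensities, -1.0)

    def test_global_factor_removed(self):
        B = default_field_grid()
        rng = np.random.default_rng(0)
        I = rng.normal(size=B.size) + 2.0
        a, b = normalize_profiles(
            [_profile(B, I, "a"), _profile(B, 3.7 * I, "b")], reference_field=10e-3
        )
        assert np.allclose(a.intensities, b.intensities, rtol=1e-12)

    def test_idempotent(self):
        B = default_field_grid()
        rng = np.random.default_rng(1)
        I = rng.normal(size=B.size) + 1.0
        once = normalize_profiles([_profile(B, I)], 10e-3)
        twice = normalize_profiles(once, 10e-3)
        assert np.allclose(once[0].intensities, twice[0].intensities, rtol=1e-12)

    def test_log_interpolation_between_grid_points(self):
        """The reference intensity interpolates linearly in log(B)."""
        B = np.array([1e-3, 1e-2, 1e-1])
        I = np.array([1.0, 2.0, 3.0])
        ref_field = math.sqrt(1e-2 * 1e-1)  # halfway in log space
        (out,) = normalize_profiles([_profile(B, I)], ref_field)
        assert np.allclose(out.intensities, I / 2.5, rtol=1e-12)

    def test_degenerate_reference_rejected(self):
        B = default_field_grid()
        I = np.zeros(B.size)
        I[0] = 1.0
        with pytest.raises(NormalizationError):
            normalize_profiles([_profile(B, I)], 10e-3)

    def test_reference_outside_range_rejected(self):
        B = np.geomspace(0.1, 1.0, 10)
        with pytest.raises(ValidationError):
            normalize_profiles([_profile(B, np.ones(10))], 10e-3)


class TestMechanismClassifier:
    def test_biradical_set(self):
        """Uniform emissive mid-field peak, silent high field -> J biradical
        with the peak located within one grid step."""
        profiles, _ = gen_field_profiles(
            "J_BIRADICAL", ["F8p", "W6", "W2"], peak_field=13e-3, snr=10, seed=42
        )
        call = classify_mechanism(profiles)
        assert call.label == MechanismLabel.J_BIRADICAL
        step = math.log(profiles[0].fields[1] / profiles[0].fields[0])
        assert abs(math.log(call.peak_field / 13e-3)) <= step
        assert call.sign_uniformity == 1.0
        assert call.highfield_ratio >= 3

    def test_intermolecular_set(self):
        """Mixed-sign high-field onsets with no mid-field peak -> delta-g."""
        profiles, _ = gen_field_profiles(
            "DG_INTERMOLECULAR", ["F8p", "F7p", "W6"], signs=[1, -1, 1], snr=10, seed=43
        )
        call = classify_mechanism(profiles)
        assert call.label == MechanismLabel.DG_INTERMOLECULAR

    def test_lowfield_set(self):
        profiles, _ = gen_field_profiles(
            "LOWFIELD_HFC", ["F8p", "W6"], signs=[1, -1], snr=10, seed=44
        )
        call = classify_mechanism(profiles)
        assert call.label == MechanismLabel.LOWFIELD_HFC

    def test_flat_profiles_none(self):
        profiles, _ = gen_field_profiles("NONE", ["a", "b"], snr=10, seed=45)
        call = classify_mechanism(profiles)
        assert call.label == MechanismLabel.NONE

    def test_single_profile_insufficient(self):
        profiles, _ = gen_field_profiles("NONE", ["a"], seed=0)
        with pytest.raises(InsufficientEvidenceError):
            classify_mechanism(profiles)

    def test_evidence_fields_well_formed(self):
        profiles, _ = gen_field_profiles(
            "J_BIRADICAL", ["a", "b"], peak_field=13e-3, snr=20, seed=7
        )
        call = classify_mechanism(profiles)
        assert 0.0 <= call.sign_uniformity <= 1.0
        assert call.highfield_ratio >= 0
        assert call.evidence_notes


class TestFieldProfileType:
    def test_validation(self):
        with pytest.raises(ValidationError):
            _profile([1e-3, 1e-3], [1, 2])  # not strictly increasing
        with pytest.raises(ValidationError):
            _profile([-1e-3, 1e-3], [1, 2])
        with pytest.raises(ValidationError):
            FieldProfile("x", np.array([1e-3, 1e-2]), np.array([1.0]), "major")
        with pytest.raises(ValidationError):
            FieldProfile("x", np.array([1e-3, 1e-2]), np.array([1.0, 2.0]), "weird")
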