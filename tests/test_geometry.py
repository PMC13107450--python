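"""Geometric classifiers: dihedrals, stacking, hydrogen bonds, statistics."""

import numpy as np
import pytest

from cidnpkit.errors import DegenerateGeometryError, ValidationError
from cidnpkit.geometry import (
    ConformerLabel,
    GeometryCriteria,
    classify_cis_trans,
    ensemble_statistics,
    frame_has_hbond,
    interplane_angle,
    is_hbond,
    is_stacked,
    label_frame,
    moiety_center_distance,
    omega_dihedral,
    per_atom_energy_difference,
)
from cidnpkit.synthetic import gen_conformer_ensemble

from conftest import make_two_ring_frame


def random_rigid_transform(rng):
    """Uniform random rotation (QR of a Gaussian matrix) + translation."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.uniform(-20, 20, size=3)


class TestOmegaDihedral:
    @pytest.mark.parametrize("omega", [-150.0, -90.0, -10.0, 0.0, 10.0, 90.0, 179.0, 180.0])
    def test_constructed_dihedral_recovered(self, omega):
        fr = make_two_ring_frame(omegas=(omega,))
        got = omega_dihedral(fr, 0)
        # compare on the circle
        diff = (got - omega + 180.0) % 360.0 - 180.0
        assert abs(diff) < 1e-9

    def test_mirror_image_flips_sign(self):
        fr = make_two_ring_frame(omegas=(35.0,))
        om = omega_dihedral(fr, 0)
        fr.coordinates[:, 2] *= -1.0
        assert omega_dihedral(fr, 0) == pytest.approx(-om, abs=1e-9)

    def test_matches_mdanalysis_dihedral(self):
        """Cross-check the dihedral against the MDAnalysis implementation."""
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(5)
        for _ in range(50):
            pts = rng.uniform(-3, 3, size=(4, 3))
            fr = make_two_ring_frame(omegas=(0.0,))
            fr.coordinates[list(fr.omega_atom_quads[0])] = pts
            try:
                mine = omega_dihedral(fr, 0)
            except DegenerateGeometryError:
                continue
            ref = np.degrees(
                calc_dihedrals(
                    pts[0][None], pts[1][None], pts[2][None], pts[3][None]
                )
            )[0]
            diff = (mine - ref + 180.0) % 360.0 - 180.0
            assert abs(diff) < 1e-4  # MDAnalysis works in float32

    def test_collinear_atoms_degenerate(self):
        fr = make_two_ring_frame(omegas=(0.0,))
        q = list(fr.omega_atom_quads[0])
        fr.coordinates[q] = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            omega_dihedral(fr, 0)

    def test_out_of_range_proline_index(self, two_ring_frame):
        with pytest.raises(ValidationError):
            omega_dihedral(two_ring_frame, 5)


class TestCisTrans:
    @pytest.mark.parametrize(
        "omega, expected",
        [(0.0, "C"), (180.0, "T"), (-180.0, "T"), (89.9, "C"), (90.0, "T"), (-90.0, "T")],
    )
    def test_rule_and_boundary(self, omega, expected):
        assert classify_cis_trans(omega) == expected

    def test_label_frame_orders_flavin_first(self):
        fr = make_two_ring_frame(omegas=(10.0, 170.0, -175.0))
        assert str(label_frame(fr)) == "CTT"

    def test_label_length_equals_proline_count(self):
        for n in (1, 2, 4):
            fr = make_two_ring_frame(omegas=tuple([180.0] * n))
            assert len(str(label_frame(fr))) == n

    def test_label_validation(self):
        with pytest.raises(ValidationError):
            ConformerLabel("CTX")
        with pytest.raises(ValidationError):
            ConformerLabel("")


class TestMoietyGeometry:
    def test_translated_point_sets_distance(self):
        fr = make_two_ring_frame(distance=5.0, tilt_deg=0.0)
        assert moiety_center_distance(fr) == pytest.approx(5.0, abs=1e-9)

    def test_matches_bruteforce_centroids(self):
        rng = np.random.default_rng(2)
        fr = make_two_ring_frame()
        fr.coordinates = rng.uniform(-10, 10, fr.coordinates.shape)
        f = fr.coordinates[fr.moiety_masks["F"]]
        w = fr.coordinates[fr.moiety_masks["W"]]
        brute = np.sqrt(np.sum((f.mean(0) - w.mean(0)) ** 2))
        assert moiety_center_distance(fr) == pytest.approx(brute, rel=1e-12)

    @pytest.mark.parametrize("tilt", [0.0, 10.0, 90.0, 170.0])
    def test_interplane_angle_of_constructed_tilt(self, tilt):
        fr = make_two_ring_frame(tilt_deg=tilt)
        got = interplane_angle(fr)
        assert min(abs(got - tilt), abs(180 - got - tilt)) < 1e-6

    def test_noisy_hexagon_normal_recovered(self):
        """With 0.01 A coordinate noise the fitted plane normal of a hexagon
        stays within 1 degree of the analytic normal (the exact flavin plane
        serves as the reference)."""
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(100):
            fr = make_two_ring_frame(tilt_deg=0.0)
            w = fr.moiety_masks["W"]
            fr.coordinates[w] += 0.01 * rng.standard_normal((w.size, 3))
            ang = interplane_angle(fr)
            worst = max(worst, min(ang, 180 - ang))
        assert worst < 1.0

    def test_rigid_motion_invariance(self):
        """Distances, angles and omega dihedrals are invariant under random
        rotations + translations of the whole frame."""
        rng = np.random.default_rng(4)
        fr = make_two_ring_frame(distance=5.5, tilt_deg=25.0, omegas=(20.0, 160.0))
        d0 = moiety_center_distance(fr)
        a0 = interplane_angle(fr)
        o0 = [omega_dihedral(fr, i) for i in range(2)]
        for _ in range(20):
            R, t = random_rigid_transform(rng)
            fr2 = make_two_ring_frame(distance=5.5, tilt_deg=25.0, omegas=(20.0, 160.0))
            fr2.coordinates = fr.coordinates @ R.T + t
            assert moiety_center_distance(fr2) == pytest.approx(d0, abs=1e-9)
            ang = interplane_angle(fr2)
            assert min(abs(ang - a0), abs(180 - ang - a0)) < 1e-6
            for i in range(2):
                diff = (omega_dihedral(fr2, i) - o0[i] + 180) % 360 - 180
                assert abs(diff) < 1e-6

    def test_collinear_mask_degenerate(self):
        fr = make_two_ring_frame()
        fr.coordinates[fr.moiety_masks["F"]] = np.outer(np.arange(6), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            interplane_angle(fr)


class TestStackingAndHbonds:
    @pytest.mark.parametrize(
        "d, theta, expected",
        [
            (5.0, 10.0, True),
            (5.0, 170.0, True),
            (7.0, 10.0, False),
            (5.0, 90.0, False),
            (3.0, 0.0, True),     # distance band inclusive
            (6.5, 179.0, True),
            (5.0, 45.0, False),   # angle bounds strict
            (5.0, 135.0, False),
            (2.9, 10.0, False),
        ],
    )
    def test_stacking_criterion(self, d, theta, expected):
        assert is_stacked(d, theta) is expected

    def test_ideal_linear_hbond(self):
        """N-H...O=C with H...O = 1.9 A and linear angles qualifies."""
        fr = make_two_ring_frame()
        q = fr.donor_quads[0]
        n_i, h_i, o_i, c_i = q
        fr.coordinates[o_i] = np.array([0.0, 0.0, 0.0])
        fr.coordinates[c_i] = np.array([-1.2, 0.0, 0.0])
        fr.coordinates[h_i] = np.array([1.9, 0.0, 0.0])
        fr.coordinates[n_i] = np.array([2.9, 0.0, 0.0])
        assert is_hbond(fr, q) is True

    def test_too_long_hbond_rejected(self):
        fr = make_two_ring_frame()
        n_i, h_i, o_i, c_i = fr.donor_quads[0]
        fr.coordinates[o_i] = [0.0, 0.0, 0.0]
        fr.coordinates[c_i] = [-1.2, 0.0, 0.0]
        fr.coordinates[h_i] = [3.5, 0.0, 0.0]
        fr.coordinates[n_i] = [4.5, 0.0, 0.0]
        assert is_hbond(fr, fr.donor_quads[0]) is False

    def test_bent_hbond_rejected(self):
        """Short H...O contact with a 100-degree N-H...O angle fails."""
        fr = make_two_ring_frame()
        n_i, h_i, o_i, c_i = fr.donor_quads[0]
        fr.coordinates[o_i] = [0.0, 0.0, 0.0]
        fr.coordinates[c_i] = [-1.2, 0.0, 0.0]
        fr.coordinates[h_i] = [2.0, 0.0, 0.0]
        # N placed to make angle(N-H-O) = 100 degrees
        ang = np.radians(100.0)
        fr.coordinates[n_i] = fr.coordinates[h_i] + [np.cos(ang), np.sin(ang), 0.0]
        assert is_hbond(fr, fr.donor_quads[0]) is False

    def test_criteria_validation(self):
        with pytest.raises(ValidationError):
            GeometryCriteria(stack_dmin=7.0)
        with pytest.raises(ValidationError):
            GeometryCriteria(stack_angle_lo=150.0)


class TestEnsembleStatistics:
    def test_all_stacked_probability_one(self):
        frames, _ = gen_conformer_ensemble(200, stacked_fraction=1.0, hbond_fraction=0.0, seed=0)
        stats = ensemble_statistics(frames)
        assert stats.pooled.p_stacked == 1.0

    def test_matches_bruteforce_loop(self):
        """Conditional probabilities equal an explicit per-frame loop."""
        frames, _ = gen_conformer_ensemble(
            1000,
            stacked_fraction=0.3,
            hbond_fraction=0.1,
            label_distribution={"TT": 0.5, "CT": 0.5},
            seed=11,
        )
        stats = ensemble_statistics(frames)
        crit = GeometryCriteria()
        counts = {}
        for fr in frames:
            lab = str(label_frame(fr, crit))
            d = moiety_center_distance(fr)
            th = interplane_angle(fr)
            st = crit.stack_dmin <= d <= crit.stack_dmax and (
                th < crit.stack_angle_lo or th > crit.stack_angle_hi
            )
            hb = frame_has_hbond(fr, crit)
            n, s, h = counts.get(lab, (0, 0, 0))
            counts[lab] = (n + 1, s + st, h + hb)
        assert set(counts) == set(stats.per_label)
        for lab, (n, s, h) in counts.items():
            assert stats.per_label[lab].n_frames == n
            assert stats.per_label[lab].p_stacked == pytest.approx(s / n)
            assert stats.per_label[lab].p_hbond == pytest.approx(h / n)

    def test_pooled_probability_is_weighted_mixture(self):
        frames, _ = gen_conformer_ensemble(
            500, 0.25, 0.05, {"TTT": 0.7, "CCC": 0.3}, seed=12
        )
        stats = ensemble_statistics(frames)
        mix = sum(
            stats.label_fractions[lab] * stats.per_label[lab].p_stacked
            for lab in stats.per_label
        )
        assert stats.pooled.p_stacked == pytest.approx(mix, abs=1e-12)

    def test_densities_integrate_to_one(self):
        frames, _ = gen_conformer_ensemble(400, 0.2, 0.05, seed=13)
        stats = ensemble_statistics(frames)
        dens, edges = stats.pooled.distance_hist
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValidationError):
            ensemble_statistics([])


class TestPerAtomEnergy:
    @pytest.mark.parametrize(
        "a, b, n, expected",
        [(26.0, 0.0, 108, 26.0 / 108), (5.0, 5.0, 10, 0.0), (10.0, 0.0, 10, 1.0)],
    )
    def test_values(self, a, b, n, expected):
        assert per_atom_energy_difference(a, b, n) == pytest.approx(expected)

    def test_conformer_energy_spread_per_atom(self):
        """A 26 kcal/mol spread over 108 atoms is ~0.24 kcal/mol per atom."""
        assert per_atom_energy_difference(26.0, 0.0, 108) == pytest.approx(0.2407, abs=1e-4)

    def test_zero_atoms_rejected(self):
        with pytest.raises(ValidationError):
            per_atom_energy_difference(1.0, 0.0, 0)
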