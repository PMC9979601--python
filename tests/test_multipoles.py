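"""Multipole rotations and L′-truncated electrostatics, validated against the
exact point-charge Coulomb oracle."""

import numpy as np
import pytest

from alfgp.alf import determine_alf, local_axes
from alfgp.geometry import ANGSTROM_PER_BOHR, MolecularGeometry
from alfgp.multipoles import (
    HARTREE_TO_KJMOL,
    DimerTransform,
    MultipoleSet,
    build_dimer,
    charges_to_multipoles,
    component_index,
    coulomb_energy,
    global_to_alf,
    alf_to_global,
    interaction_rmse_heatmap,
    pair_interaction_energy,
    rotate_multipoles,
)

from conftest import random_rotation


def z_rotation(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@pytest.fixture
def random_moments(rng):
    return MultipoleSet(rng.normal(size=25))


class TestRotation:
    def test_identity_returns_input(self, random_moments):
        out = rotate_multipoles(random_moments, np.eye(3))
        np.testing.assert_allclose(out.moments, random_moments.moments, atol=1e-13)

    def test_monopole_invariant(self, random_moments, rng):
        out = rotate_multipoles(random_moments, random_rotation(rng))
        assert out[(0, 0)] == pytest.approx(random_moments[(0, 0)], abs=1e-14)

    def test_dipole_block_matches_cartesian_vector(self, rng):
        # R_11c ↔ x, R_11s ↔ y, R_10 ↔ z: rotating the rank-1 block must equal
        # rotating the equivalent Cartesian dipole vector
        moments = np.zeros(25)
        dip = rng.normal(size=3)  # (x, y, z)
        moments[component_index(1, 1)] = dip[0]
        moments[component_index(1, -1)] = dip[1]
        moments[component_index(1, 0)] = dip[2]
        W = z_rotation(np.pi / 2)
        out = rotate_multipoles(MultipoleSet(moments), W)
        expected = W @ dip
        assert out[(1, 1)] == pytest.approx(expected[0], abs=1e-12)
        assert out[(1, -1)] == pytest.approx(expected[1], abs=1e-12)
        assert out[(1, 0)] == pytest.approx(expected[2], abs=1e-12)

    def test_quadrupole_matches_point_charge_construction(self, rng):
        # rotating moments of a charge cloud = moments of the rotated cloud
        q = rng.uniform(-1, 1, 6)
        pos = rng.uniform(-0.8, 0.8, (6, 3))
        W = random_rotation(rng)
        direct = charges_to_multipoles(q, pos @ W.T)
        rotated = rotate_multipoles(charges_to_multipoles(q, pos), W)
        np.testing.assert_allclose(rotated.moments, direct.moments, atol=1e-12)

    def test_rank_norms_preserved(self, random_moments, rng):
        for _ in range(5):
            out = rotate_multipoles(random_moments, random_rotation(rng))
            np.testing.assert_allclose(
                out.rank_norms(), random_moments.rank_norms(), atol=1e-12
            )

    def test_inverse_rotation_round_trips(self, random_moments, rng):
        W = random_rotation(rng)
        out = rotate_multipoles(rotate_multipoles(random_moments, W), W.T)
        np.testing.assert_allclose(out.moments, random_moments.moments, atol=1e-10)

    def test_composition(self, random_moments, rng):
        W1, W2 = random_rotation(rng), random_rotation(rng)
        a = rotate_multipoles(rotate_multipoles(random_moments, W1), W2)
        b = rotate_multipoles(random_moments, W2 @ W1)
        np.testing.assert_allclose(a.moments, b.moments, atol=1e-12)

    def test_non_orthonormal_matrix_rejected(self, random_moments):
        with pytest.raises(ValueError, match="orthonormal"):
            rotate_multipoles(random_moments, np.eye(3) * 1.1)

    def test_global_alf_round_trip(self, water, random_moments):
        axes = local_axes(water, determine_alf(water), 0)
        alf_m = global_to_alf(random_moments, axes)
        assert alf_m.frame == "alf"
        back = alf_to_global(alf_m, axes)
        np.testing.assert_allclose(back.moments, random_moments.moments, atol=1e-10)


class TestPairInteraction:
    def test_two_monopoles_give_coulomb_law(self):
        plus = MultipoleSet(np.eye(25)[0])
        minus = MultipoleSet(-np.eye(25)[0])
        r = np.array([0.0, 0.0, ANGSTROM_PER_BOHR])  # 1 bohr apart
        energy = pair_interaction_energy(plus, minus, r, 0, guard_angstrom=0.1)
        assert energy == pytest.approx(-HARTREE_TO_KJMOL, rel=1e-12)

    def test_lprime_zero_equals_pre_truncation(self, rng):
        A = MultipoleSet(rng.normal(size=25))
        B = MultipoleSet(rng.normal(size=25))
        r = np.array([5.0, 1.0, -2.0])
        full_then_l0 = pair_interaction_energy(A, B, r, 0)
        zeroed = pair_interaction_energy(A.truncated(0), B.truncated(0), r, 4)
        assert full_then_l0 == pytest.approx(zeroed, rel=1e-12)

    def test_converges_to_coulomb_sum_monotonically(self, rng):
        # two point-charge clusters 20 Å apart: the L′ = 4 expansion matches
        # the exact Coulomb sum to 1e-4 kJ/mol, and the error falls with L′
        q1 = rng.uniform(-1, 1, 5)
        p1 = rng.uniform(-0.5, 0.5, (5, 3))
        q2 = rng.uniform(-1, 1, 5)
        p2 = rng.uniform(-0.5, 0.5, (5, 3)) + np.array([20.0, 0.0, 0.0])
        c1, c2 = p1.mean(axis=0), p2.mean(axis=0)
        A = charges_to_multipoles(q1, p1, c1)
        B = charges_to_multipoles(q2, p2, c2)
        exact = coulomb_energy(q1, p1, q2, p2)
        errors = [
            abs(pair_interaction_energy(A, B, c2 - c1, L) - exact) for L in range(5)
        ]
        assert errors[4] < 1e-4
        assert all(np.diff(errors) < 0)

    def test_invariant_under_joint_rotation(self, rng):
        q1, p1 = rng.uniform(-1, 1, 4), rng.uniform(-0.5, 0.5, (4, 3))
        q2, p2 = rng.uniform(-1, 1, 4), rng.uniform(-0.5, 0.5, (4, 3))
        r = np.array([8.0, -3.0, 2.0])
        A = charges_to_multipoles(q1, p1)
        B = charges_to_multipoles(q2, p2)
        base = pair_interaction_energy(A, B, r, 4)
        W = random_rotation(rng)
        rotated = pair_interaction_energy(
            rotate_multipoles(A, W), rotate_multipoles(B, W), W @ r, 4
        )
        assert rotated == pytest.approx(base, rel=1e-10)

    def test_symmetric_under_monomer_swap(self, rng):
        A = MultipoleSet(rng.normal(size=25))
        B = MultipoleSet(rng.normal(size=25))
        r = np.array([6.0, 2.0, 1.0])
        assert pair_interaction_energy(A, B, r, 3) == pytest.approx(
            pair_interaction_energy(B, A, -r, 3), rel=1e-10
        )

    def test_neutral_clusters_decay_with_leading_moment(self, rng):
        # two neutral dipolar clusters: energy ~ R⁻³ at large separation
        q = np.array([0.6, -0.6])
        p1 = np.array([[0.0, 0.0, 0.2], [0.0, 0.0, -0.2]])
        A = charges_to_multipoles(q, p1)
        e20 = pair_interaction_energy(A, A, np.array([20.0, 0, 0]), 4)
        e40 = pair_interaction_energy(A, A, np.array([40.0, 0, 0]), 4)
        assert e40 == pytest.approx(e20 / 8.0, rel=1e-3)

    def test_short_range_guard(self, random_moments):
        with pytest.raises(ValueError, match="guard"):
            pair_interaction_energy(
                random_moments, random_moments, np.array([0.5, 0, 0]), 4
            )
        with pytest.warns(UserWarning, match="guard"):
            pair_interaction_energy(
                random_moments, random_moments, np.array([0.5, 0, 0]), 4,
                on_short_range="warn",
            )


class TestHeatmapAndDimer:
    def _dimer_setup(self, rng, n_frames):
        water = MolecularGeometry(
            ["O", "H", "H"],
            np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]),
        )
        transform = DimerTransform(np.eye(3), np.array([0.0, 0.0, 6.0]))
        dimers, true_m, pred_m = [], [], []
        for f in range(n_frames):
            dimer = build_dimer(water, transform)
            dimers.append(dimer)
            frame_true, frame_pred = [], []
            for i in range(6):
                m = rng.normal(scale=0.3, size=25)
                frame_true.append(MultipoleSet(m))
                frame_pred.append(MultipoleSet(m + rng.normal(scale=0.02, size=25)))
            true_m.append(frame_true)
            pred_m.append(frame_pred)
        return dimers, true_m, pred_m

    def test_perfect_prediction_gives_zero_matrix(self, rng):
        dimers, true_m, _ = self._dimer_setup(rng, 2)
        rmse = interaction_rmse_heatmap(true_m, true_m, dimers, 2, 3)
        np.testing.assert_array_equal(rmse, np.zeros((3, 3)))

    def test_single_frame_is_absolute_difference(self, rng):
        dimers, true_m, pred_m = self._dimer_setup(rng, 1)
        rmse = interaction_rmse_heatmap(true_m, pred_m, dimers, 1, 3)
        geom = dimers[0]
        for i in range(3):
            for j in range(3):
                r = geom.coordinates[3 + j] - geom.coordinates[i]
                diff = abs(
                    pair_interaction_energy(pred_m[0][i], pred_m[0][3 + j], r, 1)
                    - pair_interaction_energy(true_m[0][i], true_m[0][3 + j], r, 1)
                )
                assert rmse[i, j] == pytest.approx(diff, rel=1e-12)

    def test_matches_two_loop_oracle(self, rng):
        dimers, true_m, pred_m = self._dimer_setup(rng, 5)
        rmse = interaction_rmse_heatmap(true_m, pred_m, dimers, 2, 3)
        # independent two-loop accumulation
        expected = np.zeros((3, 3))
        for f in range(5):
            for i in range(3):
                for j in range(3):
                    r = dimers[f].coordinates[3 + j] - dimers[f].coordinates[i]
                    d = pair_interaction_energy(
                        pred_m[f][i], pred_m[f][3 + j], r, 2
                    ) - pair_interaction_energy(true_m[f][i], true_m[f][3 + j], r, 2)
                    expected[i, j] += d * d
        np.testing.assert_allclose(rmse, np.sqrt(expected / 5), rtol=1e-12)

    def test_frame_count_mismatch_raises(self, rng):
        dimers, true_m, pred_m = self._dimer_setup(rng, 2)
        with pytest.raises(ValueError, match="mismatch"):
            interaction_rmse_heatmap(true_m[:1], pred_m, dimers, 2, 3)

    def test_translation_preserves_internal_distances(self, water):
        dimer = build_dimer(
            water, DimerTransform(np.eye(3), np.array([10.0, 0.0, 0.0]))
        )
        for i in range(3):
            for j in range(i + 1, 3):
                assert dimer.distance(3 + i, 3 + j) == pytest.approx(
                    water.distance(i, j), abs=1e-12
                )

    def test_reflection_preserves_bond_lengths(self, water):
        dimer = build_dimer(
            water,
            DimerTransform(np.diag([-1.0, 1.0, 1.0]), np.array([8.0, 0.0, 0.0])),
        )
        assert dimer.distance(3, 4) == pytest.approx(water.distance(0, 1), abs=1e-12)

    def test_clash_rejected_with_pair_named(self, water):
        with pytest.raises(ValueError, match="atom"):
            build_dimer(water, DimerTransform(np.eye(3), np.array([0.1, 0.0, 0.0])))

    def test_random_transforms_respect_guard(self, water, rng):
        for _ in range(5):
            t = DimerTransform(
                random_rotation(rng), rng.normal(scale=2, size=3) + [0, 0, 8.0]
            )
            dimer = build_dimer(water, t, guard_angstrom=1.0)
            d = np.linalg.norm(
                dimer.coordinates[:3, None, :] - dimer.coordinates[None, 3:, :],
                axis=-1,
            )
            assert d.min() >= 1.0
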