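import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dimorph as dm
from dimorph.superimpose import (
    _mirror_relabel,
    _slide_pass,
    bending_energy,
    center_configuration,
)
from conftest import make_aligned, random_similarity


class TestCentroidSize:
    def test_unit_square(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert dm.centroid_size(pts) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_single_point_is_zero(self):
        assert dm.centroid_size([(3.0, 4.0)]) == 0.0

    @given(st.floats(0.01, 100))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity(self, c):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 2))
        assert dm.centroid_size(pts * c) == pytest.approx(
            c * dm.centroid_size(pts), rel=1e-10
        )


class TestOptimalRotation:
    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        A = center_configuration(rng.normal(size=(6, 2)))
        theta = np.radians(30)
        R30 = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        B = A @ R30.T
        R = dm.optimal_rotation(A, B)
        assert np.linalg.norm(A @ R - B) < 1e-10

    def test_identity_for_equal_inputs(self):
        A = center_configuration(np.random.default_rng(2).normal(size=(5, 2)))
        np.testing.assert_allclose(dm.optimal_rotation(A, A), np.eye(2),
                                   atol=1e-12)

    def test_determinant_plus_one_even_for_reflected_target(self):
        rng = np.random.default_rng(3)
        A = center_configuration(rng.normal(size=(5, 2)))
        B = A * [1, -1]  # reflection: best proper rotation must not reflect
        R = dm.optimal_rotation(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(4)
        A = center_configuration(rng.normal(size=(5, 2)))
        B = center_configuration(rng.normal(size=(5, 2)))
        R = dm.optimal_rotation(A, B)
        found = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
        # cost(theta) is a sinusoid: dense grid over rotation angle
        thetas = np.radians(np.arange(-180, 180, 0.001))
        c, s = np.cos(thetas), np.sin(thetas)
        H = A.T @ B
        trace = c * (H[0, 0] + H[1, 1]) + s * (H[1, 0] - H[0, 1])
        best = np.degrees(thetas[np.argmax(trace)])
        assert abs((found - best + 180) % 360 - 180) < 0.01


class TestGPA:
    def test_orbit_of_one_shape_collapses(self, face):
        template, base = face
        rng = np.random.default_rng(5)
        pts = np.stack([random_similarity(rng, base) for _ in range(20)])
        aligned = make_aligned(pts, template)
        d = aligned.shapes - aligned.shapes[0]
        assert np.abs(d).max() < 1e-8

    def test_two_shapes_match_pairwise_procrustes(self, face):
        template, base = face
        rng = np.random.default_rng(6)
        A = center_configuration(base + rng.normal(0, 0.05, base.shape))
        B = center_configuration(base + rng.normal(0, 0.05, base.shape))
        A /= dm.centroid_size(A)
        B /= dm.centroid_size(B)
        # oracle: ordinary (pairwise) Procrustes distance
        d_opa = np.linalg.norm(A @ dm.optimal_rotation(A, B) - B)
        aligned = dm.gpa(np.stack([A, B]), template=template,
                         project_to_tangent=False)
        d_gpa = dm.procrustes_distance(aligned.shapes[0], aligned.shapes[1])
        assert d_gpa == pytest.approx(d_opa, abs=1e-8)

    def test_unit_centroid_size_after_scaling(self, small_aligned):
        # tangent projection perturbs size slightly; scaling itself is exact
        sizes = [dm.centroid_size(p) for p in small_aligned.points()]
        np.testing.assert_allclose(sizes, 1.0, atol=1e-3)
        raw = dm.gpa(
            small_aligned.points(), template=small_aligned.template,
            project_to_tangent=False,
        )
        sizes = [dm.centroid_size(p) for p in raw.points()]
        np.testing.assert_allclose(sizes, 1.0, atol=1e-10)

    def test_invariant_to_input_similarity_transforms(self, face):
        template, base = face
        rng = np.random.default_rng(7)
        pts = base + rng.normal(0, 0.02, (15, 20, 2))
        moved = np.stack(
            [random_similarity(np.random.default_rng(100 + i), p)
             for i, p in enumerate(pts)]
        )
        a1 = make_aligned(pts, template)
        a2 = make_aligned(moved, template)
        # common frame differs by one joint rotation: align consensus first
        R = dm.optimal_rotation(
            a2.consensus_points(), a1.consensus_points()
        )
        realigned = a2.points() @ R
        assert np.abs(realigned.reshape(a1.n, -1) - a1.shapes).max() < 1e-6

    def test_consensus_is_row_mean(self, small_aligned):
        np.testing.assert_allclose(
            small_aligned.consensus, small_aligned.shapes.mean(axis=0),
            atol=1e-12,
        )

    def test_zero_centroid_size_rejected(self, face):
        template, _ = face
        pts = np.zeros((3, 20, 2))
        with pytest.raises(ValueError, match="zero centroid"):
            make_aligned(pts, template)


class TestBendingEnergy:
    def test_affine_displacements_have_zero_energy(self, face):
        _, base = face
        B = dm.bending_energy_matrix(base)
        rng = np.random.default_rng(8)
        M = rng.normal(size=(2, 2))
        t = rng.normal(size=2)
        affine = base @ M.T + t - base
        assert abs(bending_energy(B, affine)) < 1e-10

    def test_symmetric_positive_semidefinite(self, face):
        _, base = face
        B = dm.bending_energy_matrix(base)
        np.testing.assert_allclose(B, B.T, atol=1e-12)
        assert np.linalg.eigvalsh(B).min() > -1e-10

    def test_duplicate_landmark_names_pair(self):
        pts = np.array([(0, 0), (1, 0), (1, 0), (0, 1)], dtype=float)
        with pytest.raises(ValueError, match="1 and 2"):
            dm.bending_energy_matrix(pts)

    def test_matches_naive_tps_coefficient_oracle(self, face):
        _, base = face
        B = dm.bending_energy_matrix(base)
        rng = np.random.default_rng(9)
        disp = rng.normal(0, 0.05, base.shape)
        # oracle: solve the full TPS interpolation system for the non-affine
        # coefficients w and evaluate w' K w per coordinate
        k = base.shape[0]
        diff = base[:, None] - base[None, :]
        r2 = (diff**2).sum(-1)
        K = np.where(r2 > 0, r2 * np.log(np.where(r2 > 0, r2, 1)), 0.0)
        Q = np.column_stack([np.ones(k), base])
        L = np.block([[K, Q], [Q.T, np.zeros((3, 3))]])
        expected = 0.0
        for c in range(2):
            sol = np.linalg.solve(L, np.concatenate([disp[:, c], np.zeros(3)]))
            w = sol[:k]
            expected += float(w @ K @ w)
        assert bending_energy(B, disp) == pytest.approx(expected, rel=1e-8)


class TestSliding:
    def test_specimen_at_consensus_does_not_move(self, face):
        template, base = face
        B = dm.bending_energy_matrix(base)
        out = _slide_pass(base[None], base, template, B)
        assert np.abs(out[0] - base).max() < 1e-10

    def test_energy_non_increasing_over_passes(self, small_aligned):
        slid = dm.slide_semilandmarks(small_aligned, iterations=3)
        h = np.array(slid.energy_history)
        assert len(h) == 4
        assert np.all(np.diff(h) <= 1e-10)
        assert slid.slid

    def test_single_semilandmark_matches_golden_section_oracle(self):
        # 6-point template: one curve, one semilandmark (index 1)
        template = dm.LandmarkTemplate(
            n_landmarks=6, semilandmark_indices=(1,), curves=((0, 1, 2),)
        )
        rng = np.random.default_rng(10)
        cons = np.array(
            [(0, 0), (1.0, 0.3), (2, 0), (1, 1.5), (0.2, 1.1), (1.8, 1.2)]
        )
        spec = cons + rng.normal(0, 0.1, cons.shape)
        B = dm.bending_energy_matrix(cons)
        out = _slide_pass(spec[None], cons, template, B)[0]
        tangent = spec[2] - spec[0]
        tangent /= np.linalg.norm(tangent)

        from scipy.optimize import minimize_scalar

        def energy_at(u):
            moved = spec.copy()
            moved[1] += u * tangent
            return bending_energy(B, moved - cons)

        res = minimize_scalar(energy_at, bounds=(-1, 1), method="bounded",
                              options={"xatol": 1e-10})
        expected = spec[1] + res.x * tangent
        np.testing.assert_allclose(out[1], expected, atol=1e-6)


class TestSymmetrize:
    def test_symmetric_input_is_fixed_point(self, face):
        template, base = face
        stack = np.stack([base, base])
        aligned = make_aligned(stack, template)
        sym = dm.symmetrize(aligned)
        assert np.abs(sym.points()[0] - aligned.points()[0]).max() < 1e-10

    def test_output_exactly_mirror_symmetric(self, small_aligned):
        sym = dm.symmetrize(small_aligned)
        worst = max(
            np.abs(_mirror_relabel(p, sym.template) - p).max()
            for p in sym.points()
        )
        assert worst < 1e-10
        assert sym.symmetrized

    def test_idempotent(self, small_aligned):
        once = dm.symmetrize(small_aligned)
        twice = dm.symmetrize(once)
        assert np.abs(twice.shapes - once.shapes).max() < 1e-10

    def test_mirror_twin_maps_to_same_shape(self):
        # 6-landmark toy: 2 midline + 2 bilateral pairs
        template = dm.LandmarkTemplate(
            n_landmarks=6,
            bilateral_pairs=((1, 2), (3, 4)),
            midline_indices=(0, 5),
        )
        rng = np.random.default_rng(11)
        pts = np.array(
            [(0, 1.1), (-0.9, 0.4), (1.0, 0.5), (-0.6, -0.8), (0.7, -0.7),
             (0.05, -1.2)]
        ) + rng.normal(0, 0.05, (6, 2))
        twin = _mirror_relabel(center_configuration(pts), template)
        both = np.stack([center_configuration(pts), twin])
        aligned = dm.gpa(both, template=template, project_to_tangent=False)
        sym = dm.symmetrize(aligned)
        a, b = sym.points()
        # same symmetric shape up to rotation in the common frame
        R = dm.optimal_rotation(b - b.mean(0), a - a.mean(0))
        assert np.linalg.norm((b - b.mean(0)) @ R - (a - a.mean(0))) < 1e-8

    def test_unpaired_landmark_rejected(self, small_aligned):
        import dataclasses

        bad = dm.LandmarkTemplate(n_landmarks=20)
        with pytest.raises(Exception, match="bilateral|unpaired"):
            dm.symmetrize(
                dataclasses.replace(small_aligned, template=bad)
            )


class TestDistanceAndOutliers:
    def test_distance_axioms_on_random_triples(self):
        rng = np.random.default_rng(12)
        a, b, c = rng.normal(size=(3, 40))
        assert dm.procrustes_distance(a, a) == 0.0
        assert dm.procrustes_distance(a, b) == dm.procrustes_distance(b, a)
        assert dm.procrustes_distance(a, c) <= (
            dm.procrustes_distance(a, b) + dm.procrustes_distance(b, c)
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            dm.procrustes_distance(np.zeros(4), np.zeros(6))

    def test_gross_outlier_flagged(self, face):
        template, base = face
        rng = np.random.default_rng(13)
        pts = base + rng.normal(0, 0.002, (30, 20, 2))
        pts[7] = base + rng.normal(0, 0.4, (20, 2))
        aligned = make_aligned(pts, template)
        assert dm.detect_outliers(aligned) == ["s7"]

    def test_huge_multiplier_flags_nothing(self, small_aligned):
        assert dm.detect_outliers(small_aligned, multiplier=10) == []

    def test_matches_brute_force_quartile_rule(self, small_aligned):
        flagged = dm.detect_outliers(small_aligned, multiplier=1.0)
        d = np.array(
            [dm.procrustes_distance(row, small_aligned.consensus)
             for row in small_aligned.shapes]
        )
        q1, q3 = np.percentile(d, [25, 75])
        expected = small_aligned.meta["id"][
            d > q3 + 1.0 * (q3 - q1)
        ].tolist()
        assert flagged == expected


class TestRepeatability:
    def _replicate_aligned(self, face, sigma_b, sigma_w, n=200, seed=14):
        template, base = face
        rng = np.random.default_rng(seed)
        true = base.reshape(-1) + rng.normal(0, sigma_b, (n, 40))
        obs = np.repeat(true, 2, axis=0) + rng.normal(0, sigma_w, (2 * n, 40))
        meta = pd.DataFrame(
            {
                "id": [f"r{i}" for i in range(2 * n)],
                "individual": np.repeat([f"i{j}" for j in range(n)], 2),
            }
        )
        return dm.gpa(obs.reshape(-1, 20, 2), template=template, meta=meta)

    def test_identical_replicates_give_exactly_one(self, face):
        aligned = self._replicate_aligned(face, sigma_b=0.01, sigma_w=0.0)
        res = dm.repeatability(aligned)
        assert res.repeatability == 1.0
        assert res.measurement_error == 0.0

    def test_pure_noise_gives_near_zero(self, face):
        aligned = self._replicate_aligned(face, sigma_b=0.0, sigma_w=0.01)
        res = dm.repeatability(aligned)
        assert res.repeatability < 0.05

    def test_nine_to_one_variance_ratio_recovered(self, face):
        aligned = self._replicate_aligned(face, sigma_b=0.012, sigma_w=0.004)
        res = dm.repeatability(aligned)
        assert res.repeatability == pytest.approx(0.9, abs=0.02)
        assert res.repeatability + res.measurement_error == pytest.approx(1.0)

    def test_single_replicate_rejected(self, face):
        aligned = self._replicate_aligned(face, 0.01, 0.01, n=5)
        labels = np.array([f"u{i}" for i in range(aligned.n)])  # all singletons
        with pytest.raises(ValueError, match="< 2 replicates"):
            dm.repeatability(aligned, labels)
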