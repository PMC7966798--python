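import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dimorph as dm
from conftest import make_aligned


def _two_sex_shapes(s_m, s_f):
    shapes = np.stack([s_m, s_f])
    sex = np.array(["male", "female"])
    return shapes, sex


class TestSexDifferenceVector:
    def test_two_individuals(self):
        rng = np.random.default_rng(0)
        s_m, s_f = rng.normal(size=(2, 10))
        shapes, sex = _two_sex_shapes(s_m, s_f)
        v = dm.sex_difference_vector(shapes, sex)
        np.testing.assert_allclose(v.v1, s_m - s_f, atol=1e-15)
        np.testing.assert_allclose(v.MM, s_m)
        np.testing.assert_allclose(v.FM, s_f)

    def test_identical_means_give_zero_vector_and_projection_refuses(self):
        s = np.ones(6)
        shapes, sex = _two_sex_shapes(s, s)
        v = dm.sex_difference_vector(shapes, sex)
        assert v.norm == 0.0
        with pytest.raises(ValueError, match="degenerate"):
            dm.sexscore(shapes, v)

    def test_missing_sex_raises(self):
        with pytest.raises(ValueError, match="both sexes"):
            dm.sex_difference_vector(
                np.ones((3, 4)), np.array(["male"] * 3)
            )

    def test_recovers_generated_effect(self, small_aligned, small_study):
        # per-population ||v1|| vs the generated ||d_p + dh*b_p|| (the sex
        # vector includes the allometric term through the sample height gap);
        # norms compared because the aligned frame is jointly rotated
        meta = small_aligned.meta
        for p in ("P1", "P2"):
            mask = (meta["population"] == p).to_numpy()
            sex = meta["sex"].to_numpy()[mask]
            v = dm.sex_difference_vector(small_aligned.shapes[mask], sex)
            d = np.asarray(small_study.truth["populations"][p]["sex_effect"])
            b = np.asarray(
                small_study.truth["populations"][p]["allometric_vector"]
            )
            h = meta["height"].to_numpy(dtype=float)[mask]
            dh = h[sex == "male"].mean() - h[sex == "female"].mean()
            expected = np.linalg.norm(d + dh * b)
            assert abs(v.norm - expected) / expected < 0.2


class TestSexscore:
    def test_dot_product_arithmetic(self):
        v1 = np.zeros(6)
        v1[0] = 2.0
        A = np.zeros(6)
        A[0], A[1] = 3.0, 1.0
        assert dm.sexscore(A, v1) == pytest.approx(6.0)

    def test_mean_identity(self):
        rng = np.random.default_rng(1)
        shapes = rng.normal(size=(40, 12))
        sex = np.array(["male", "female"] * 20)
        v = dm.sex_difference_vector(shapes, sex)
        gap = dm.sexscore(v.MM, v) - dm.sexscore(v.FM, v)
        assert gap == pytest.approx(v.norm**2, abs=1e-12)

    def test_affine_in_interpolation_parameter(self):
        rng = np.random.default_rng(2)
        shapes = rng.normal(size=(10, 8))
        sex = np.array(["male"] * 5 + ["female"] * 5)
        v = dm.sex_difference_vector(shapes, sex)
        ts = np.linspace(-1, 2, 7)
        scores = [dm.sexscore(v.FM + t * v.v1, v) for t in ts]
        slopes = np.diff(scores) / np.diff(ts)
        np.testing.assert_allclose(slopes, v.norm**2, rtol=1e-10)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, a, b):
        rng = np.random.default_rng(3)
        A, B = rng.normal(size=(2, 10))
        v1 = rng.normal(size=10)
        lhs = dm.sexscore(a * A + b * B, v1)
        rhs = a * dm.sexscore(A, v1) + b * dm.sexscore(B, v1)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestInversion:
    def test_female_negated_male_unchanged(self):
        scores = np.array([-0.3, 0.5])
        sex = np.array(["female", "male"])
        out = dm.invert_female_scores(scores, sex)
        np.testing.assert_allclose(out, [0.3, 0.5])

    def test_all_male_is_identity(self):
        scores = np.array([0.1, -0.2])
        out = dm.invert_female_scores(scores, np.array(["male", "male"]))
        np.testing.assert_array_equal(out, scores)

    def test_double_inversion_guarded(self):
        with pytest.raises(ValueError, match="already inverted"):
            dm.invert_female_scores(
                np.zeros(2), np.array(["male", "female"]),
                already_inverted=True,
            )


class TestShapeRegression:
    def test_orthogonal_covariate_gives_zero_coefficients(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 8))
        h = rng.normal(size=50)
        # orthogonalize each column against the centred covariate
        hc = h - h.mean()
        X = X - np.outer(hc, (hc @ X) / (hc @ hc))
        fitted, resid, coef = dm.regress_shape_on_covariate(X, h)
        np.testing.assert_allclose(coef, 0.0, atol=1e-12)
        np.testing.assert_allclose(resid, X - X.mean(axis=0), atol=1e-12)

    def test_exact_interpolation_recovers_coefficients(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=6)
        b = rng.normal(size=6)
        h = rng.normal(170, 7, size=30)
        X = base + np.outer(h, b)
        _, resid, coef = dm.regress_shape_on_covariate(X, h)
        np.testing.assert_allclose(coef, b, atol=1e-10)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_matches_two_pass_covariance_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 5))
        h = rng.normal(size=40)
        _, _, coef = dm.regress_shape_on_covariate(X, h)
        expected = [
            np.cov(h, X[:, j], ddof=1)[0, 1] / np.var(h, ddof=1)
            for j in range(5)
        ]
        np.testing.assert_allclose(coef, expected, rtol=1e-10)

    def test_fitted_plus_residual_is_identity(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 4))
        h = rng.normal(size=20)
        fitted, resid, _ = dm.regress_shape_on_covariate(X, h)
        np.testing.assert_allclose(fitted + resid, X, atol=1e-12)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dm.regress_shape_on_covariate(np.ones((5, 4)), np.ones(5))


class TestAngles:
    @pytest.mark.parametrize(
        "v, w, expected",
        [((1, 0), (0, 1), 90.0), ((1, 0), (1, 1), 45.0), ((1, 0), (2, 0), 0.0)],
    )
    def test_hand_computed_angles(self, v, w, expected):
        assert dm.angle_between(np.array(v), np.array(w)) == pytest.approx(
            expected, abs=1e-10
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            dm.angle_between(np.zeros(2), np.ones(2))

    def test_antiparallel_is_180(self):
        assert dm.angle_between(np.ones(4), -np.ones(4)) == pytest.approx(180)


def _decomp_study(seed, n_per_sex=150, b_norm=0.002, d_norm=0.03,
                  noise=0.003, orthogonal=False, height_gap=13.0):
    template, base = dm.generate_template_face()
    rng = np.random.default_rng(seed)
    d = dm.structured_vector(rng, base, template, d_norm)
    if b_norm == 0:
        b = np.zeros(40)
    else:
        b = dm.structured_vector(rng, base, template, b_norm)
        if orthogonal:
            b -= (b @ d) / (d @ d) * d
            b *= b_norm / np.linalg.norm(b)
    pop = dm.PopulationSpec(
        name="P1", n_per_sex=n_per_sex, mean_offset=np.zeros(40),
        sex_effect=d, allometric_vector=b,
        height_mean_f=171.5 - height_gap / 2,
        height_mean_m=171.5 + height_gap / 2,
    )
    spec = dm.SyntheticSpec(populations=[pop], shape_noise_sd=noise,
                            seed=seed)
    ds = dm.generate_dataset(spec)
    aligned = dm.gpa(
        dm.assemble_dataset(ds.configs, ds.metadata, ds.template)
    )
    return aligned, d, b


class TestAllometricDecomposition:
    def test_no_allometry_limit(self):
        # b = 0 and no sex height gap (so height does not proxy for sex):
        # v2 is pure noise, allometric scores tiny, nu near 0
        aligned, d, _ = _decomp_study(seed=8, b_norm=0.0, noise=0.002,
                                      n_per_sex=300, height_gap=0.0)
        res = dm.allometric_decomposition(aligned, scope="global",
                                          invert_female=False)
        assert np.linalg.norm(res.v2) < 0.03 * np.linalg.norm(d)
        assert res.nu_deg < 5.0
        # allometric scores sit at the finite-sample noise floor set by the
        # accidental sample correlation of height with sex, O(1/sqrt(n))
        assert np.std(res.scores_allometric) < 0.15 * np.std(
            res.scores_overall
        )

    def test_nonallometric_matches_overall_when_no_allometry(self):
        aligned, _, _ = _decomp_study(seed=9, b_norm=0.0, noise=0.002,
                                      n_per_sex=300, height_gap=0.0)
        res = dm.allometric_decomposition(aligned, scope="global",
                                          invert_female=False)
        r = np.corrcoef(res.scores_overall, res.scores_nonallometric)[0, 1]
        assert r > 0.99

    def test_orthogonal_allometry_gives_right_angle(self):
        # d exactly orthogonal to b and no sex height gap: alpha -> 90 deg
        # and non-allometric scores track overall scores
        aligned, d, b = _decomp_study(seed=15, b_norm=0.002, noise=0.002,
                                      n_per_sex=2000, orthogonal=True,
                                      height_gap=0.0)
        res = dm.allometric_decomposition(aligned, scope="global",
                                          invert_female=False)
        assert res.alpha_deg == pytest.approx(90.0, abs=5.0)
        r = np.corrcoef(res.scores_overall, res.scores_nonallometric)[0, 1]
        assert r > 0.95

    def test_alpha_and_nu_track_generated_geometry(self):
        # pooled regression picks up b plus the sex-height confound:
        # E[v2] = b + lam*d, global v1 = d + dh*b, v3 = (1 - lam*dh)*d
        aligned, d, b = _decomp_study(seed=10, n_per_sex=500, noise=0.002)
        res = dm.allometric_decomposition(aligned, scope="global")
        dh, sh = 13.0, 6.0
        lam = (dh / 4) / (sh**2 + dh**2 / 4)
        alpha_true = dm.angle_between(d + dh * b, b + lam * d)
        nu_true = dm.angle_between(d + dh * b, d)
        assert res.alpha_deg == pytest.approx(alpha_true, abs=5.0)
        assert res.nu_deg == pytest.approx(nu_true, abs=5.0)

    def test_scores_inverted_for_females(self):
        aligned, _, _ = _decomp_study(seed=11)
        inv = dm.allometric_decomposition(aligned, scope="global")
        raw = dm.allometric_decomposition(aligned, scope="global",
                                          invert_female=False)
        f = inv.sex == "female"
        np.testing.assert_allclose(inv.scores_overall[f],
                                   -raw.scores_overall[f])
        np.testing.assert_allclose(inv.scores_overall[~f],
                                   raw.scores_overall[~f])

    def test_angle_invariant_to_height_rescaling(self):
        aligned, _, _ = _decomp_study(seed=12)
        res1 = dm.allometric_decomposition(aligned, scope="global")
        scaled = aligned.meta.copy()
        scaled["height"] = scaled["height"] * 3.7
        import dataclasses

        res2 = dm.allometric_decomposition(
            dataclasses.replace(aligned, meta=scaled), scope="global"
        )
        assert res1.alpha_deg == pytest.approx(res2.alpha_deg, abs=1e-8)
        assert res1.nu_deg == pytest.approx(res2.nu_deg, abs=1e-8)

    def test_missing_heights_excluded(self, small_aligned):
        meta = small_aligned.meta.copy()
        meta.loc[:4, "height"] = np.nan
        import dataclasses

        res = dm.allometric_decomposition(
            dataclasses.replace(small_aligned, meta=meta), scope="global"
        )
        assert len(res.scores_overall) == small_aligned.n - 5


class TestTrajectoryAnalysis:
    def test_diagonal_angles_zero_and_matrices_symmetric(self, small_aligned):
        res = dm.trajectory_analysis(small_aligned, n_perm=49, seed=0)
        np.testing.assert_array_equal(np.diag(res.angles_deg), 0.0)
        np.testing.assert_allclose(res.angles_deg, res.angles_deg.T)
        np.testing.assert_allclose(res.magnitude_diff, res.magnitude_diff.T)
        assert np.all(res.magnitudes >= 0)

    def test_doubled_effect_detected(self, face):
        template, base = face
        rng = np.random.default_rng(13)
        d = dm.structured_vector(rng, base, template, 0.03)
        pops = [
            dm.PopulationSpec(name="A", n_per_sex=150,
                              mean_offset=np.zeros(40), sex_effect=d,
                              allometric_vector=np.zeros(40)),
            dm.PopulationSpec(name="B", n_per_sex=150,
                              mean_offset=np.zeros(40), sex_effect=2 * d,
                              allometric_vector=np.zeros(40)),
        ]
        ds = dm.generate_dataset(
            dm.SyntheticSpec(populations=pops, shape_noise_sd=0.002, seed=14)
        )
        aligned = dm.gpa(
            dm.assemble_dataset(ds.configs, ds.metadata, ds.template)
        )
        res = dm.trajectory_analysis(aligned, n_perm=199, seed=1)
        observed = res.magnitude_diff[0, 1]
        assert observed == pytest.approx(np.linalg.norm(d), rel=0.1)
        assert res.p_magnitude[0, 1] < 0.01

    def test_seed_is_required(self, small_aligned):
        with pytest.raises(ValueError, match="seed"):
            dm.trajectory_analysis(small_aligned, n_perm=9)

    def test_reproducible_given_seed(self, small_aligned):
        r1 = dm.trajectory_analysis(small_aligned, n_perm=49, seed=7)
        r2 = dm.trajectory_analysis(small_aligned, n_perm=49, seed=7)
        np.testing.assert_array_equal(r1.p_magnitude, r2.p_magnitude)
        np.testing.assert_array_equal(r1.p_angle, r2.p_angle)
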