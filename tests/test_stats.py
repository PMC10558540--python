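"""PCA, LDA accuracy, Procrustes linear models, repeatability, allometry."""

import numpy as np
import pytest
from sklearn.decomposition import PCA as SkPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from craniomap import (
    SyntheticSpec,
    allometric_regression,
    angle_permutation_test,
    form_matrix,
    gpa,
    lda_accuracy,
    n_components_for_variance,
    pca,
    procrustes_lm,
    repeatability,
    simulate,
    trajectory_angle,
)
from craniomap.errors import (
    CollinearityError,
    ConfigurationError,
    DimensionError,
    SingularGeometryError,
    UnbalancedDesignError,
)
from craniomap.synthetic import planted_variance_dataset

from conftest import make_specimen_set


class TestPca:
    def test_invariants_on_random_data(self, rng):
        x = rng.normal(size=(40, 7)) @ np.diag([5, 3, 2, 1, 1, 0.5, 0.1])
        p = pca(x)
        gram = p.components @ p.components.T
        np.testing.assert_allclose(gram, np.eye(p.n_components), atol=1e-9)
        np.testing.assert_allclose(p.scores.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(p.scores.var(axis=0, ddof=1), p.eigenvalues, atol=1e-8)
        assert np.all(np.diff(p.variance_fractions) <= 1e-12)
        assert p.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_known_covariance_eigenvalues(self):
        # build a matrix whose sample covariance is exactly [[2,1],[1,2]]
        n = 20
        z = np.zeros((n, 2))
        z[:, 0] = np.tile([1.0, -1.0], n // 2)
        z[: n // 2, 1] = 1.0
        z[n // 2:, 1] = -1.0
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
        z[:, 1] -= z[:, 0] * (z[:, 0] @ z[:, 1]) / (z[:, 0] @ z[:, 0])
        z[:, 1] /= z[:, 1].std(ddof=1)
        chol = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        x = z @ chol.T
        p = pca(x)
        np.testing.assert_allclose(p.eigenvalues, [3.0, 1.0], atol=1e-9)
        np.testing.assert_allclose(p.variance_fractions, [0.75, 0.25], atol=1e-9)

    def test_reconstruction_is_complete(self, rng):
        x = rng.normal(size=(15, 6))
        p = pca(x)
        recon = p.mean_vector + p.scores @ p.components
        np.testing.assert_allclose(recon, x, atol=1e-9)

    def test_matches_sklearn_oracle(self, rng):
        x = rng.normal(size=(30, 5))
        p = pca(x)
        sk = SkPCA().fit(x)
        np.testing.assert_allclose(p.eigenvalues, sk.explained_variance_, atol=1e-9)
        np.testing.assert_allclose(
            np.abs(p.components), np.abs(sk.components_), atol=1e-8
        )

    def test_constant_matrix_flagged_degenerate(self):
        p = pca(np.ones((5, 3)))
        assert p.degenerate
        np.testing.assert_allclose(p.eigenvalues, 0, atol=1e-12)


class TestFormMatrix:
    def test_log_size_column_for_identical_shapes(self, rng):
        shape = rng.normal(size=(6, 3))
        stack = np.array([shape * np.e, shape * np.e ** 2])
        cs = np.sqrt(((shape - shape.mean(0)) ** 2).sum())
        proc = gpa(make_specimen_set(stack / cs), scale=True)
        fm = form_matrix(proc)
        assert fm.shape[1] == 3 * 6 + 1
        np.testing.assert_allclose(fm[:, -1], [1.0, 2.0], atol=1e-9)
        # identical shapes: only the size column varies
        assert np.abs(fm[0, :-1] - fm[1, :-1]).max() <= 1e-8

    def test_unscaled_gpa_rejected(self, null_small):
        specimens, _ = null_small
        proc = gpa(specimens, scale=False)
        with pytest.raises(ConfigurationError):
            form_matrix(proc)

    def test_pc1_tracks_log_size_under_strong_allometry(self):
        spec = SyntheticSpec(
            n_points=60, n_per_group=(30, 30), size_means=(700.0, 700.0),
            size_sds=(140.0, 140.0), allometry_strength=0.3, noise_sd=0.05,
            seed=2,
        )
        specimens, _ = simulate(spec)
        proc = gpa(specimens, scale=True)
        p = pca(form_matrix(proc))
        r = np.corrcoef(p.scores[:, 0], np.log(proc.centroid_sizes))[0, 1]
        assert abs(r) > 0.99


class TestNComponents:
    @pytest.mark.parametrize(
        "fractions, threshold, expected",
        [((0.5, 0.3, 0.2), 0.9, 3), ((0.95, 0.05), 0.9, 1), ((0.5, 0.3, 0.2), 1.0, 3)],
    )
    def test_examples(self, fractions, threshold, expected, rng):
        fake = pca(rng.normal(size=(10, 3)))
        fake = type(fake)(
            mean_vector=fake.mean_vector, components=fake.components,
            eigenvalues=fake.eigenvalues, scores=fake.scores,
            variance_fractions=np.array(fractions),
        )
        assert n_components_for_variance(fake, threshold) == expected

    def test_threshold_validated(self, rng):
        p = pca(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            n_components_for_variance(p, 0.0)


class TestLdaAccuracy:
    def test_well_separated_clouds_are_perfect(self, rng):
        x = np.vstack([rng.normal(0, 1, (20, 4)), rng.normal(10, 1, (20, 4))])
        labels = np.array(["F"] * 20 + ["M"] * 20, dtype=object)
        res = lda_accuracy(x, labels, n_perm=25, seed=1)
        assert res.acc_total == 1.0
        assert res.acc_F == 1.0 and res.acc_M == 1.0

    def test_coin_labels_on_noise_sit_at_chance(self, rng):
        # n large enough that the held-out-mean pessimism of cross-validation
        # under the null (~p/n) stays inside the binomial band
        x = rng.normal(size=(200, 5))
        labels = np.where(rng.random(200) < 0.5, "F", "M").astype(object)
        res = lda_accuracy(x, labels, n_perm=200, seed=2)
        assert abs(res.acc_total - 0.5) <= 0.05

    def test_matches_hand_computed_discriminant_on_fixed_split(self):
        # 12 specimens, 2 variables; train = first 4 of each class, test = rest.
        # Oracle: closed-form pooled-covariance discriminant computed from
        # explicit formulas (independent of the package's LDA class).
        x = np.array([
            [0.0, 0.2], [0.4, -0.1], [-0.2, 0.1], [0.1, 0.3], [0.2, 0.0], [-0.1, -0.2],
            [1.0, 1.2], [1.3, 0.9], [0.8, 1.1], [1.1, 1.4], [0.7, 0.6], [1.2, 1.0],
        ])
        y = np.array([False] * 6 + [True] * 6)
        train = np.array([0, 1, 2, 3, 6, 7, 8, 9])
        test = np.array([4, 5, 10, 11])
        m0 = x[train[:4]].mean(axis=0)
        m1 = x[train[4:]].mean(axis=0)
        r0 = x[train[:4]] - m0
        r1 = x[train[4:]] - m1
        sw = (r0.T @ r0 + r1.T @ r1) / (8 - 2)
        w = np.linalg.inv(sw) @ (m1 - m0)
        oracle_pred = (x[test] - 0.5 * (m0 + m1)) @ w > 0.0
        from craniomap.stats import _TwoClassLDA

        model = _TwoClassLDA().fit(x[train], y[train])
        np.testing.assert_array_equal(model.predict(x[test]), oracle_pred)
        # cross-check against sklearn on the same split (dual route)
        sk = LinearDiscriminantAnalysis().fit(x[train], y[train])
        np.testing.assert_array_equal(sk.predict(x[test]).astype(bool), oracle_pred)

    def test_invariant_to_feature_space_rotation(self, rng):
        x = np.vstack([rng.normal(0, 1, (15, 6)), rng.normal(0.8, 1, (15, 6))])
        labels = np.array(["F"] * 15 + ["M"] * 15, dtype=object)
        from scipy.stats import ortho_group

        q = ortho_group.rvs(6, random_state=4)
        res1 = lda_accuracy(x, labels, n_perm=50, seed=9)
        res2 = lda_accuracy(x @ q, labels, n_perm=50, seed=9)
        assert res1.acc_total == pytest.approx(res2.acc_total, abs=1e-12)

    def test_small_class_rejected(self, rng):
        x = rng.normal(size=(5, 2))
        labels = np.array(["F", "F", "F", "F", "M"], dtype=object)
        with pytest.raises(DimensionError):
            lda_accuracy(x, labels)


class TestProcrustesLm:
    def test_exact_linear_response_takes_all_variance(self, rng):
        size = rng.normal(size=50)
        y = np.outer(size, rng.normal(size=(8,)))
        rows = procrustes_lm(y, [("size", size)], n_perm=99, seed=0)
        assert rows[0]["fraction"] == pytest.approx(1.0, abs=1e-9)
        assert rows[0]["p_value"] == pytest.approx(1 / 100)

    def test_fractions_sum_to_one(self, rng):
        y = rng.normal(size=(40, 6))
        size = rng.normal(size=40)
        sex = np.where(np.arange(40) % 2 == 0, "F", "M").astype(object)
        rows = procrustes_lm(y, [("size", size), ("sex", sex)], n_perm=19, seed=0)
        assert sum(r["fraction"] for r in rows) == pytest.approx(1.0, abs=1e-9)

    def test_null_term_has_unextreme_pvalues(self):
        # a term independent of the response should rarely be significant
        lows = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            y = rng.normal(size=(40, 5))
            noise_term = rng.normal(size=40)
            rows = procrustes_lm(y, [("noise", noise_term)], n_perm=99, seed=rep)
            assert rows[0]["fraction"] < 0.2  # ~ E[1/(n-1)] plus spread
            if rows[0]["p_value"] < 0.05:
                lows += 1
        assert lows <= 3

    def test_planted_fraction_recovery(self):
        y, size, sex = planted_variance_dataset(200, 50, 0.4, 0.1, seed=11)
        inter = size * np.where(sex == "M", 1.0, -1.0)
        rows = procrustes_lm(
            y, [("size", size), ("sex", sex), ("size_x_sex", inter)], n_perm=99, seed=1
        )
        assert rows[0]["fraction"] == pytest.approx(0.4, abs=0.05)
        assert rows[1]["fraction"] == pytest.approx(0.1, abs=0.05)
        assert rows[0]["p_value"] <= 0.05 and rows[1]["p_value"] <= 0.05

    def test_confounded_terms_rejected(self, rng):
        y = rng.normal(size=(20, 4))
        t = rng.normal(size=20)
        with pytest.raises(CollinearityError):
            procrustes_lm(y, [("a", t), ("b", 2 * t)], n_perm=9)


class TestRepeatability:
    def test_identical_replicates_give_hundred_percent(self, rng):
        base = rng.normal(size=(6, 12))
        y = np.repeat(base, 3, axis=0)
        ids = np.repeat(np.arange(6), 3)
        assert repeatability(y, ids, 3) == pytest.approx(100.0, abs=1e-9)

    def test_pure_noise_replicates_near_zero(self):
        vals = []
        for rep in range(50):
            rng = np.random.default_rng(rep)
            y = rng.normal(size=(8 * 4, 10))
            ids = np.repeat(np.arange(8), 4)
            vals.append(repeatability(y, ids, 4))
        assert np.mean(vals) <= 10.0  # clamped at 0, so the mean sits just above

    def test_planted_variance_ratio_matches_component_oracle(self):
        # among:within = 9:1 with r = 4, 8 individuals; oracle estimates the
        # components directly from empirical variances of the same draws
        rng = np.random.default_rng(21)
        g, r, p = 8, 4, 15
        ind_effects = rng.normal(0, 3.0, size=(g, p))
        y = np.repeat(ind_effects, r, axis=0) + rng.normal(0, 1.0, size=(g * r, p))
        ids = np.repeat(np.arange(g), r)
        rep = repeatability(y, ids, r)
        means = np.array([y[ids == i].mean(axis=0) for i in range(g)])
        sigma_w = np.mean([y[ids == i].var(axis=0, ddof=1).sum() for i in range(g)])
        sigma_a = means.var(axis=0, ddof=1).sum() - sigma_w / r
        oracle = 100 * sigma_a / (sigma_a + sigma_w)
        assert rep == pytest.approx(oracle, abs=1e-9)
        assert rep == pytest.approx(100 * 9 / 10, abs=8.0)

    def test_unbalanced_design_rejected(self, rng):
        y = rng.normal(size=(5, 4))
        ids = np.array([0, 0, 1, 1, 1])
        with pytest.raises(UnbalancedDesignError):
            repeatability(y, ids, 2)


class TestAllometry:
    def make_linear_proc(self, rng, n=30, n_points=8):
        """A ProcrustesResult whose aligned shapes are an exact linear
        function of the stored centroid sizes (direct construction, so the
        regression contract is isolated from the superimposition step)."""
        from craniomap.datatypes import ProcrustesResult

        base = rng.normal(size=(n_points, 3))
        base = base - base.mean(axis=0)
        base /= np.sqrt((base ** 2).sum())
        beta = rng.normal(size=(n_points, 3)) * 0.001
        sizes = rng.uniform(50, 150, size=n)
        aligned = np.array([base + beta * (s - 100.0) for s in sizes])
        proc = ProcrustesResult(
            aligned=aligned, centroid_sizes=sizes, consensus=aligned.mean(axis=0),
            scaled=True, n_iterations=1, final_change=0.0,
        )
        return proc, beta, sizes

    def test_exact_linear_shape_gives_r2_one(self, rng):
        proc, beta, sizes = self.make_linear_proc(rng)
        model = allometric_regression(proc)
        assert model.groups["all"].r_squared == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            model.groups["all"].coefficients, beta.ravel(), atol=1e-8
        )
        # predicted extreme shapes are evaluated at the observed size range
        np.testing.assert_allclose(
            model.groups["all"].predicted_max_shape,
            proc.aligned[np.argmax(sizes)], atol=1e-8,
        )

    def test_size_independent_shapes_have_tiny_r2(self, rng):
        base = rng.normal(size=(8, 3))
        vals = []
        for rep in range(20):
            rng2 = np.random.default_rng(rep)
            sizes = rng2.uniform(50, 150, size=100)
            stack = np.array([
                (base + rng2.normal(0, 0.05, base.shape)) * s for s in sizes
            ])
            proc = gpa(make_specimen_set(stack), scale=True)
            vals.append(allometric_regression(proc).groups["all"].r_squared)
        assert np.mean(vals) <= 3 / 99

    def test_coefficients_match_per_variable_ols_oracle(self, rng):
        # noisy data through the real GPA path; oracle fits each coordinate
        # separately with numpy.polyfit
        base = rng.normal(size=(8, 3))
        sizes = rng.uniform(50, 150, size=30)
        stack = np.array([
            base * s + rng.normal(0, 0.5, base.shape) for s in sizes
        ])
        proc = gpa(make_specimen_set(stack), scale=True)
        model = allometric_regression(proc)
        flat = proc.aligned.reshape(len(stack), -1)
        oracle = np.array([
            np.polyfit(proc.centroid_sizes, flat[:, j], 1)[0] for j in range(flat.shape[1])
        ])
        np.testing.assert_allclose(model.groups["all"].coefficients, oracle, atol=1e-10)

    def test_constant_predictor_rejected(self, rng):
        base = rng.normal(size=(6, 3))
        stack = np.array([base + rng.normal(0, 0.01, base.shape) for _ in range(5)])
        proc = gpa(make_specimen_set(stack), scale=True)
        object.__setattr__(proc, "centroid_sizes", np.ones(5))
        with pytest.raises(SingularGeometryError):
            allometric_regression(proc)


class TestTrajectoryAngle:
    def test_closed_form_cases(self):
        v = np.array([1.0, 0.0, 0.0])
        assert trajectory_angle(v, v) == pytest.approx(0.0, abs=1e-12)
        assert trajectory_angle(v, np.array([0.0, 1.0, 0.0])) == pytest.approx(90.0)
        assert trajectory_angle(v, -v) == pytest.approx(180.0)

    def test_constructed_rotation_angle(self):
        v = np.array([2.0, 0.0, 0.0])
        theta = np.radians(25.0)
        u = np.array([np.cos(theta), np.sin(theta), 0.0]) * 0.7
        assert trajectory_angle(v, u) == pytest.approx(25.0, abs=1e-9)
        assert trajectory_angle(u, v) == pytest.approx(25.0, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(SingularGeometryError):
            trajectory_angle(np.zeros(3), np.ones(3))


class TestAnglePermutationTest:
    def test_reproducible_and_in_range(self, null_small):
        specimens, _ = null_small
        proc = gpa(specimens, scale=True)
        labels = np.asarray(specimens.sex, dtype=object)
        a1, p1 = angle_permutation_test(proc, labels, n_perm=49, seed=3)
        a2, p2 = angle_permutation_test(proc, labels, n_perm=49, seed=3)
        assert (a1, p1) == (a2, p2)
        assert 0 < p1 <= 1

    def test_planted_divergence_is_significant(self):
        spec = SyntheticSpec(
            n_points=60, n_per_group=(40, 40), allometry_strength=0.1,
            allometry_angle_deg=60.0, noise_sd=0.01, size_means=(780.0, 780.0),
            size_sds=(60.0, 60.0), seed=4,
        )
        specimens, _ = simulate(spec)
        proc = gpa(specimens, scale=True)
        angle, p = angle_permutation_test(
            proc, np.asarray(specimens.sex, dtype=object), n_perm=99, seed=5,
            log_predictor=True,
        )
        assert angle == pytest.approx(60.0, abs=5.0)
        assert p <= 0.01
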