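"""PCA / ANOVA selection / LDA against independent oracles, and the
cross-validation driver's leakage and bookkeeping contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bonescatter as bs
from bonescatter import (
    CohortMatrix,
    CohortTable,
    PCLDA,
    anova_select,
    cross_validate,
    fit_lda,
    fit_pca,
    subset_by_sex,
)


def _table(groups, sexes=None, patients=None):
    n = len(groups)
    sexes = sexes or ["male"] * n
    patients = patients or [f"p{i}" for i in range(n)]
    return CohortTable(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "patient_id": patients,
                "group": groups,
                "sex": sexes,
                "age": [70] * n,
            }
        )
    )


def _toy_matrix(n_pos=10, n_neg=10, channels=30, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(channels)
    direction /= np.linalg.norm(direction)
    X = rng.standard_normal((n_pos + n_neg, channels))
    X[:n_pos] += sep * direction
    groups = ["fracture"] * n_pos + ["non_fracture"] * n_neg
    return CohortMatrix(
        matrix=X,
        channel_grid=np.arange(float(channels)),
        table=_table(groups),
    )


class TestFitPCA:
    def test_reconstruction_matches_eigendecomposition(self, rng):
        X = rng.standard_normal((20, 50))
        X -= X.mean(axis=0)
        loadings, var, scores = fit_pca(X)
        assert loadings.shape == (50, 19)
        np.testing.assert_allclose(scores @ loadings.T, X, atol=1e-8)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(19), atol=1e-8)
        assert np.all(np.diff(var) <= 1e-12)
        # eigenvalues of the sample covariance agree
        eig = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1][:19]
        np.testing.assert_allclose(var, eig, atol=1e-8)

    def test_agrees_with_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.decomposition")
        X = rng.standard_normal((15, 40))
        X -= X.mean(axis=0)
        loadings, var, _ = fit_pca(X, max_components=5)
        ref = sk.PCA(n_components=5).fit(X)
        np.testing.assert_allclose(var, ref.explained_variance_, atol=1e-8)
        for j in range(5):
            dot = abs(loadings[:, j] @ ref.components_[j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_rank_one_recovers_direction(self, rng):
        u = rng.standard_normal(12)
        u -= u.mean()
        v = rng.standard_normal(25)
        X = np.outer(u, v)
        loadings, var, _ = fit_pca(X)
        assert var[0] > 1e-6 and np.all(var[1:] < 1e-12)
        cos = abs(loadings[:, 0] @ (v / np.linalg.norm(v)))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_non_centred_input_rejected(self, rng):
        X = rng.standard_normal((10, 5)) + 3.0
        with pytest.raises(ValueError, match="centred"):
            fit_pca(X)

    def test_symmetric_toy_has_equal_eigenvalues(self):
        X = np.array([[-1.0, -1.0], [1.0, 1.0], [-1.0, 1.0], [1.0, -1.0]])
        _loadings, var, scores = fit_pca(X)
        assert var[0] == pytest.approx(var[1], rel=1e-12)
        cov = np.cov(scores.T)
        assert abs(cov[0, 1]) < 1e-10


class TestAnovaSelect:
    def test_identical_groups_give_zero_f(self):
        scores = np.concatenate([np.arange(5.0), np.arange(5.0)]).reshape(-1, 1)
        labels = np.array(["fracture"] * 5 + ["non_fracture"] * 5)
        F, p, selected = anova_select(scores, labels)
        assert F[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)
        assert selected.size == 0

    def test_f_equals_squared_t_and_matches_scipy(self, rng):
        a = rng.standard_normal((8, 6))
        b = rng.standard_normal((11, 6)) + 0.8
        scores = np.vstack([a, b])
        labels = np.array(["fracture"] * 8 + ["non_fracture"] * 11)
        F, p, _ = anova_select(scores, labels)
        for j in range(6):
            t = stats.ttest_ind(a[:, j], b[:, j], equal_var=True)
            assert F[j] == pytest.approx(t.statistic**2, abs=1e-10)
            f_ref = stats.f_oneway(a[:, j], b[:, j])
            assert F[j] == pytest.approx(f_ref.statistic, abs=1e-10)
            assert p[j] == pytest.approx(f_ref.pvalue, abs=1e-10)

    def test_type_one_error_rate_near_alpha(self):
        # null scores: selection of a PC is a false positive at rate ~alpha
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 200
        for _ in range(reps):
            scores = rng.standard_normal((24, 1))
            labels = np.array(["fracture"] * 12 + ["non_fracture"] * 12)
            _, _, sel = anova_select(scores, labels, alpha=0.05)
            hits += sel.size
        # binomial(200, 0.05): central 99.9% region is roughly [1, 21]
        assert 1 <= hits <= 21

    def test_tiny_group_rejected(self):
        labels = np.array(["fracture", "non_fracture", "non_fracture"])
        with pytest.raises(ValueError, match="at least 2"):
            anova_select(np.zeros((3, 1)), labels)


class TestFitLDA:
    def test_one_dimensional_closed_form(self):
        scores = np.array([[2.0], [2.2], [0.0], [0.2]])
        labels = np.array(["fracture", "fracture", "non_fracture", "non_fracture"])
        w, threshold = fit_lda(scores, labels)
        # fracture projects negative: w = -1, threshold = -(2.1+0.1)/2
        assert w[0] == pytest.approx(-1.0)
        assert threshold == pytest.approx(-1.1)
        proj = scores @ w
        pred = np.where(proj < threshold, "fracture", "non_fracture")
        assert (pred == labels).all()

    def test_isotropic_covariance_aligns_with_mean_difference(self, rng):
        mu = np.array([2.0, -1.0, 0.5])
        a = rng.standard_normal((400, 3)) + mu
        b = rng.standard_normal((400, 3))
        X = np.vstack([a, b])
        labels = np.array(["fracture"] * 400 + ["non_fracture"] * 400)
        w, _ = fit_lda(X, labels)
        cos = (w @ mu) / np.linalg.norm(mu)
        assert abs(cos) > 0.99

    def test_direction_maximizes_fisher_criterion(self, rng):
        # brute-force scan of unit vectors in the plane, 0.05 degree grid
        a = rng.standard_normal((30, 2)) @ np.array([[1.0, 0.6], [0.0, 0.8]])
        b = rng.standard_normal((30, 2)) @ np.array([[1.2, 0.1], [0.3, 0.7]]) + [1.5, 0.8]
        X = np.vstack([a, b])
        labels = np.array(["fracture"] * 30 + ["non_fracture"] * 30)
        w, _ = fit_lda(X, labels)

        def fisher(v):
            pa, pb = a @ v, b @ v
            between = (pa.mean() - pb.mean()) ** 2
            within = pa.var(ddof=1) * 29 + pb.var(ddof=1) * 29
            return between / within

        angles = np.radians(np.arange(0.0, 180.0, 0.05))
        vals = [fisher(np.array([np.cos(t), np.sin(t)])) for t in angles]
        best = angles[int(np.argmax(vals))]
        w_angle = np.arctan2(w[1], w[0]) % np.pi
        delta = abs(np.degrees(best - w_angle)) % 180
        assert min(delta, 180 - delta) < 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_lda(np.zeros((3, 1)), np.array(["fracture"] * 3))


class TestModelFitAndPredict:
    def test_training_group_means_classified_correctly(self):
        m = _toy_matrix()
        res = PCLDA(m).fit()
        pos_mean = m.matrix[m.labels == "fracture"].mean(axis=0)
        neg_mean = m.matrix[m.labels == "non_fracture"].mean(axis=0)
        _, pred = res.predict(np.vstack([pos_mean, neg_mean]))
        assert pred.tolist() == ["fracture", "non_fracture"]

    def test_cohort_mean_scores_at_centred_origin(self):
        m = _toy_matrix()
        res = PCLDA(m).fit()
        s, _ = res.predict(res.mean_spectrum)
        assert s[0] == pytest.approx(0.0, abs=1e-10)

    def test_projection_matches_straight_line_reimplementation(self):
        m = _toy_matrix(seed=3)
        res = PCLDA(m).fit()
        X = np.random.default_rng(9).standard_normal((20, m.matrix.shape[1]))
        manual = ((X - res.mean_spectrum) @ res.loadings[:, res.selected]) @ res.ld_weights
        np.testing.assert_allclose(res.decision_scores(X), manual, atol=1e-12)

    def test_loadings_orthonormal_and_variance_sorted(self):
        res = PCLDA(_toy_matrix()).fit()
        k = res.loadings.shape[1]
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(k), atol=1e-8
        )
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_channel_mismatch_rejected(self):
        res = PCLDA(_toy_matrix()).fit()
        with pytest.raises(ValueError, match="mismatch"):
            res.predict(np.zeros(7))

    def test_agrees_with_sklearn_lda_predictions(self):
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        m = _toy_matrix(n_pos=15, n_neg=15, sep=2.0, seed=4)
        res = PCLDA(m).fit()
        sel_scores = (m.matrix - res.mean_spectrum) @ res.loadings[:, res.selected]
        ref = sk.LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(
            sel_scores, m.labels
        )
        _, pred = res.predict(m.matrix)
        assert (pred == ref.predict(sel_scores)).mean() == 1.0

    def test_summary_reports_selection(self):
        res = PCLDA(_toy_matrix()).fit()
        text = res.summary()
        assert "selected" in text and "threshold" in text


class TestCrossValidate:
    def test_confusion_bookkeeping(self):
        m = _toy_matrix(n_pos=8, n_neg=9, sep=3.0)
        cv = cross_validate(m)
        c = cv.confusion
        assert c["TP"] + c["FN"] == 8
        assert c["TN"] + c["FP"] == 9
        assert len(cv.records) == 17
        assert cv.records["sample_id"].is_unique
        assert cv.records["fold"].nunique() == 17

    def test_definitional_rates(self):
        records = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(108)],
                "patient_id": "p",
                "true_group": ["fracture"] * 54 + ["non_fracture"] * 54,
                "ld_score": 0.0,
                "predicted": ["fracture"] * 50 + ["non_fracture"] * 4
                + ["non_fracture"] * 49 + ["fracture"] * 5,
                "fold": range(108),
            }
        )
        cv = bs.CVResult(records=records, mode="leave_one_sample_out")
        assert cv.confusion == {"TP": 50, "FN": 4, "TN": 49, "FP": 5}
        assert cv.sensitivity == pytest.approx(92.59, abs=0.01)
        assert cv.specificity == pytest.approx(90.74, abs=0.01)

    def test_patient_mode_folds_and_integrity(self):
        groups = ["fracture"] * 6 + ["non_fracture"] * 6
        patients = ["pa"] * 3 + ["pb"] * 3 + [f"q{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 20))
        X[:6] += 2.5
        m = CohortMatrix(
            matrix=X,
            channel_grid=np.arange(20.0),
            table=_table(groups, patients=patients),
        )
        cv = cross_validate(m, mode="patient")
        assert cv.records["fold"].nunique() == 8  # 2 fracture + 6 donors
        # all samples of a patient share a fold
        per = cv.records.groupby("patient_id")["fold"].nunique()
        assert (per == 1).all()

    def test_separable_cohort_is_perfect(self):
        m = _toy_matrix(n_pos=10, n_neg=10, sep=12.0)
        cv = cross_validate(m)
        assert cv.sensitivity == 100.0 and cv.specificity == 100.0

    def test_rates_invariant_under_row_shuffle(self):
        m = _toy_matrix(n_pos=9, n_neg=9, sep=2.0, seed=8)
        perm = np.random.default_rng(5).permutation(18)
        shuffled = m.subset(perm)
        a, b = cross_validate(m), cross_validate(shuffled)
        assert a.sensitivity == b.sensitivity
        assert a.specificity == b.specificity

    def test_fold_losing_a_group_rejected(self):
        m = _toy_matrix(n_pos=2, n_neg=5)
        with pytest.raises(ValueError, match="fewer than 2"):
            cross_validate(m)


class TestSubsetBySex:
    def _matrix_with_sexes(self):
        rng = np.random.default_rng(1)
        groups = ["fracture"] * 8 + ["non_fracture"] * 8
        sexes = (["male"] * 4 + ["female"] * 4) * 2
        return CohortMatrix(
            matrix=rng.standard_normal((16, 10)),
            channel_grid=np.arange(10.0),
            table=_table(groups, sexes=sexes),
        )

    def test_partition_reunites_cohort(self):
        m = self._matrix_with_sexes()
        male = subset_by_sex(m, "male")
        female = subset_by_sex(m, "female")
        assert len(male.table) + len(female.table) == len(m.table)
        ids = set(male.table.table["sample_id"]) | set(female.table.table["sample_id"])
        assert ids == set(m.table.table["sample_id"])

    def test_study_design_sex_counts(self, study_matrix):
        male = subset_by_sex(study_matrix, "male")
        counts = male.table.counts()
        assert counts["fracture"]["samples"] == 18
        assert counts["non_fracture"]["samples"] == 27

    def test_missing_sex_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            subset_by_sex(self._matrix_with_sexes(), "unknown")
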