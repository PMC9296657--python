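"""Classification workflow: LDA against closed-form and sklearn oracles,
LOOCV semantics, ROC/AUC pair-counting equivalence, PCA structure."""

import itertools

import numpy as np
import pandas as pd
import pytest

from natremri import biomarker as bm
from natremri import synth

FEATURES = ["max_na_norm", "adc"]


def table_from_arrays(x, labels, features=("f1", "f2")):
    x = np.atleast_2d(np.asarray(x, float))
    df = pd.DataFrame(x, columns=list(features)[: x.shape[1]])
    df["region"] = labels
    df["subject"] = [f"s{i}" for i in range(len(df))]
    return df


def lda_oracle_predict(x_train, y_train, x_new):
    """Closed-form Gaussian discriminant with pooled covariance: independent
    route used to check the package's LDA predictions."""
    classes = [bm.NEGATIVE, bm.POSITIVE]
    x_train = np.atleast_2d(x_train)
    mus = [x_train[y_train == c].mean(axis=0) for c in classes]
    n = len(x_train)
    pooled = sum(
        (x_train[y_train == c] - mu).T @ (x_train[y_train == c] - mu)
        for c, mu in zip(classes, mus)
    ) / (n - 2)
    priors = [np.mean(y_train == c) for c in classes]
    inv = np.linalg.inv(np.atleast_2d(pooled))
    out = []
    for x in np.atleast_2d(x_new):
        deltas = [
            x @ inv @ mu - 0.5 * mu @ inv @ mu + np.log(pi)
            for mu, pi in zip(mus, priors)
        ]
        out.append(classes[int(np.argmax(deltas))])
    return np.array(out)


def auc_pair_oracle(scores, labels):
    """Mann-Whitney pair-win fraction with ties counted 1/2."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos
        for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestLDAFit:
    def test_one_dim_threshold_near_midpoint(self):
        rng = np.random.default_rng(0)
        n = 4000
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(10, 1, n)])
        y = np.array([bm.NEGATIVE] * n + [bm.POSITIVE] * n)
        tbl = table_from_arrays(x[:, None], y)
        model = bm.fit_lda(tbl, ["f1"])
        grid = np.linspace(3, 7, 4001)[:, None]
        pred = model.predict(grid)
        boundary = grid[np.argmax(pred == bm.POSITIVE), 0]
        assert boundary == pytest.approx(5.0, abs=0.15)

    def test_duplicate_features_raise_singularity(self, cohort):
        tbl = cohort.copy()
        tbl["dup"] = tbl["max_na_norm"]
        with pytest.raises(np.linalg.LinAlgError, match="standardise|singular"):
            bm.fit_lda(tbl, ["max_na_norm", "dup"])

    def test_toy_set_matches_closed_form_oracle(self):
        x = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]])
        y = np.array([bm.NEGATIVE] * 3 + [bm.POSITIVE] * 3)
        tbl = table_from_arrays(x, y)
        model = bm.fit_lda(tbl, ["f1", "f2"])
        probe = np.array([[0.5, 0.5], [5.5, 5.5], [2.5, 2.5], [3.0, 2.0], [1.0, 4.0]])
        assert (model.predict(probe) == lda_oracle_predict(x, y, probe)).all()

    def test_posteriors_sum_to_one(self, cohort):
        model = bm.fit_lda(cohort, FEATURES)
        post = model.posterior(cohort[FEATURES].to_numpy())
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_matches_sklearn(self, cohort):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        model = bm.fit_lda(cohort, FEATURES)
        X = cohort[FEATURES].to_numpy()
        sk = sklearn.LinearDiscriminantAnalysis().fit(X, cohort["region"])
        assert (model.predict(X) == sk.predict(X)).all()
        col = list(sk.classes_).index(bm.POSITIVE)
        assert np.allclose(model.positive_score(X), sk.predict_proba(X)[:, col],
                           atol=1e-6)

    def test_parameter_recovery_large_n(self):
        spec = synth.CohortSpec(n_subjects=500, seed=13)
        tbl = synth.generate_cohort(spec)
        model = bm.fit_lda(tbl, FEATURES)
        idx = model.classes.index(bm.POSITIVE)
        se = np.sqrt(np.diag(spec.tumour_cov) / spec.n_subjects)
        assert np.all(np.abs(model.means[idx] - spec.tumour_mean) < 3 * se)
        # pooled covariance within 10% Frobenius of the shared generating scale
        avg_cov = 0.5 * (np.asarray(spec.tumour_cov) + np.asarray(spec.non_tumour_cov))
        rel = np.linalg.norm(model.pooled_cov - avg_cov) / np.linalg.norm(avg_cov)
        assert rel < 0.10

    def test_serialisation_round_trip(self, cohort, tmp_path):
        model = bm.fit_lda(cohort, FEATURES)
        model.to_json(tmp_path / "lda.json")
        back = bm.LDAModel.from_json(tmp_path / "lda.json")
        X = cohort[FEATURES].to_numpy()
        assert (model.predict(X) == back.predict(X)).all()


class TestLOOCV:
    def test_separable_classes_are_perfect(self):
        x = np.concatenate([np.random.default_rng(1).normal(0, 0.1, 10),
                            np.random.default_rng(2).normal(50, 0.1, 10)])
        y = np.array([bm.NEGATIVE] * 10 + [bm.POSITIVE] * 10)
        rep = bm.loocv(table_from_arrays(x[:, None], y), ["f1"])
        assert rep.accuracy == 1.0

    def test_four_point_layout_matches_hand_enumeration(self):
        """XOR-like 1-D layout N T N T: every held-out point sits inside the
        other class's span, so enumerating the 4 folds by hand gives 0/4."""
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([bm.NEGATIVE, bm.POSITIVE, bm.NEGATIVE, bm.POSITIVE])
        tbl = table_from_arrays(x, y)
        expected = []
        for i in range(4):
            keep = np.arange(4) != i
            expected.append(
                lda_oracle_predict(x[keep], y[keep], x[i : i + 1])[0] == y[i]
            )
        rep = bm.loocv(tbl, ["f1"])
        assert rep.accuracy == np.mean(expected)

    def test_shuffled_labels_near_majority_rate(self):
        """Labels independent of features: mean LOOCV accuracy over several
        permutations within 5 points of the majority-class rate at n = 400."""
        rng = np.random.default_rng(7)
        tbl = synth.generate_cohort(synth.CohortSpec(n_subjects=200, seed=5))
        accs, majorities = [], []
        for _ in range(5):
            shuffled = tbl.copy()
            shuffled["region"] = rng.permutation(tbl["region"].to_numpy())
            accs.append(bm.loocv(shuffled, FEATURES).accuracy)
            majorities.append(
                max(
                    (shuffled["region"] == bm.POSITIVE).mean(),
                    (shuffled["region"] == bm.NEGATIVE).mean(),
                )
            )
        assert abs(np.mean(accs) - np.mean(majorities)) <= 0.05

    def test_loocv_tracks_test_accuracy_as_n_grows(self):
        gaps = {}
        for n in (15, 150):
            tr = synth.generate_cohort(synth.CohortSpec(n_subjects=n, seed=61))
            te = synth.generate_cohort(synth.CohortSpec(n_subjects=500, seed=62))
            cv = bm.loocv(tr, FEATURES).accuracy
            test = bm.evaluate_on_test(bm.fit_lda(tr, FEATURES), te).accuracy
            gaps[n] = abs(cv - test)
        assert gaps[150] <= gaps[15] + 0.05


class TestTestSetEvaluation:
    def test_resubstitution_matches_on_separable_data(self):
        jitter = np.linspace(-0.1, 0.1, 6)
        x = np.concatenate([jitter, 10.0 + jitter])
        y = np.array([bm.NEGATIVE] * 6 + [bm.POSITIVE] * 6)
        tbl = table_from_arrays(x[:, None], y)
        model = bm.fit_lda(tbl, ["f1"])
        rep = bm.evaluate_on_test(model, tbl)
        assert rep.accuracy == 1.0 and rep.tp == 6 and rep.tn == 6

    def test_label_swap_swaps_sensitivity_specificity(self, cohort):
        model = bm.fit_lda(cohort, FEATURES)
        test = synth.generate_cohort(synth.CohortSpec(seed=77))
        rep = bm.evaluate_on_test(model, test)
        swapped = test.copy()
        swapped["region"] = swapped["region"].map(
            {bm.POSITIVE: bm.NEGATIVE, bm.NEGATIVE: bm.POSITIVE}
        )
        rep_sw = bm.evaluate_on_test(model, swapped)
        assert rep_sw.sensitivity == pytest.approx(1.0 - rep.specificity)
        assert rep_sw.specificity == pytest.approx(1.0 - rep.sensitivity)

    def test_combined_model_at_least_as_good_as_single(self):
        """Median over 20 seeds: two-feature accuracy >= best single feature."""
        deltas = []
        for s in range(20):
            tr = synth.generate_cohort(synth.CohortSpec(seed=100 + s))
            te = synth.generate_cohort(synth.CohortSpec(seed=900 + s))
            accs = {
                feats: bm.evaluate_on_test(bm.fit_lda(tr, list(feats)), te).accuracy
                for feats in (("max_na_norm",), ("adc",), ("max_na_norm", "adc"))
            }
            deltas.append(
                accs[("max_na_norm", "adc")]
                - max(accs[("max_na_norm",)], accs[("adc",)])
            )
        assert np.median(deltas) >= 0.0

    def test_feature_mismatch_rejected(self, cohort):
        model = bm.fit_lda(cohort, FEATURES)
        bad = cohort.rename(columns={"adc": "something_else"})
        with pytest.raises(ValueError):
            bm.evaluate_on_test(model, bad)

    def test_confusion_matrix_identities(self, cohort):
        model = bm.fit_lda(cohort, FEATURES)
        rep = bm.evaluate_on_test(model, synth.generate_cohort(synth.CohortSpec(seed=3)))
        assert rep.accuracy == (rep.tp + rep.tn) / rep.n
        assert rep.confusion_matrix.sum() == rep.n


class TestROC:
    def test_perfect_ranking(self):
        _, auc = bm.roc_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert auc == 1.0

    def test_known_example(self):
        _, auc = bm.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        _, auc = bm.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_exhaustive_small_datasets_match_pair_oracle(self):
        """All labelings and a score grid for n <= 6: trapezoid AUC equals the
        Mann-Whitney pair-count, ties counted 1/2."""
        score_grid = [0.0, 0.25, 0.5, 0.5, 0.75, 1.0]
        for n in range(2, 7):
            for labels in itertools.product([0, 1], repeat=n):
                if len(set(labels)) < 2:
                    continue
                for scores in itertools.combinations_with_replacement(score_grid, n):
                    _, auc = bm.roc_auc(list(scores), list(labels))
                    assert auc == pytest.approx(
                        auc_pair_oracle(scores, labels), abs=1e-12
                    )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        _, a1 = bm.roc_auc(scores, labels)
        _, a2 = bm.roc_auc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            bm.roc_auc([0.1, 0.2], [1, 1])

    def test_curve_monotone(self, cohort):
        model = bm.fit_lda(cohort, FEATURES)
        rep = bm.evaluate_on_test(model, synth.generate_cohort(synth.CohortSpec(seed=9)))
        assert np.all(np.diff(rep.roc_points[:, 0]) >= 0)
        assert np.all(np.diff(rep.roc_points[:, 1]) >= 0)


class TestPCA:
    def test_collinear_data_single_component(self):
        x = np.arange(10.0)
        tbl = table_from_arrays(np.column_stack([x, 2 * x]), ["tumour"] * 10)
        res = bm.pca(tbl, ["f1", "f2"], scaling="covariance")
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_correlation_eigenvalues_closed_form(self, rng):
        """Standardised 2-D data: eigenvalues are 1 + r and 1 - r."""
        n = 3000
        r_target = 0.6
        z = rng.multivariate_normal([0, 0], [[1, r_target], [r_target, 1]], n)
        tbl = table_from_arrays(z, ["tumour"] * n)
        res = bm.pca(tbl, ["f1", "f2"], scaling="correlation")
        r_emp = np.corrcoef(z.T)[0, 1]
        total = 2.0
        assert res.explained_variance_ratio[0] == pytest.approx(
            (1 + abs(r_emp)) / total, abs=1e-9
        )

    def test_anticorrelated_features_oppose_on_pc1(self, cohort):
        res = bm.pca(cohort, FEATURES)
        assert res.loadings[0, 0] * res.loadings[1, 0] < 0

    def test_loadings_orthonormal_and_ratios_sum_to_one(self, cohort):
        res = bm.pca(cohort, FEATURES)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(2), atol=1e-10)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_zero_variance_feature_rejected(self):
        tbl = table_from_arrays(
            np.column_stack([np.ones(5), np.arange(5.0)]), ["tumour"] * 5
        )
        with pytest.raises(ValueError):
            bm.pca(tbl, ["f1", "f2"], scaling="correlation")

    def test_concentration_ellipse_coverage(self, rng):
        pts = rng.multivariate_normal([1, 2], [[2, 0.8], [0.8, 1]], 20000)
        centre, semi, angle = bm.concentration_ellipse(pts, level=0.95)
        rot = np.array([[np.cos(angle), np.sin(angle)], [-np.sin(angle), np.cos(angle)]])
        local = (pts - centre) @ rot.T
        inside = np.mean(np.sum((local / semi) ** 2, axis=1) <= 1.0)
        assert inside == pytest.approx(0.95, abs=0.01)
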