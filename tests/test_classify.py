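"""PCA-LDA staging: oracles for Fisher direction, ROC/AUC, ellipses."""

import numpy as np
import pytest

from fluorostage.classify import (
    DegenerateDataError,
    PairwiseLDAModel,
    classify_dataset,
    confusion_ellipse_analysis,
    evaluate_pair,
    fit_lda_pairwise,
    fit_pca,
    roc_curve,
    train_validation_split,
)


class TestPCA:
    def test_identical_spectra_rejected(self):
        matrix = np.tile(np.linspace(0, 1, 20), (5, 1))
        with pytest.raises(DegenerateDataError):
            fit_pca(matrix)

    def test_near_collinear_data_dominated_by_first_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=100)
        matrix = np.column_stack([t, 2 * t]) + rng.normal(scale=1e-4, size=(100, 2))
        model = fit_pca(matrix)
        assert model.explained_variance_fractions[0] > 0.99

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        matrix = rng.normal(size=(6, 4))
        model = fit_pca(matrix, variance_threshold=1.0, min_components=4)
        centered = matrix - model.mean_spectrum
        reconstructed = model.transform(matrix) @ model.loadings
        assert np.allclose(reconstructed, centered, atol=1e-9)

    def test_loadings_orthonormal_fractions_nonincreasing(self, staging_result):
        loadings = staging_result.pca.loadings
        gram = loadings @ loadings.T
        assert np.allclose(gram, np.eye(loadings.shape[0]), atol=1e-9)
        fractions = staging_result.pca.explained_variance_fractions
        assert np.all(np.diff(fractions) <= 1e-12)
        assert np.all((fractions > 0) & (fractions <= 1))


class TestPairwiseLDA:
    def two_cluster_scores(self, gap=10.0, n=20, seed=0):
        rng = np.random.default_rng(seed)
        neg = rng.normal(-gap / 2, 0.1, size=(n, 2))
        pos = rng.normal(gap / 2, 0.1, size=(n, 2))
        scores = np.vstack([neg, pos])
        labels = np.array(["control"] * n + ["mild"] * n, dtype=object)
        return scores, labels

    def test_separated_clusters_classified_at_zero_cutoff(self):
        scores, labels = self.two_cluster_scores()
        model = fit_lda_pairwise(scores, labels, pair=("control", "mild"))
        assert model.positive_class == "mild"
        report = evaluate_pair(model, scores, labels, "training")
        assert report.sensitivity == 100.0 and report.specificity == 100.0

    def test_class_mean_scores_symmetric_about_zero(self):
        scores, labels = self.two_cluster_scores(seed=3)
        model = fit_lda_pairwise(scores, labels, pair=("control", "mild"))
        out = model.decision_scores(scores)
        mean_neg = out[labels == "control"].mean()
        mean_pos = out[labels == "mild"].mean()
        assert abs(mean_neg + mean_pos) < 1e-9

    def test_swapping_pair_orientation_negates_weights(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(30, 3))
        labels = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        scores[labels == "b"] += 1.0
        fwd = fit_lda_pairwise(scores, labels, pair=("a", "b"))
        rev = fit_lda_pairwise(scores, labels, pair=("b", "a"))
        assert np.allclose(fwd.weight_vector, -rev.weight_vector)
        rep_f = evaluate_pair(fwd, scores, labels, "training")
        rep_r = evaluate_pair(rev, scores, labels, "training")
        assert rep_f.tp == rep_r.tn and rep_f.fn == rep_r.fp

    def test_fisher_direction_matches_angle_scan(self):
        # brute-force search over direction angle maximizing the
        # between/within variance ratio of the projected scores
        rng = np.random.default_rng(7)
        neg = rng.multivariate_normal([0, 0], [[2.0, 0.8], [0.8, 0.5]], size=200)
        pos = rng.multivariate_normal([1.5, 1.0], [[2.0, 0.8], [0.8, 0.5]], size=200)
        scores = np.vstack([neg, pos])
        labels = np.array(["control"] * 200 + ["moderate"] * 200, dtype=object)
        model = fit_lda_pairwise(scores, labels, pair=("control", "moderate"))

        def ratio(theta):
            w = np.array([np.cos(theta), np.sin(theta)])
            a, b = neg @ w, pos @ w
            between = (a.mean() - b.mean()) ** 2
            within = a.var(ddof=1) + b.var(ddof=1)
            return between / within

        thetas = np.linspace(0, np.pi, 36001)
        best = thetas[np.argmax([ratio(t) for t in thetas])]
        fitted = np.arctan2(model.weight_vector[1], model.weight_vector[0]) % np.pi
        delta = abs(np.degrees(best - fitted))
        assert min(delta, 180 - delta) < 0.5

    def test_singular_scatter_triggers_ridge_warning(self):
        scores = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        labels = np.array(["control", "control", "mild", "mild"], dtype=object)
        with pytest.warns(RuntimeWarning, match="ridge"):
            model = fit_lda_pairwise(scores, labels, pair=("control", "mild"))
        out = model.decision_scores(scores)
        assert (out[2:] > 0).all() and (out[:2] < 0).all()


class TestEvaluatePair:
    def make_model(self):
        return PairwiseLDAModel(
            pair=("mild", "reversal"),
            positive_class="mild",
            weight_vector=np.array([1.0]),
            offset=0.0,
        )

    def test_validation_misclassification_arithmetic(self):
        # 10 positives with 2 misclassified, 10 negatives with 1
        # misclassified -> Se 80%, Sp 90%
        model = self.make_model()
        pos_scores = np.array([1.0] * 8 + [-1.0] * 2)
        neg_scores = np.array([-1.0] * 9 + [1.0] * 1)
        scores = np.concatenate([pos_scores, neg_scores])[:, None]
        labels = np.array(["mild"] * 10 + ["reversal"] * 10, dtype=object)
        report = evaluate_pair(model, scores, labels, "validation")
        assert report.sensitivity == pytest.approx(80.0)
        assert report.specificity == pytest.approx(90.0)
        assert (report.tp, report.fn, report.tn, report.fp) == (8, 2, 9, 1)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=(50, 1))
        labels = rng.choice(["mild", "reversal"], size=50)
        labels[:2] = ["mild", "reversal"]  # both classes present
        model = self.make_model()
        report = evaluate_pair(model, scores, labels, "training")
        tp = sum(
            1 for s, l in zip(scores[:, 0], labels) if l == "mild" and s >= 0
        )
        fn = sum(1 for s, l in zip(scores[:, 0], labels) if l == "mild" and s < 0)
        tn = sum(
            1 for s, l in zip(scores[:, 0], labels) if l == "reversal" and s < 0
        )
        fp = sum(
            1 for s, l in zip(scores[:, 0], labels) if l == "reversal" and s >= 0
        )
        assert (report.tp, report.fn, report.tn, report.fp) == (tp, fn, tn, fp)

    def test_zero_score_goes_to_positive_class(self):
        model = self.make_model()
        scores = np.array([[0.0], [-0.1]])
        labels = np.array(["mild", "reversal"], dtype=object)
        report = evaluate_pair(model, scores, labels, "training")
        assert report.tp == 1 and report.tn == 1

    def test_foreign_label_rejected(self):
        model = self.make_model()
        with pytest.raises(ValueError, match="outside"):
            evaluate_pair(
                model,
                np.zeros((2, 1)),
                np.array(["mild", "control"], dtype=object),
                "training",
            )


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        points, auc = roc_curve(scores, labels, positive_class="b")
        assert auc == 1.0
        assert points[0].tolist() == [0.0, 0.0]
        assert points[-1].tolist() == [1.0, 1.0]

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=4000)
        labels = rng.choice(["a", "b"], size=4000)
        _, auc = roc_curve(scores, labels, positive_class="b")
        assert abs(auc - 0.5) < 0.03

    def test_auc_equals_mann_whitney_pair_count(self):
        rng = np.random.default_rng(17)
        # integer scores force ties across and within classes
        scores = rng.integers(0, 6, size=60).astype(float)
        labels = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
        scores[labels == "b"] += rng.integers(0, 3, size=30)
        _, auc = roc_curve(scores, labels, positive_class="b")
        pos = scores[labels == "b"]
        neg = scores[labels == "a"]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(19)
        scores = rng.normal(size=200)
        labels = np.where(rng.random(200) < 0.4, "b", "a").astype(object)
        scores[labels == "b"] += 0.8
        _, auc = roc_curve(scores, labels, positive_class="b")
        assert auc == pytest.approx(roc_auc_score(labels == "b", scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=100)
        labels = rng.choice(["a", "b"], size=100)
        labels[:2] = ["a", "b"]
        _, auc1 = roc_curve(scores, labels, positive_class="b")
        _, auc2 = roc_curve(np.exp(3 * scores), labels, positive_class="b")
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_roc_points_monotone(self, staging_result):
        for res in staging_result.pairs.values():
            points = res.merged_roc_points
            assert np.all(np.diff(points[:, 0]) >= 0)
            assert np.all(np.diff(points[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.array([1.0, 2.0]), np.array(["a", "a"]), "a")


class TestEllipses:
    def four_clusters(self, n=20, spread=0.05, seed=29):
        rng = np.random.default_rng(seed)
        centers = {
            "control": (0, 0),
            "mild": (10, 0),
            "moderate": (0, 10),
            "reversal": (10, 10),
        }
        scores, labels = [], []
        for group, center in centers.items():
            scores.append(rng.normal(center, spread, size=(n, 2)))
            labels.extend([group] * n)
        return np.vstack(scores), np.array(labels, dtype=object)

    def test_tight_clusters_diagonal_confusion(self):
        scores, labels = self.four_clusters()
        summary = confusion_ellipse_analysis(scores, labels)
        confusion = summary.confusion_matrix
        assert np.all(np.diag(confusion.to_numpy()) == 20)
        assert confusion.to_numpy().sum() == 80

    def test_centroid_equals_member_mean(self):
        scores, labels = self.four_clusters(seed=31)
        summary = confusion_ellipse_analysis(scores, labels)
        for group, ellipse in summary.ellipses.items():
            members = summary.coordinates[summary.labels == group]
            assert np.allclose(ellipse.centroid, members.mean(axis=0))

    def test_inside_flag_matches_mahalanobis_oracle(self):
        scores, labels = self.four_clusters(spread=1.0, seed=37)
        summary = confusion_ellipse_analysis(scores, labels)
        for group, ellipse in summary.ellipses.items():
            mask = summary.labels == group
            diff = summary.coordinates[mask] - ellipse.centroid
            inv = np.linalg.inv(ellipse.covariance)
            d2 = np.array([d @ inv @ d for d in diff])
            assert np.array_equal(summary.inside_own[mask], d2 <= 4.0)
            assert ellipse.n_inside == int((d2 <= 4.0).sum())

    def test_small_class_rejected(self):
        scores, labels = self.four_clusters(n=2)
        with pytest.raises(ValueError, match=">= 3"):
            confusion_ellipse_analysis(scores, labels)


class TestStagingRun:
    def test_split_sizes_and_disjointness(self, normalized_dataset):
        train, valid = train_validation_split(normalized_dataset, 50, 10, seed=17)
        assert train.group_counts == {g: 50 for g in train.group_counts}
        assert valid.group_counts == {g: 10 for g in valid.group_counts}
        assert not {s.spectrum_id for s in train} & {s.spectrum_id for s in valid}

    def test_validation_shuffle_does_not_change_model(self, normalized_dataset):
        train, valid = train_validation_split(normalized_dataset, 50, 10, seed=17)
        pca = fit_pca(train.intensity_matrix())
        pair = ("moderate", "reversal")
        sub = train.subset(pair)
        model = fit_lda_pairwise(pca.transform(sub.intensity_matrix()), sub.labels(), pair)
        vsub = valid.subset(pair)
        scores = pca.transform(vsub.intensity_matrix())
        labels = vsub.labels()
        report = evaluate_pair(model, scores, labels, "validation")
        perm = np.random.default_rng(0).permutation(len(labels))
        shuffled = evaluate_pair(model, scores[perm], labels[perm], "validation")
        assert (report.tp, report.fp, report.tn, report.fn) == (
            shuffled.tp,
            shuffled.fp,
            shuffled.tn,
            shuffled.fn,
        )

    def test_end_to_end_determinism(self):
        from fluorostage import generate_dataset, normalize_dataset

        def run():
            ds = normalize_dataset(generate_dataset(n_per_group=15, seed=5))
            res = classify_dataset(ds, n_train=10, n_valid=5, seed=5)
            return res.report_table()

        a, b = run(), run()
        assert a.equals(b)

    def test_report_table_shape(self, staging_result):
        table = staging_result.report_table()
        assert len(table) == 4 * 3  # four pairs x training/validation/overall
        assert set(table["role"]) == {"training", "validation", "overall"}
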