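import numpy as np
import pytest
import scipy.linalg

from paleomorph.classify import classify_holdout, lda_cv_confusion, lda_fit, pca
from paleomorph.logshape import ShapeMatrix, ShapeVector, log_shape_ratios
from paleomorph.morphodata import Clade, ValidationError


def matrix_from_array(X, clades, subset=None):
    X = np.asarray(X, dtype=float)
    subset = subset or tuple(f"v{i}" for i in range(X.shape[1]))
    return ShapeMatrix(
        subset=tuple(subset),
        specimen_ids=tuple(f"s{i}" for i in range(len(X))),
        clades=tuple(clades),
        values=X,
    )


def four_cluster_matrix(rng, n=12, sep=8.0, p=4):
    """Four well-separated Gaussian clusters, one per extant clade."""
    centers = sep * np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
    X, clades = [], []
    for c, clade in zip(centers, Clade.comparative()):
        pts = rng.normal(0, 0.3, size=(n, 2)) + c
        X.append(np.column_stack([pts] + [rng.normal(0, 0.3, size=(n, p - 2))]))
        clades += [clade] * n
    return matrix_from_array(np.vstack(X), clades)


class TestPCA:
    def test_hand_built_diagonal_covariance_fractions(self):
        # sample covariance exactly [[4/3, 0], [0, 2/3]]: fractions 2/3, 1/3
        X = np.array([[np.sqrt(2), 0], [-np.sqrt(2), 0], [0, 1], [0, -1]])
        res = pca(matrix_from_array(X, [Clade.MACAQUES] * 4))
        np.testing.assert_allclose(res.variance_fraction, [2 / 3, 1 / 3], atol=1e-12)

    def test_data_on_a_line_is_one_component(self):
        t = np.linspace(-1, 1, 6)
        X = np.column_stack([t, np.zeros_like(t)])
        res = pca(matrix_from_array(X, [Clade.MACAQUES] * 6))
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_fractions_sum_to_one_and_scores_uncorrelated(self, calibrated_matrix):
        res = pca(calibrated_matrix)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)
        k = np.sum(res.variance_fraction > 1e-10)
        corr = np.corrcoef(res.scores[:, :k].T)
        np.testing.assert_allclose(corr - np.diag(np.diag(corr)), 0.0, atol=1e-8)

    def test_fossil_excluded_from_decomposition_but_projected(self, calibrated_matrix):
        res = pca(calibrated_matrix)
        assert res.scores.shape[0] == len(calibrated_matrix) - 1
        assert res.fossil_ids == ("Trinil 5703",)
        assert res.fossil_scores.shape[1] == res.scores.shape[1]

    def test_zero_variance_matrix_is_error(self):
        X = np.ones((5, 3))
        with pytest.raises(ValidationError, match="zero variance"):
            pca(matrix_from_array(X, [Clade.MACAQUES] * 5))


class TestLDAFit:
    def test_two_separated_clusters_put_all_variance_on_ld1(self, rng):
        m = four_cluster_matrix(rng, sep=12.0)
        res = lda_fit(m)
        assert res.axis_variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.n_functions == 3
        confusion = lda_cv_confusion(m)
        np.testing.assert_array_equal(confusion.rounded(), 100 * np.eye(4, dtype=int))

    def test_axes_match_generalized_eigenproblem_oracle(self, calibrated_matrix):
        """Discriminant axes solve Sb w = lambda Sw w; compare the
        implementation against an independent scipy.linalg.eigh solve."""
        res = lda_fit(calibrated_matrix)
        X = calibrated_matrix.comparative[:, :-1]
        labels = calibrated_matrix.comparative_clades
        grand = X.mean(axis=0)
        Sw = np.zeros((X.shape[1], X.shape[1]))
        Sb = np.zeros_like(Sw)
        for clade in Clade.comparative():
            G = X[[l is clade for l in labels]]
            mu = G.mean(axis=0)
            Sw += (G - mu).T @ (G - mu)
            Sb += len(G) * np.outer(mu - grand, mu - grand)
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        # eigenvalue ratios -> axis variance fractions
        np.testing.assert_allclose(
            res.axis_variance_fraction, evals[:3] / evals[:3].sum(), atol=1e-8)
        # axes agree up to sign/scale: |cos angle| = 1
        for k in range(3):
            a, b = res.discriminant_axes[:, k], evecs[:, k]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_rescaling_all_variables_does_not_change_predictions(self, rng):
        m = four_cluster_matrix(rng, sep=3.0)
        scale = np.array([2.0, 0.5, 7.0, 1.5])
        m2 = matrix_from_array(m.values * scale, m.clades, m.subset)
        c1 = lda_cv_confusion(m)
        c2 = lda_cv_confusion(m2)
        np.testing.assert_array_equal(c1.counts, c2.counts)

    def test_too_few_specimens_per_clade_is_error(self, rng):
        m = four_cluster_matrix(rng, n=2)
        small = matrix_from_array(
            np.vstack([m.values[:2], m.values[2:3], m.values[4:6], m.values[6:8]]),
            [Clade.SMALL_APES] * 2 + [Clade.LANGURS] + [Clade.ODD_NOSED] * 2
            + [Clade.MACAQUES] * 2,
        )
        with pytest.raises(ValidationError, match="langurs"):
            lda_fit(small)


class TestConfusion:
    def test_rows_sum_to_100(self, calibrated_matrix):
        res = lda_cv_confusion(calibrated_matrix)
        np.testing.assert_allclose(res.row_percent.sum(axis=1), 100.0, atol=1e-9)
        assert np.all(np.abs(res.rounded().sum(axis=1) - 100) <= 2)  # rounding slack

    def test_counts_match_clade_sizes(self, calibrated_matrix):
        res = lda_cv_confusion(calibrated_matrix)
        np.testing.assert_array_equal(res.counts.sum(axis=1), [49, 18, 6, 28])

    def test_kfold_agrees_roughly_with_loo(self, calibrated_matrix):
        loo = lda_cv_confusion(calibrated_matrix)
        kf = lda_cv_confusion(calibrated_matrix, cv="kfold:5", seed=1)
        # same diagonal within 20 percentage points per clade
        assert np.all(np.abs(np.diag(loo.row_percent) - np.diag(kf.row_percent)) < 20)

    def test_shuffled_labels_classify_at_chance(self, rng):
        """With labels randomly permuted, each clade's row is statistically
        indistinguishable from the 25% chance level."""
        n = 60
        X = rng.normal(size=(4 * n, 5))
        clades = [c for c in Clade.comparative() for _ in range(n)]
        perm = rng.permutation(len(clades))
        m = matrix_from_array(X, [clades[i] for i in perm])
        res = lda_cv_confusion(m)
        # binomial sd at p=.25, n=60 is ~5.6 points; allow 4 sd
        assert np.all(np.abs(res.row_percent - 25.0) < 4 * 5.6)

    def test_fold_emptying_a_clade_is_error(self, rng):
        m = four_cluster_matrix(rng, n=2)
        with pytest.raises(ValidationError, match="kfold|empties|smaller"):
            lda_cv_confusion(m, cv="kfold:40")


class TestHoldout:
    def test_group_mean_classifies_to_its_group(self, calibrated_matrix):
        res = lda_fit(calibrated_matrix)
        X = calibrated_matrix.comparative
        labels = calibrated_matrix.comparative_clades
        for clade in Clade.comparative():
            mu = X[[l is clade for l in labels]].mean(axis=0)
            vec = ShapeVector(
                specimen_id="mean", clade=Clade.FOSSIL,
                subset=calibrated_matrix.subset, values=mu,
            )
            assert classify_holdout(vec, res)[0] is clade

    def test_fossil_receives_scores_on_all_functions(self, calibrated_matrix, trinil):
        res = lda_fit(calibrated_matrix)
        clade, scores = classify_holdout(log_shape_ratios(trinil), res)
        assert scores.shape == (3,)
        assert clade in Clade.comparative()

    def test_subset_mismatch_is_error(self, calibrated_matrix):
        res = lda_fit(calibrated_matrix)
        vec = ShapeVector(
            specimen_id="bad", clade=Clade.FOSSIL,
            subset=("a", "b", "c"), values=np.zeros(3),
        )
        with pytest.raises(ValidationError, match="subset"):
            classify_holdout(vec, res)

    def test_majority_recovery_of_generated_fossils(self, calibrated_matrix):
        """Synthetic hold-outs from each clade generator are assigned to
        their true clade far above the 25% chance level."""
        from paleomorph.synthetic_data import clade_spec_from_reference, gen_measurements

        res = lda_fit(calibrated_matrix)
        for s, clade in enumerate(Clade.comparative()):
            spec = clade_spec_from_reference(clade, n=60)
            fossils = gen_measurements(spec, seed=700 + s, drop_tl=True,
                                       clade_label=Clade.FOSSIL)
            hits = sum(
                classify_holdout(log_shape_ratios(f), res)[0] is clade
                for f in fossils
            )
            assert hits / 60 > 0.45  # >= majority-ish, chance is 0.25
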