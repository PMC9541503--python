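"""Shape-space PCA, PC selection, PERMANOVA and distributional screens."""

import numpy as np
import pytest

from dentmorph.outlines import LandmarkConfiguration, centroid_size, normalize_configuration
from dentmorph.shapespace import (ShapeSpaceModel, assumption_screen, fit_shape_pca,
                                  permanova_pairwise, pseudo_f, select_pcs)


def _configs_from_matrix(X):
    out = []
    for row in X:
        pts = row.reshape(-1, 2)
        out.append(LandmarkConfiguration(points=pts, centroid_size=1.0, normalized=True))
    return out


def _random_normalized_configs(n, rng):
    out = []
    for _ in range(n):
        pts = rng.normal(size=(16, 2))
        out.append(normalize_configuration(
            LandmarkConfiguration(points=pts, centroid_size=centroid_size(pts))))
    return out


class TestShapePCA:
    def test_single_direction_gives_pc1_everything(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=32)
        direction = rng.normal(size=32)
        X = base + np.linspace(-1, 1, 10)[:, None] * direction
        model = fit_shape_pca(_configs_from_matrix(X), ["a"] * 10)
        assert model.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(5)
        configs = _random_normalized_configs(12, rng)
        model = fit_shape_pca(configs, ["g"] * 12)
        X = np.vstack([c.flatten() for c in configs])
        recon = model.mean + model.training_scores @ model.eigenvectors.T
        np.testing.assert_allclose(recon, X, atol=1e-9)

    def test_eigenvalues_match_covariance_oracle(self):
        rng = np.random.default_rng(7)
        configs = _random_normalized_configs(25, rng)
        model = fit_shape_pca(configs, ["g"] * 25)
        X = np.vstack([c.flatten() for c in configs])
        oracle = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1]
        np.testing.assert_allclose(model.eigenvalues, oracle[: len(model.eigenvalues)],
                                   atol=1e-9)
        # total variance conserved
        assert model.eigenvalues.sum() == pytest.approx(
            np.sum(np.var(X, axis=0, ddof=1)), abs=1e-9)

    def test_unnormalized_input_rejected(self):
        pts = np.random.default_rng(1).normal(size=(16, 2))
        raw = LandmarkConfiguration(points=pts, centroid_size=centroid_size(pts))
        with pytest.raises(ValueError):
            fit_shape_pca([raw] * 3, ["a"] * 3)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(9)
        model = fit_shape_pca(_random_normalized_configs(10, rng), ["g"] * 10)
        assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)


class TestSelectPCs:
    def test_examples(self):
        def fake_model(eigenvalues):
            m = len(eigenvalues)
            return ShapeSpaceModel(mean=np.zeros(2 * m),
                                   eigenvectors=np.eye(2 * m)[:, :m],
                                   eigenvalues=np.array(eigenvalues, dtype=float),
                                   training_scores=np.zeros((3, m)), labels=["x"] * 3)

        assert select_pcs(fake_model([5.0, 0.0]), 0.9) == 1
        assert select_pcs(fake_model([4.0, 3.0, 2.0, 1.0]), 0.9) == 3  # exactly 0.9
        m = fake_model([4.0, 3.0, 2.0, 1.0])
        cum = np.cumsum(m.variance_fractions)
        for frac in (0.3, 0.5, 0.7, 0.95, 1.0):
            k = select_pcs(m, frac)
            assert cum[k - 1] >= frac - 1e-12
            assert k == 1 or cum[k - 2] < frac - 1e-12


class TestPermanova:
    def test_univariate_equals_classical_anova(self):
        from scipy.stats import f_oneway
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1.0, 1, 15)
        x = np.concatenate([a, b])[:, None]
        groups = np.array(["a"] * 12 + ["b"] * 15)
        f_perm = pseudo_f(squareform(pdist(x)), groups)
        f_classic = f_oneway(a, b).statistic
        assert f_perm == pytest.approx(f_classic, abs=1e-9)

    def test_exhaustive_enumeration_p_value(self):
        # two groups of 4, separated by 100x the within-group spread
        from itertools import combinations
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.01, size=(4, 3))
        b = rng.normal(1.0, 0.01, size=(4, 3))
        X = np.vstack([a, b])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        dist = squareform(pdist(X))
        f_obs = pseudo_f(dist, labels)
        # enumeration oracle over all C(8,4)=70 assignments
        count = 0
        for comb in combinations(range(8), 4):
            lab = np.array(["b"] * 8)
            lab[list(comb)] = "a"
            if pseudo_f(dist, lab) >= f_obs - 1e-12:
                count += 1
        exact_p = count / 70.0
        assert exact_p == pytest.approx(2.0 / 70.0)
        res = permanova_pairwise(X, labels, n_permutations=9999, seed=1)[0]
        assert res.p_raw == pytest.approx(exact_p, abs=0.01)

    def test_matches_skbio_oracle(self):
        import warnings
        from scipy.spatial.distance import pdist, squareform
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from skbio.stats.distance import DistanceMatrix, permanova as skbio_permanova

        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 4))
        X[10:] += 0.8
        labels = ["a"] * 10 + ["b"] * 10
        dist = squareform(pdist(X))
        ours = pseudo_f(dist, np.array(labels))
        theirs = skbio_permanova(DistanceMatrix(dist), labels, permutations=0)
        assert ours == pytest.approx(float(theirs["test statistic"]), abs=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(16, 5))
        labels = np.array(["a"] * 8 + ["b"] * 8)
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        r1 = permanova_pairwise(X, labels, n_permutations=99, seed=3)[0]
        r2 = permanova_pairwise(X @ q, labels, n_permutations=99, seed=3)[0]
        assert r1.F == pytest.approx(r2.F, abs=1e-9)
        assert r1.p_raw == r2.p_raw

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(14, 3))
        labels = np.array(["a"] * 7 + ["b"] * 7)
        r1 = permanova_pairwise(X, labels, n_permutations=499, seed=21)
        r2 = permanova_pairwise(X, labels, n_permutations=499, seed=21)
        assert r1[0].p_raw == r2[0].p_raw

    def test_bonferroni_over_pairs(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(3, 1, (6, 2)),
                       rng.normal(6, 1, (6, 2))])
        labels = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        res = permanova_pairwise(X, labels, n_permutations=199, seed=5)
        assert len(res) == 3
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 3))

    def test_small_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError):
            permanova_pairwise(X, np.array(["a", "a", "a", "a", "b"]), 99, 0)


class TestAssumptionScreen:
    def test_gaussian_null_pvalues_mostly_nonsignificant(self):
        rng = np.random.default_rng(14)
        hits = 0
        for _ in range(100):
            x = rng.normal(size=(50, 1))
            rep = assumption_screen(x, np.array(["g"] * 50))
            hits += rep.shapiro_p.iloc[0, 0] > 0.05
        assert hits >= 90

    def test_fligner_detects_variance_ratio(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 10, 40)
        rep = assumption_screen(np.concatenate([a, b])[:, None],
                                np.array(["a"] * 40 + ["b"] * 40))
        assert rep.fligner_p.iloc[0] < 0.01

    def test_constant_scores_flagged_not_crashing(self):
        x = np.zeros((10, 1))
        rep = assumption_screen(x, np.array(["a"] * 5 + ["b"] * 5))
        assert np.isnan(rep.shapiro_p.iloc[0, 0])
        assert rep.flags
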