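"""PCA, PERMANOVA, dispersion homogeneity and pairwise comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

import shrubrange as sr
from shrubrange.multivariate import adjust_pvalues, permanova_f, _squared_distances


class TestPCA:
    def test_perfectly_correlated_pair(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": x})
        res = sr.pca(X)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(res.loadings["PC1"].to_numpy(), [0.7071, 0.7071], atol=1e-4)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        res = sr.pca(X)
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - Z).max() < 1e-10

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        res = sr.pca(pd.DataFrame(rng.normal(size=(15, 3))))
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(res.variance_fraction) <= 1e-12).all()

    def test_matches_sklearn_decomposition(self):
        from sklearn.decomposition import PCA as SkPCA
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(12, 3)))
        ours = sr.pca(X)
        ref = SkPCA().fit(((X - X.mean()) / X.std(ddof=1)).to_numpy())
        assert np.allclose(ours.variance_fraction, ref.explained_variance_ratio_, atol=1e-10)
        assert np.allclose(np.abs(ours.loadings.to_numpy()),
                           np.abs(ref.components_.T), atol=1e-10)

    def test_sign_convention_pins_largest_loading_positive(self):
        rng = np.random.default_rng(10)
        res = sr.pca(pd.DataFrame(rng.normal(size=(20, 3))))
        L = res.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_missing_cells_name_species(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]},
                         index=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="s2"):
            sr.pca(X)

    def test_constant_column_rejected_when_scaling(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="a"):
            sr.pca(X)


def exhaustive_permanova_p(X, groups):
    """Brute-force oracle: exact permutation p over all distinct label
    assignments, independent of the sampled implementation."""
    labels = np.asarray(groups)
    d2 = _squared_distances(X, distance=False)
    observed = permanova_f(d2, labels)
    n = len(labels)
    stats = []
    # enumerate assignments of the first-group positions
    g1 = sorted(set(labels))[0]
    k = int((labels == g1).sum())
    for idx in itertools.combinations(range(n), k):
        perm = np.array([g1 if i in idx else "other" for i in range(n)], dtype=object)
        stats.append(permanova_f(d2, perm))
    stats = np.asarray(stats)
    return float((stats >= observed - 1e-12).mean()), float(observed)


class TestPermanova:
    def test_sampled_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(6, 2)) + np.array([[1.0, 0.0]] * 3 + [[0.0, 0.0]] * 3)
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        p_exact, f_exact = exhaustive_permanova_p(X, labels)
        res = sr.permanova(X, labels, permutations=999, seed=0)
        assert res.statistic == pytest.approx(f_exact, abs=1e-12)
        # add-one sampled estimator vs exact p, within ~3.5 binomial SDs
        tol = 3.5 * np.sqrt(p_exact * (1 - p_exact) / 999) + 2 / 999
        assert abs(res.p_value - p_exact) <= tol

    def test_matches_scikit_bio(self):
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(14)
        X = rng.normal(size=(18, 3))
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        res = sr.permanova(X, labels, permutations=99, seed=1)
        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(18)])
        ref = skbio_permanova(dm, labels, permutations=99)
        assert res.statistic == pytest.approx(float(ref["test statistic"]), abs=1e-10)

    def test_separated_clusters_hit_the_p_floor(self):
        rng = np.random.default_rng(15)
        X = np.vstack([rng.normal(0, 0.1, size=(8, 2)), rng.normal(50, 0.1, size=(8, 2))])
        labels = ["a"] * 8 + ["b"] * 8
        res = sr.permanova(X, labels, permutations=999, seed=2)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_never_zero_and_seed_reproducible(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(12, 2))
        labels = ["a"] * 6 + ["b"] * 6
        r1 = sr.permanova(X, labels, permutations=199, seed=5)
        r2 = sr.permanova(X, labels, permutations=199, seed=5)
        assert r1.p_value == r2.p_value > 0

    def test_tiny_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.raises(ValueError):
            sr.permanova(X, ["a", "a", "a", "b"])


class TestDispersion:
    def test_translated_groups_have_equal_dispersion(self):
        rng = np.random.default_rng(17)
        base = rng.normal(size=(25, 2))
        X = np.vstack([base, base + 10.0])
        labels = ["a"] * 25 + ["b"] * 25
        res = sr.dispersion_homogeneity(X, labels)
        assert res.p_value > 0.99  # identical spreads by construction
        assert res.group_mean_distance["a"] == pytest.approx(res.group_mean_distance["b"])

    def test_double_spread_detected(self):
        rng = np.random.default_rng(18)
        X = np.vstack([rng.normal(0, 1, size=(50, 2)), rng.normal(0, 2, size=(50, 2))])
        labels = ["a"] * 50 + ["b"] * 50
        res = sr.dispersion_homogeneity(X, labels)
        assert res.p_value < 0.05

    def test_degenerate_groups_have_zero_distance(self):
        X = np.array([[1.0, 1.0]] * 3 + [[4.0, 4.0]] * 3)
        labels = ["a"] * 3 + ["b"] * 3
        res = sr.dispersion_homogeneity(X, labels)
        assert np.allclose(res.distances, 0.0)


class TestPairwise:
    def test_three_groups_give_three_pairs(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(15, 2))
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        out = sr.pairwise_permanova(X, labels, permutations=99, seed=3)
        assert len(out) == 3

    def test_bonferroni_arithmetic(self):
        adj = adjust_pvalues([0.01, 0.02, 0.04], "bonferroni")
        assert np.allclose(adj, [0.03, 0.06, 0.12])

    def test_holm_dominates_bonferroni(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            p = rng.uniform(size=4)
            holm = adjust_pvalues(p, "holm")
            bonf = adjust_pvalues(p, "bonferroni")
            assert np.all(holm <= bonf + 1e-12)
            assert np.all(holm >= p - 1e-12)


class TestScoresModels:
    def test_planted_association_flagged(self):
        rng = np.random.default_rng(21)
        n = 60
        latent = rng.normal(size=n)
        X = pd.DataFrame({
            "a": latent + rng.normal(0, 0.2, n),
            "b": latent + rng.normal(0, 0.2, n),
            "c": rng.normal(size=n),
        }, index=[f"sp{i}" for i in range(n)])
        ordination = sr.pca(X)
        responses = pd.DataFrame(
            {"shift": 0.8 * latent + rng.normal(0, 0.3, n)}, index=X.index
        )
        fits, skipped = sr.scores_models(ordination, responses)
        assert not skipped
        pc1 = [f for f in fits if f.label == "PC1~shift"][0]
        slope = pc1.terms.set_index("term").loc["shift"]
        assert slope["clear_relationship"]

    def test_missing_species_dropped_and_reported(self):
        rng = np.random.default_rng(22)
        X = pd.DataFrame(rng.normal(size=(10, 3)), index=[f"sp{i}" for i in range(10)])
        responses = pd.DataFrame({"y": rng.normal(size=8)}, index=[f"sp{i}" for i in range(8)])
        fits, skipped = sr.scores_models(sr.pca(X), responses)
        assert skipped == ["sp8", "sp9"]
        assert fits and all(f.n == 8 for f in fits)
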