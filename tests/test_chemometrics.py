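"""PLS1 calibration, repeated K-fold CV, LOD arithmetic and PCA."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as SkPCA

import caroraman as cr
from caroraman.chemometrics import CVResult, _coefficient_path
from caroraman.preprocess import preprocess_set
from caroraman.spectra import SpectrumSet


def rank1_data(n=24, p=60, seed=0, noise=0.0):
    """Rows = c_i * fixed spectrum (+ optional noise)."""
    rng = np.random.default_rng(seed)
    v = np.abs(rng.random(p)) + 0.1
    c = np.linspace(0.05, 2.0, n)
    X = np.outer(c, v)
    if noise:
        X = X + noise * rng.standard_normal(X.shape)
    return X, c, v


class TestFitPLSR:
    def test_rank1_exact_with_one_lv(self):
        X, c, _ = rank1_data()
        model = cr.fit_plsr(X, c, n_lv=1)
        rmse = np.sqrt(np.mean((model.predict(X) - c) ** 2))
        assert rmse < 1e-8

    def test_coefficients_proportional_to_spectrum(self):
        """On single-component data the regression vector points along
        the component spectrum."""
        X, c, v = rank1_data()
        model = cr.fit_plsr(X, c, n_lv=1)
        cos = np.dot(model.coefficients, v) / (
            np.linalg.norm(model.coefficients) * np.linalg.norm(v)
        )
        assert cos > 0.9999

    def test_n_lv_out_of_range(self):
        X, c, _ = rank1_data(n=10)
        with pytest.raises(ValueError, match="n_lv"):
            cr.fit_plsr(X, c, n_lv=10)

    def test_training_error_monotone_in_lv(self):
        X, c, _ = rank1_data(n=30, noise=0.05)
        errs = []
        for k in (1, 3, 5, 8):
            m = cr.fit_plsr(X, c, n_lv=k)
            errs.append(np.sqrt(np.mean((m.predict(X) - c) ** 2)))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_coefficient_path_matches_per_lv_refits(self):
        """Truncating the NIPALS rotation/loading sequence at k components
        equals refitting with n_components=k (the CV fast path)."""
        X, c, _ = rank1_data(n=30, p=40, noise=0.05)
        full = PLSRegression(n_components=6, scale=False).fit(X, c)
        path = _coefficient_path(full)
        for k in (1, 2, 4, 6):
            sub = PLSRegression(n_components=k, scale=False).fit(X, c)
            np.testing.assert_allclose(path[:, k - 1], sub.coef_.ravel(),
                                       rtol=1e-8, atol=1e-10)


class TestCrossValidate:
    def test_rank1_rmsecv_negligible(self):
        X, c, _ = rank1_data()
        cv = cr.cross_validate(X, c, n_lv_max=3, k=10, repeats=5, seed=0)
        assert cv.rmsecv_per_lv[0] < 1e-6
        assert np.all(cv.rmsecv_per_lv < 1e-6)

    def test_deterministic_under_seed(self):
        X, c, _ = rank1_data(noise=0.05)
        a = cr.cross_validate(X, c, n_lv_max=4, k=5, repeats=10, seed=3)
        b = cr.cross_validate(X, c, n_lv_max=4, k=5, repeats=10, seed=3)
        assert np.array_equal(a.rmsecv_per_lv, b.rmsecv_per_lv)
        assert np.array_equal(a.mean_predictions, b.mean_predictions)

    def test_k_larger_than_n_rejected(self):
        X, c, _ = rank1_data(n=8)
        with pytest.raises(ValueError, match="exceeds"):
            cr.cross_validate(X, c, n_lv_max=2, k=10)

    def test_cv_predictions_unbiased(self):
        X, c, _ = rank1_data(n=40, noise=0.02, seed=5)
        cv = cr.cross_validate(X, c, n_lv_max=2, k=10, repeats=10, seed=1)
        assert abs(cv.bias(2)) < 0.5 * cv.rmsecv_per_lv[1]


class TestSelectNLV:
    def test_variance_saturation_rule(self):
        assert cr.select_n_lv([60, 95, 99.95, 100], policy="variance_saturation") == 3

    def test_rmsecv_min_rule(self):
        assert cr.select_n_lv(rmsecv_per_lv=[5, 1, 1.01, 1.02], policy="rmsecv_min") == 2

    def test_rank1_noise_free_both_rules_choose_one(self):
        X, c, _ = rank1_data()
        model = cr.fit_plsr(X, c, n_lv=4)
        cv = cr.cross_validate(X, c, n_lv_max=4, k=8, repeats=3, seed=0)
        assert cr.select_n_lv(model.cumulative_variance, policy="variance_saturation") == 1
        assert cr.select_n_lv(rmsecv_per_lv=cv.rmsecv_per_lv, policy="rmsecv_min") == 1


class TestLOD:
    def test_values(self):
        assert cr.lod(0.0032) == pytest.approx(0.01056)
        assert cr.lod(0.0) == 0.0
        assert cr.lod(1.0) == pytest.approx(3.3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cr.lod(-0.1)


@pytest.fixture(scope="module")
def carotenoid_pca_set(cfg, ref_sum, water, bsa, absorption_models):
    """10 preprocessed + corrected replicates per carotenoid at 1 mg/mL."""
    rng = np.random.default_rng(11)
    specs = []
    for name in cr.CAROTENOIDS:
        for rep in range(10):
            s = cr.simulate_measurement({name: 1.0}, cfg,
                                        seed=int(rng.integers(0, 2**31 - 1)))
            s.meta.update({"analyte": name, "concentration": 1.0, "replicate": rep})
            specs.append(s)
    sset = SpectrumSet.from_spectra(specs)
    proc = preprocess_set(sset, ref_sum, [water, bsa])
    rows = [
        cr.correct_self_absorption(
            proc.spectrum(i), absorption_models[proc.labels["analyte"].iloc[i]], 1.0
        ).intensity
        for i in range(len(proc))
    ]
    return SpectrumSet(proc.axis, np.vstack(rows), proc.labels)


class TestPCA:
    def test_two_samples_pc1_explains_everything(self):
        rng = np.random.default_rng(0)
        X = rng.random((2, 30))
        res = cr.fit_pca(X)
        assert res.explained_variance_pct[0] == pytest.approx(100.0)

    def test_reconstruction_and_orthonormal_loadings(self, carotenoid_pca_set):
        res = cr.fit_pca(carotenoid_pca_set)
        X = carotenoid_pca_set.matrix.copy()
        X /= np.linalg.norm(X, axis=1)[:, None]
        np.testing.assert_allclose(res.reconstruct(), X - X.mean(axis=0), atol=1e-8)
        gram = res.loadings @ res.loadings.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert np.all(np.diff(res.explained_variance_pct) <= 1e-9)
        assert res.explained_variance_pct.sum() <= 100.0 + 1e-6

    def test_matches_sklearn_up_to_sign(self, carotenoid_pca_set):
        """Independent cross-check: singular spectrum equals sklearn PCA."""
        X = carotenoid_pca_set.matrix.copy()
        X /= np.linalg.norm(X, axis=1)[:, None]
        sk = SkPCA(n_components=5, svd_solver="full").fit(X)
        res = cr.fit_pca(carotenoid_pca_set, n_pc=5)
        np.testing.assert_allclose(
            res.explained_variance_pct, 100 * sk.explained_variance_ratio_, rtol=1e-8
        )
        for i in range(5):
            dot = abs(np.dot(res.loadings[i], sk.components_[i]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_sign_convention_deterministic(self, carotenoid_pca_set):
        a = cr.fit_pca(carotenoid_pca_set)
        b = cr.fit_pca(carotenoid_pca_set)
        np.testing.assert_array_equal(a.scores, b.scores)
        for row in a.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_zero_norm_row_rejected(self):
        X = np.ones((3, 10))
        X[1] = 0.0
        with pytest.raises(ValueError, match="row 1"):
            cr.fit_pca(X)

    def test_three_classes_separate_in_pc_plane(self, carotenoid_pca_set):
        """PC1+PC2 carry >90% of the variance and class centroids are
        separated by >3x the within-class spread."""
        res = cr.fit_pca(carotenoid_pca_set)
        assert res.explained_variance_pct[:2].sum() > 90.0
        scores = res.scores[:, :2]
        labels = carotenoid_pca_set.labels["analyte"].values
        cents = {c: scores[labels == c].mean(axis=0) for c in cr.CAROTENOIDS}
        spreads = [
            np.linalg.norm(scores[labels == c] - cents[c], axis=1).mean()
            for c in cr.CAROTENOIDS
        ]
        within = max(spreads)
        for i, a in enumerate(cr.CAROTENOIDS):
            for b in list(cr.CAROTENOIDS)[i + 1:]:
                assert np.linalg.norm(cents[a] - cents[b]) > 3.0 * within

    def test_pc1_loading_derivative_shape_at_nu1(self, carotenoid_pca_set):
        """The Beta Carotene / Lutein nu1 shift shows as a sign change of
        the PC1 loading inside the 1450-1600 cm^-1 window."""
        res = cr.pairwise_pca(carotenoid_pca_set, ("beta_carotene", "lutein"))
        w = (carotenoid_pca_set.axis >= 1450) & (carotenoid_pca_set.axis <= 1600)
        seg = res.loadings[0][w]
        assert seg.max() > 0 and seg.min() < 0
        assert abs(seg.min()) > 0.05 * seg.max()


class TestPairwisePCA:
    def test_pc1_dominates(self, carotenoid_pca_set):
        res = cr.pairwise_pca(carotenoid_pca_set, ("lutein", "zeaxanthin"))
        assert res.explained_variance_pct[0] > res.explained_variance_pct[1]
        assert len(res.labels) == 20

    def test_identical_classes_show_no_separation(self):
        rng = np.random.default_rng(2)
        base = rng.random(50)
        X = base + 0.01 * rng.standard_normal((12, 50))
        import pandas as pd

        labels = pd.DataFrame({"analyte": ["a"] * 6 + ["b"] * 6})
        sset = SpectrumSet(np.arange(50.0), X, labels)
        res = cr.pairwise_pca(sset, ("a", "b"))
        s = res.scores[:, :2]
        ca, cb = s[:6].mean(axis=0), s[6:].mean(axis=0)
        within = np.linalg.norm(s[:6] - ca, axis=1).mean()
        assert np.linalg.norm(ca - cb) < within

    def test_missing_label_rejected(self, carotenoid_pca_set):
        with pytest.raises(ValueError, match="absent"):
            cr.pairwise_pca(carotenoid_pca_set, ("lutein", "lycopene"))
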