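"""PCA fitting against an independent oracle, and loading-extrema selection."""

import numpy as np
import pytest

from nirhsi.bands import (
    BandSet,
    PCAResult,
    default_components,
    fit_pca,
    select_extrema_bands,
    variance_report,
)
from nirhsi.envi import WavelengthGrid


def eig_oracle(X):
    """Brute-force covariance eigendecomposition (independent of the SVD path)."""
    C = np.cov(np.asarray(X, dtype=float), rowvar=False)
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order].T


class TestFitPca:
    def test_matches_covariance_oracle_on_random_tables(self):
        r = np.random.default_rng(7)
        for _ in range(20):
            n = int(r.integers(5, 201))
            b = int(r.integers(2, 21))
            X = r.normal(size=(n, b)) @ r.normal(size=(b, b))
            res = fit_pca(X)
            w, v = eig_oracle(X)
            k = min(n - 1, b)
            np.testing.assert_allclose(res.eigenvalues[:k], w[:k],
                                       rtol=1e-8, atol=1e-10)
            for i in range(k):
                if w[i] < 1e-10:
                    continue
                dot = abs(np.dot(res.loadings[i], v[i]))
                assert dot == pytest.approx(1.0, abs=1e-7)

    def test_matches_sklearn(self, rng):
        from sklearn.decomposition import PCA

        X = rng.normal(size=(80, 10))
        res = fit_pca(X)
        sk = PCA().fit(X)
        np.testing.assert_allclose(res.eigenvalues, sk.explained_variance_,
                                   rtol=1e-9)
        for ours, theirs in zip(res.loadings, sk.components_):
            assert abs(np.dot(ours, theirs)) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_data_has_unit_first_fraction(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([2 * t + 1, -3 * t + 4])
        res = fit_pca(X)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        assert variance_report(res, 2)[0][1] == pytest.approx(100.0)
        assert variance_report(res, 2)[1][1] == pytest.approx(0.0, abs=1e-9)

    def test_isotropic_limit_fractions_near_uniform(self):
        r = np.random.default_rng(3)
        X = r.standard_normal((20000, 4))
        res = fit_pca(X)
        np.testing.assert_allclose(res.variance_fraction, 0.25, atol=0.02)

    def test_orthonormal_loadings(self, rng):
        res = fit_pca(rng.normal(size=(50, 8)))
        gram = res.loadings @ res.loadings.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-10)

    def test_reconstruction_identity(self, rng):
        X = rng.normal(size=(40, 6))
        res = fit_pca(X)
        Xc = X - res.band_mean
        back = (Xc @ res.loadings.T) @ res.loadings
        np.testing.assert_allclose(back, Xc, atol=1e-10)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        X = rng.normal(size=(60, 7))
        res = fit_pca(X)
        assert res.eigenvalues.sum() == pytest.approx(
            np.trace(np.cov(X, rowvar=False)), rel=1e-10
        )

    def test_sign_convention(self, rng):
        res = fit_pca(rng.normal(size=(30, 5)))
        for vec in res.loadings:
            assert vec[np.argmax(np.abs(vec))] > 0

    def test_constant_data_warns_zero_eigenvalues(self, caplog):
        with caplog.at_level("WARNING"):
            res = fit_pca(np.full((10, 3), 2.5))
        assert np.all(res.eigenvalues == 0)
        assert "constant" in caplog.text

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((1, 5)))
        with pytest.raises(ValueError):
            fit_pca(np.array([[1.0, np.nan], [2.0, 3.0]]))


def _result_from_loadings(loadings, grid, fractions=None):
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    k = len(loadings)
    frac = np.asarray(fractions if fractions is not None else np.ones(k) / k)
    return PCAResult(
        eigenvalues=frac.copy(),
        loadings=loadings,
        variance_fraction=frac,
        band_mean=np.zeros(loadings.shape[1]),
        grid=grid,
    )


class TestSelectExtremaBands:
    def test_hand_built_max_min_pair(self, small_grid):
        """Loadings [0, 1, 0, -1, 0]: one max (band 2) and one min (band 4)."""
        res = _result_from_loadings([[0.0, 1.0, 0.0, -1.0, 0.0]], small_grid)
        out = select_extrema_bands(res, components=[0], prominence=0.5)
        np.testing.assert_array_equal(out.wavelengths, [1100.0, 1300.0])
        assert out.source[1100.0] == [(0, "max")]
        assert out.source[1300.0] == [(0, "min")]

    def test_single_gaussian_bump(self):
        grid = WavelengthGrid.linspace(1000.0, 1500.0, 101)
        curve = np.exp(-0.5 * ((grid.centers - 1230.0) / 30.0) ** 2)
        res = _result_from_loadings([curve], grid)
        out = select_extrema_bands(res, components=[0], prominence=0.15)
        assert len(out) == 1
        assert out.wavelengths[0] == grid.centers[grid.nearest(1230.0)]

    def test_sign_flip_invariance(self, rng):
        grid = WavelengthGrid.linspace(1000.0, 1500.0, 60)
        curve = np.sin(np.linspace(0, 3 * np.pi, 60))
        a = select_extrema_bands(_result_from_loadings([curve], grid), [0], 0.2)
        b = select_extrema_bands(_result_from_loadings([-curve], grid), [0], 0.2)
        np.testing.assert_array_equal(a.wavelengths, b.wavelengths)

    def test_endpoints_never_selected(self):
        grid = WavelengthGrid.linspace(1000.0, 1100.0, 11)
        curve = np.linspace(0.0, 1.0, 11)  # monotone: extrema only at ends
        out = select_extrema_bands(_result_from_loadings([curve], grid), [0], 0.0)
        assert len(out) == 0

    def test_prominence_filters_small_wiggles(self):
        grid = WavelengthGrid.linspace(1000.0, 1500.0, 101)
        lam = grid.centers
        deep = -np.exp(-0.5 * ((lam - 1100.0) / 20.0) ** 2)
        shallow = -0.05 * np.exp(-0.5 * ((lam - 1400.0) / 20.0) ** 2)
        res = _result_from_loadings([deep + shallow], grid)
        strict = select_extrema_bands(res, [0], prominence=0.15)
        loose = select_extrema_bands(res, [0], prominence=0.01)
        assert [round(w) for w in strict.wavelengths] == [1100]
        assert 1400 in {round(w) for w in loose.wavelengths}

    def test_union_is_deduplicated_and_sorted(self, small_grid):
        res = _result_from_loadings(
            [[0.0, 1.0, 0.0, -1.0, 0.0], [0.0, -1.0, 0.0, 1.0, 0.0]], small_grid
        )
        out = select_extrema_bands(res, components=[0, 1], prominence=0.5)
        np.testing.assert_array_equal(out.wavelengths, [1100.0, 1300.0])
        assert len(out.source[1100.0]) == 2

    def test_max_per_component_keeps_most_prominent(self, small_grid):
        res = _result_from_loadings([[0.0, 0.4, 0.0, -1.0, 0.0]], small_grid)
        out = select_extrema_bands(res, [0], prominence=0.1, max_per_component=1)
        np.testing.assert_array_equal(out.wavelengths, [1300.0])

    def test_no_extremum_warns_empty(self, small_grid, caplog):
        res = _result_from_loadings([[0.0, 0.1, 0.2, 0.3, 0.4]], small_grid)
        with caplog.at_level("WARNING"):
            out = select_extrema_bands(res, [0], prominence=0.5)
        assert len(out) == 0

    def test_missing_component_rejected(self, small_grid):
        res = _result_from_loadings([[0.0, 1.0, 0.0, -1.0, 0.0]], small_grid)
        with pytest.raises(ValueError):
            select_extrema_bands(res, components=[3])


class TestDefaultComponents:
    def _res(self, fractions):
        frac = np.asarray(fractions, dtype=float)
        b = len(frac)
        return PCAResult(frac.copy(), np.eye(b), frac, np.zeros(b), None)

    def test_cumulative_rule(self):
        assert default_components(self._res([0.95, 0.03, 0.02])) == [0, 1]
        assert default_components(self._res([0.98, 0.02])) == [0]

    def test_noise_tail_is_ignored(self):
        """Sub-floor components never count toward the cumulative target."""
        frac = np.r_[0.90, 0.03, np.full(70, 0.001)]
        assert default_components(self._res(frac)) == [0, 1]

    def test_explicit_floor(self):
        frac = np.array([0.6, 0.3, 0.08, 0.02])
        assert default_components(self._res(frac), floor=0.05) == [0, 1, 2]


class TestBandSet:
    def test_invariants(self):
        with pytest.raises(ValueError):
            BandSet(np.array([1100.0, 1100.0]))
        with pytest.raises(ValueError):
            BandSet(np.array([1200.0, 1100.0]))

    def test_json_round_trip(self, tmp_path):
        bs = BandSet(np.array([1000.0, 1200.0]), {1000.0: [(0, "max")],
                                                  1200.0: [(1, "min")]})
        bs.to_json(tmp_path / "bands.json")
        back = BandSet.from_json(tmp_path / "bands.json")
        np.testing.assert_array_equal(back.wavelengths, bs.wavelengths)
        assert back.source[1200.0] == [(1, "min")]
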