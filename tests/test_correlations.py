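"""Polychoric estimation, its asymptotic covariance, and attenuation theory."""

import numpy as np
import pytest

from overfactor.correlations import (
    DegenerateColumnError,
    acov_polychoric,
    dichotomized_population_correlation,
    estimate_thresholds,
    nearest_pd_correlation,
    ordinal_population_correlation,
    polychoric_matrix,
    polychoric_pair,
)
from overfactor._bvn import bvn_cdf, rectangle_probs
from overfactor.synthetic_data import (
    GeneratorSpec,
    discretize,
    generate_latent,
    thresholds_from_gamma,
)


def _ordinal_pair(rho, thresholds_a, thresholds_b, n, seed):
    g = np.random.default_rng(seed)
    z = g.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    x = np.searchsorted(thresholds_a, z[:, 0])
    y = np.searchsorted(thresholds_b, z[:, 1])
    return x.astype(np.int64), y.astype(np.int64)


class TestThresholdEstimation:
    def test_median_split(self):
        col = np.array([0] * 50 + [1] * 50)
        tau, rec, nc = estimate_thresholds(col)
        assert tau == pytest.approx([0.0], abs=1e-12)

    def test_equal_thirds_symmetric(self):
        col = np.repeat([0, 1, 2], 40)
        tau, _, _ = estimate_thresholds(col)
        assert tau[0] == pytest.approx(-tau[1], abs=1e-12)

    def test_collapse_recorded_and_recode(self):
        col = np.array([0] * 30 + [2] * 70)  # category 1 empty
        tau, rec, nc = estimate_thresholds(col, K=3)
        assert len(tau) == 1 and nc == 1
        assert set(rec) == {0, 1}

    def test_constant_column_degenerate(self):
        with pytest.raises(DegenerateColumnError):
            estimate_thresholds(np.zeros(20, dtype=int))


class TestPolychoricPair:
    def test_matches_brute_force_grid(self):
        """Two-step ML agrees with a brute-force likelihood grid search."""
        x, y = _ordinal_pair(0.45, [0.3], [-0.2], 800, seed=5)
        rho, info = polychoric_pair(x, y)
        a, b = info["thresholds"]
        table = info["table"]
        grid = np.arange(-0.999, 0.999, 1e-4)
        ll = [np.sum(table * np.log(np.maximum(rectangle_probs(a, b, r), 1e-300)))
              for r in grid]
        assert rho == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)

    def test_independence(self):
        g = np.random.default_rng(0)
        x = g.integers(0, 2, 4000)
        y = g.integers(0, 3, 4000)
        rho, _ = polychoric_pair(x, y)
        assert abs(rho) < 0.05

    def test_parameter_recovery(self):
        """rho* = 0.71^2 = 0.5041 recovered from n=10^4 ordinal pair."""
        ts = thresholds_from_gamma(1, 2).thresholds
        x, y = _ordinal_pair(0.5041, ts, ts, 10_000, seed=9)
        rho, _ = polychoric_pair(x, y)
        assert rho == pytest.approx(0.5041, abs=0.03)

    def test_boundary_clamped(self):
        x = np.array([0] * 50 + [1] * 50)
        rho, info = polychoric_pair(x, x.copy())
        assert info["clamped"] and rho == pytest.approx(1.0, abs=1e-5)


class TestPolychoricMatrix:
    def test_one_factor_recovery_and_acov(self):
        lam = 0.9
        spec = GeneratorSpec(n=5000, p=4, r=2, loading=lam, gamma_per_item=(0,) * 4, seed=21)
        ts = thresholds_from_gamma(0, 2)
        data = discretize(generate_latent(spec), [ts] * 4)
        res = polychoric_matrix(data)
        off = res.rho_matrix[np.triu_indices(4, 1)]
        assert np.allclose(off, lam**2, atol=0.03)
        assert np.allclose(res.rho_matrix, res.rho_matrix.T)
        assert np.all(np.diag(res.acov) > 0)
        assert np.allclose(res.acov, res.acov.T, atol=1e-10)

    def test_acov_scales_with_n(self):
        """diag(Gamma) estimates n*var, so it is stable when n doubles."""
        diags = []
        for n, seed in ((1000, 3), (4000, 3)):
            spec = GeneratorSpec(n=n, p=3, r=1, loading=0.6, gamma_per_item=(0,) * 3, seed=seed)
            ts = thresholds_from_gamma(0, 1)
            data = discretize(generate_latent(spec), [ts] * 3)
            diags.append(np.diag(acov_polychoric(polychoric_matrix(data, compute_acov=False))))
        assert np.allclose(diags[0], diags[1], rtol=0.35)

    def test_independent_columns_cross_acov_small(self):
        g = np.random.default_rng(17)
        data = g.integers(0, 3, size=(4000, 4))
        res = polychoric_matrix(data)
        off = res.acov[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.25 * np.max(np.diag(res.acov))

    def test_constant_column_error_names_column(self):
        data = np.column_stack([np.zeros(50, int), np.tile([0, 1], 25)])
        with pytest.raises(DegenerateColumnError, match="column 0"):
            polychoric_matrix(data)

    def test_nearest_pd(self):
        R = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        S, smoothed = nearest_pd_correlation(R)
        assert smoothed
        assert np.linalg.eigvalsh(S).min() > 0
        assert np.allclose(np.diag(S), 1.0)


class TestAttenuation:
    def test_median_split_closed_form(self):
        """At zero thresholds the manifest correlation is (2/pi) asin(rho*)."""
        for rho in (0.2, 0.5041, 0.81):
            res = dichotomized_population_correlation(0.0, 0.0, rho)
            assert res.rho_y == pytest.approx(2 / np.pi * np.arcsin(rho), abs=1e-9)
        assert dichotomized_population_correlation(0, 0, 0.5041).rho_y == pytest.approx(0.3365, abs=2e-4)

    def test_trivial_and_symmetry(self):
        assert dichotomized_population_correlation(0.7, 0.7, 1e-12).rho_y == pytest.approx(0.0, abs=1e-9)
        a = dichotomized_population_correlation(0.4, -1.1, 0.5)
        b = dichotomized_population_correlation(-0.4, 1.1, 0.5)
        assert a.rho_y == pytest.approx(b.rho_y, abs=1e-10)

    def test_attenuation_inequalities(self):
        """|rho_y| <= |rho*|, maximal at (0,0); opposite skew attenuates most."""
        rho = 0.5041
        taus = np.linspace(-2, 2, 9)
        best = dichotomized_population_correlation(0, 0, rho).rho_y
        for t1 in taus:
            for t2 in taus:
                ry = dichotomized_population_correlation(t1, t2, rho).rho_y
                assert abs(ry) <= rho + 1e-12
                assert ry <= best + 1e-12
        same = dichotomized_population_correlation(-2, -2, rho).rho_y
        opposite = dichotomized_population_correlation(-2, 2, rho).rho_y
        assert opposite < same

    def test_ordinal_generalizes_dichotomous(self):
        """The polytomous population correlation reduces to the binary case."""
        r1 = dichotomized_population_correlation(0.6, -0.3, 0.45).rho_y
        r2 = ordinal_population_correlation([0.6], [-0.3], 0.45)
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_bvn_cdf_against_scipy(self):
        from scipy.stats import multivariate_normal

        for h, k, r in [(0.3, -1.2, 0.6), (-2.0, 2.0, -0.4), (0.0, 0.5, 0.81)]:
            want = multivariate_normal([0, 0], [[1, r], [r, 1]]).cdf([h, k])
            assert float(bvn_cdf(h, k, r)) == pytest.approx(want, abs=1e-8)
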