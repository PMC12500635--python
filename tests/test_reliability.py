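"""Reliability diagnostics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kanokit as kk
from kanokit.reliability import ReliabilityDiagnostics, alpha_band, kmo_band


def _rng(seed=0):
    return np.random.default_rng(seed)


def alpha_oracle(X):
    """Independent covariance-matrix identity: alpha = k/(k-1)*(1 - tr(C)/sum(C))."""
    C = np.cov(np.asarray(X, float), rowvar=False, ddof=1)
    k = C.shape[0]
    return k / (k - 1) * (1 - np.trace(C) / C.sum())


def kmo_oracle(X):
    """Brute-force KMO from the explicitly inverted correlation matrix."""
    R = np.corrcoef(np.asarray(X, float), rowvar=False)
    S = np.linalg.inv(R)
    k = R.shape[0]
    r2 = q2 = 0.0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            r2 += R[i, j] ** 2
            q2 += (-S[i, j] / np.sqrt(S[i, i] * S[j, j])) ** 2
    return r2 / (r2 + q2)


class TestCronbachAlpha:
    def test_identical_items_give_one(self):
        col = _rng().integers(1, 6, size=30).astype(float)
        X = np.column_stack([col, col, col])
        assert kk.cronbach_alpha(X) == pytest.approx(1.0)

    def test_fixed_matrix_matches_covariance_oracle(self):
        X = np.array([[1, 2, 3], [2, 4, 5], [3, 3, 4], [5, 4, 1]], dtype=float)
        assert kk.cronbach_alpha(X) == pytest.approx(alpha_oracle(X), abs=1e-12)

    def test_uncorrelated_items_near_zero(self):
        X = _rng(3).normal(size=(5000, 2))
        assert kk.cronbach_alpha(X) == pytest.approx(0.0, abs=0.1)

    def test_constant_shift_invariance(self):
        X = _rng(1).integers(1, 6, size=(20, 4)).astype(float)
        shifted = X + np.array([10.0, 0.0, -3.0, 100.0])
        assert kk.cronbach_alpha(shifted) == pytest.approx(kk.cronbach_alpha(X))

    def test_zero_total_variance_rejected(self):
        X = np.ones((5, 3))
        with pytest.raises(ValueError, match="variance"):
            kk.cronbach_alpha(X)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_oracle_on_random_matrices(self, seed):
        X = _rng(seed).integers(1, 6, size=(12, 5)).astype(float)
        X += _rng(seed + 1).normal(scale=0.01, size=X.shape)  # avoid degenerate columns
        assert kk.cronbach_alpha(X) == pytest.approx(alpha_oracle(X), abs=1e-10)


class TestKMO:
    def test_two_items_is_half_for_any_nonzero_r(self):
        for seed in (0, 1, 2):
            z = _rng(seed).normal(size=(200, 2))
            z[:, 1] = 0.6 * z[:, 0] + 0.8 * z[:, 1]
            assert kk.kmo(z) == pytest.approx(0.5, abs=1e-12)

    def test_fixed_matrix_matches_bruteforce_oracle(self):
        X = np.array(
            [[1, 2, 3, 4], [2, 3, 1, 5], [4, 1, 2, 2], [5, 5, 4, 1], [3, 2, 5, 3], [1, 4, 4, 4]],
            dtype=float,
        )
        assert kk.kmo(X) == pytest.approx(kmo_oracle(X), abs=1e-12)

    def test_in_unit_interval(self):
        X = _rng(7).normal(size=(50, 6))
        assert 0.0 <= kk.kmo(X) <= 1.0

    def test_singular_correlation_rejected(self):
        z = _rng(0).normal(size=(30, 2))
        X = np.column_stack([z[:, 0], z[:, 0], z[:, 1]])  # exact collinearity
        with pytest.raises(ValueError, match="singular"):
            kk.kmo(X)


class TestBartlett:
    def test_identity_correlation_gives_zero(self):
        n, k = 50, 4
        X = _rng(11).normal(size=(n, k))
        # orthogonalise columns so the sample correlation is exactly identity
        Q, _ = np.linalg.qr(X - X.mean(0))
        chi2, df, p = kk.bartlett_sphericity(Q)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)
        assert df == k * (k - 1) // 2

    def test_df_formula(self):
        X = _rng(2).normal(size=(30, 3))
        assert kk.bartlett_sphericity(X).df == 3

    def test_matches_formula_oracle(self):
        X = _rng(5).integers(1, 6, size=(10, 3)).astype(float)
        X += _rng(6).normal(scale=0.01, size=X.shape)
        R = np.corrcoef(X, rowvar=False)
        n, k = X.shape
        expected = -(n - 1 - (2 * k + 5) / 6) * np.log(np.linalg.det(R))
        assert kk.bartlett_sphericity(X).chi2 == pytest.approx(expected, abs=1e-9)

    def test_linear_growth_in_n(self):
        """With correlations held fixed, chi2 scales as (n - 1 - (2k+5)/6)."""
        base = _rng(9).normal(size=(40, 3))
        base[:, 1] += 0.5 * base[:, 0]
        X2 = np.vstack([base, base])  # doubled n, identical correlations
        k = 3
        c1 = kk.bartlett_sphericity(base).chi2
        c2 = kk.bartlett_sphericity(X2).chi2
        f = (80 - 1 - (2 * k + 5) / 6) / (40 - 1 - (2 * k + 5) / 6)
        assert c2 == pytest.approx(f * c1, rel=1e-9)

    def test_requires_more_respondents_than_items(self):
        X = _rng(0).normal(size=(3, 4))
        with pytest.raises(ValueError, match="more respondents"):
            kk.bartlett_sphericity(X)


class TestBands:
    @pytest.mark.parametrize(
        "value,band",
        [(0.59, "revise scale"), (0.6, "acceptable"), (0.7, "good"),
         (0.8, "excellent"), (0.905, "excellent")],
    )
    def test_alpha_bands_left_closed(self, value, band):
        assert alpha_band(value) == band

    @pytest.mark.parametrize(
        "value,band",
        [(0.69, "inadequate"), (0.7, "acceptable"), (0.759, "acceptable"),
         (0.8, "good"), (0.9, "excellent")],
    )
    def test_kmo_bands_left_closed(self, value, band):
        assert kmo_band(value) == band


class TestReliabilityDiagnostics:
    def test_full_report(self):
        X = _rng(4).integers(1, 6, size=(40, 5)).astype(float)
        X += _rng(5).normal(scale=0.01, size=X.shape)
        rel = ReliabilityDiagnostics().fit(X)
        rep = rel.report()
        assert rep.n_respondents == 40 and rep.n_items == 5
        assert rep.alpha == pytest.approx(alpha_oracle(X), abs=1e-10)
        assert rep.kmo == pytest.approx(kmo_oracle(X), abs=1e-10)
        assert rep.errors is None

    def test_listwise_deletion(self):
        X = _rng(4).normal(size=(30, 3))
        Xm = X.copy()
        Xm[0, 0] = np.nan
        assert kk.cronbach_alpha(Xm) == pytest.approx(kk.cronbach_alpha(X[1:]))

    def test_partial_failure_reported_not_fatal(self):
        z = _rng(0).normal(size=(30, 2))
        X = np.column_stack([z[:, 0], z[:, 0], z[:, 1]])
        rel = ReliabilityDiagnostics().fit(X)
        assert rel.kmo_ is None and "kmo" in rel.errors_
        assert rel.alpha_ is not None  # alpha tolerates collinearity
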