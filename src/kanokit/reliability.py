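"""Questionnaire reliability and sampling-adequacy diagnostics.

Implements the three standard instrument checks from their closed forms:

* Cronbach's alpha — internal consistency,
  ``alpha = k/(k-1) * (1 - sum(item variances) / var(total score))``;
* the Kaiser-Meyer-Olkin (KMO) measure of sampling adequacy, built from
  the anti-image partial correlations obtained via the inverse of the
  item correlation matrix;
* Bartlett's test of sphericity,
  ``chi2 = -(n - 1 - (2k+5)/6) * ln det(R)`` with ``df = k(k-1)/2``.

Sample (n-1) variance convention throughout; rows with missing cells are
dropped listwise before any statistic is computed.  Interpretation bands:
alpha 0.6-0.7 acceptable, 0.7-0.8 good, >=0.8 excellent (below 0.6 the
scale needs revision); KMO 0.7-0.8 acceptable, 0.8-0.9 good, >=0.9
excellent.  Band intervals are left-closed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "cronbach_alpha",
    "kmo",
    "bartlett_sphericity",
    "alpha_band",
    "kmo_band",
    "BartlettResult",
    "ReliabilityReport",
    "ReliabilityDiagnostics",
]


class BartlettResult(NamedTuple):
    chi2: float
    df: int
    pvalue: float


def _as_matrix(scores) -> np.ndarray:
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"scores must be a 2-D respondents x items matrix, got ndim={X.ndim}")
    # listwise deletion of incomplete rows
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 complete respondents and 2 items, got {n}x{k}")
    return X


def cronbach_alpha(scores) -> float:
    """Cronbach's alpha of a respondents x items score matrix."""
    X = _as_matrix(scores)
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


def _correlation(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = list(np.nonzero(sd == 0)[0])
        raise ValueError(f"items with zero variance (columns {const}); correlations undefined")
    return np.corrcoef(X, rowvar=False)


def kmo(scores) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy, in [0, 1].

    ``KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2)`` over i != j, where the
    anti-image partial correlations are
    ``q_ij = -S_ij / sqrt(S_ii S_jj)`` with ``S = R^{-1}``.
    For k = 2 the partial correlation equals the correlation, so KMO = 0.5
    whenever r != 0.
    """
    X = _as_matrix(scores)
    R = _correlation(X)
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > 1e10:
        raise ValueError("correlation matrix is singular or near-singular; KMO undefined")
    S = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    Q = -S / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(scores) -> BartlettResult:
    """Bartlett's test that the correlation matrix is the identity."""
    X = _as_matrix(scores)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more respondents than items (n={n}, k={k})")
    R = _correlation(X)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * k + 5) / 6.0) * logdet
    df = k * (k - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    return BartlettResult(chi2=float(chi2), df=int(df), pvalue=p)


def alpha_band(alpha: float) -> str:
    """Interpretation band for Cronbach's alpha (left-closed intervals)."""
    if alpha >= 0.8:
        return "excellent"
    if alpha >= 0.7:
        return "good"
    if alpha >= 0.6:
        return "acceptable"
    return "revise scale"


def kmo_band(value: float) -> str:
    """Interpretation band for the KMO measure (left-closed intervals)."""
    if value >= 0.9:
        return "excellent"
    if value >= 0.8:
        return "good"
    if value >= 0.7:
        return "acceptable"
    return "inadequate"


@dataclass(frozen=True)
class ReliabilityReport:
    alpha: float | None
    alpha_band: str | None
    kmo: float | None
    kmo_band: str | None
    bartlett_chi2: float | None
    bartlett_df: int | None
    bartlett_p: float | None
    n_respondents: int
    n_items: int
    errors: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


class ReliabilityDiagnostics(BaseEstimator):
    """Compute alpha, KMO and Bartlett's sphericity on a score matrix.

    ``fit`` accepts a respondents x items array or DataFrame of numeric
    scores (Likert codes).  Statistics whose preconditions fail (e.g. a
    zero-variance item for KMO) are recorded as ``None`` with the error
    message kept in ``errors_`` rather than aborting the other two.
    """

    def fit(self, X, y=None) -> "ReliabilityDiagnostics":
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        M = _as_matrix(X)
        self.n_, self.k_ = M.shape
        self.errors_ = {}
        try:
            self.alpha_ = float(cronbach_alpha(M))
            self.alpha_band_ = alpha_band(self.alpha_)
        except ValueError as e:
            self.alpha_, self.alpha_band_ = None, None
            self.errors_["alpha"] = str(e)
        try:
            self.kmo_ = float(kmo(M))
            self.kmo_band_ = kmo_band(self.kmo_)
        except ValueError as e:
            self.kmo_, self.kmo_band_ = None, None
            self.errors_["kmo"] = str(e)
        try:
            b = bartlett_sphericity(M)
            self.bartlett_chi2_, self.bartlett_df_, self.bartlett_p_ = b.chi2, b.df, b.pvalue
        except ValueError as e:
            self.bartlett_chi2_ = self.bartlett_df_ = self.bartlett_p_ = None
            self.errors_["bartlett"] = str(e)
        return self

    def report(self) -> ReliabilityReport:
        check_is_fitted(self, "errors_")
        return ReliabilityReport(
            alpha=self.alpha_,
            alpha_band=self.alpha_band_,
            kmo=self.kmo_,
            kmo_band=self.kmo_band_,
            bartlett_chi2=self.bartlett_chi2_,
            bartlett_df=self.bartlett_df_,
            bartlett_p=self.bartlett_p_,
            n_respondents=self.n_,
            n_items=self.k_,
            errors=self.errors_ or None,
        )
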