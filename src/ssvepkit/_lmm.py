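"""Random-intercept linear mixed model with Satterthwaite inference.

Supports exactly the model class the two-eyes-per-participant analyses
need:

    y = X beta + u[participant] + eps,   u ~ N(0, tau^2),  eps ~ N(0, sigma^2)

fitted by REML with the variance ratio lambda = tau^2/sigma^2 profiled out,
using the closed forms available for a single grouping factor
(V0_i^{-1} = I - lambda/(1 + n_i lambda) J per participant).  Denominator
degrees of freedom follow Satterthwaite's approximation, with the REML
information matrix obtained numerically from the exact restricted
log-likelihood; multi-row F tests combine per-eigenvector Satterthwaite dfs.

statsmodels' MixedLM fits the same model and is used as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from scipy.optimize import minimize_scalar

__all__ = ["RandomInterceptLMM", "LMMFit"]

_TAU2_FLOOR_REL = 1e-8  # below this (relative to sigma^2) the fit is treated as OLS


@dataclass
class LMMFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    tau2: float
    sigma2: float
    loglik_reml: float
    n_obs: int
    n_groups: int
    rank_x: int
    singular: bool  #: tau^2 estimated at (or numerically on) the zero boundary


class RandomInterceptLMM:
    """REML machinery for one response vector, design matrix and grouping."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("y and X must be aligned")
        uniques, codes = np.unique(np.asarray(groups), return_inverse=True)
        self.y = y
        self.X = X
        self.codes = codes
        self.n_obs, self.p = X.shape
        self.n_groups = len(uniques)
        self.group_sizes = np.bincount(self.codes, minlength=self.n_groups).astype(float)
        # per-group column sums of X and sums of y
        self.S = np.zeros((self.n_groups, self.p))
        np.add.at(self.S, self.codes, X)
        self.ysum = np.bincount(self.codes, weights=y, minlength=self.n_groups)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        if np.linalg.matrix_rank(self.XtX) < self.p:
            raise ValueError("design matrix is rank deficient")
        self.fit_: LMMFit | None = None

    # -- GLS pieces at a given variance ratio ------------------------------
    def _gls(self, lam: float):
        w = lam / (1.0 + self.group_sizes * lam)
        A = self.XtX - (self.S.T * w) @ self.S
        b = self.Xty - self.S.T @ (w * self.ysum)
        beta = np.linalg.solve(A, b)
        r = self.y - self.X @ beta
        tsum = np.bincount(self.codes, weights=r, minlength=self.n_groups)
        q = float(r @ r - np.sum(w * tsum**2))
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        return beta, A, q, logdetA

    def _profile_deviance(self, lam: float) -> float:
        _, _, q, logdetA = self._gls(lam)
        nmp = self.n_obs - self.p
        return nmp * np.log(q / nmp) + float(np.sum(np.log1p(self.group_sizes * lam))) + logdetA

    def reml_loglik(self, tau2: float, sigma2: float) -> float:
        """Exact restricted log-likelihood at (tau^2, sigma^2)."""
        if sigma2 <= 0 or tau2 < 0:
            return -np.inf
        lam = tau2 / sigma2
        _, _, q, logdetA = self._gls(lam)
        nmp = self.n_obs - self.p
        logdet_v = self.n_obs * np.log(sigma2) + float(np.sum(np.log1p(self.group_sizes * lam)))
        logdet_xvx = logdetA - self.p * np.log(sigma2)
        return -0.5 * (nmp * np.log(2.0 * np.pi) + logdet_v + logdet_xvx + q / sigma2)

    # -- fitting -----------------------------------------------------------
    def fit(self) -> LMMFit:
        res = minimize_scalar(
            lambda t: self._profile_deviance(np.exp(t)),
            bounds=(-15.0, 10.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        # prefer the boundary when it matches the interior optimum (this also
        # resolves the flat profile of designs without within-group replication)
        if self._profile_deviance(0.0) <= res.fun + 1e-7 * (1.0 + abs(res.fun)):
            lam = 0.0
        beta, A, q, _ = self._gls(lam)
        sigma2 = max(q / (self.n_obs - self.p), 1e-30 + 1e-14 * float(np.var(self.y)))
        tau2 = lam * sigma2
        singular = tau2 < _TAU2_FLOOR_REL * sigma2
        fit = LMMFit(
            beta=beta,
            cov_beta=sigma2 * np.linalg.inv(A),
            tau2=float(tau2),
            sigma2=float(sigma2),
            loglik_reml=self.reml_loglik(tau2, sigma2),
            n_obs=self.n_obs,
            n_groups=self.n_groups,
            rank_x=self.p,
            singular=bool(singular),
        )
        self.fit_ = fit
        return fit

    # -- Satterthwaite machinery -------------------------------------------
    def _cov_beta_at(self, tau2: float, sigma2: float) -> np.ndarray:
        lam = max(tau2, 0.0) / sigma2
        w = lam / (1.0 + self.group_sizes * lam)
        A = self.XtX - (self.S.T * w) @ self.S
        return sigma2 * np.linalg.inv(A)

    def _vcov_theta(self) -> np.ndarray:
        """Asymptotic covariance of (tau^2, sigma^2): inverse REML information."""
        fit = self.fit_
        theta = np.array([fit.tau2, fit.sigma2])
        h = np.array([max(1e-8, 1e-4 * fit.sigma2), max(1e-8, 1e-4 * fit.sigma2)])

        def nll(t):
            if t[1] <= 0:
                return 1e30  # finite penalty keeps difference quotients defined
            return -self.reml_loglik(max(t[0], 0.0), t[1])

        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                H[i, j] = H[j, i] = (
                    nll(theta + ei + ej) - nll(theta + ei - ej)
                    - nll(theta - ei + ej) + nll(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(H)

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Denominator df for the single contrast ``c' beta``."""
        fit = self.fit_ if self.fit_ is not None else self.fit()
        resid_df = self.n_obs - self.p
        if fit.singular:
            return float(resid_df)
        c = np.asarray(c, dtype=float)
        theta = np.array([fit.tau2, fit.sigma2])
        h = np.array([max(1e-8, 1e-4 * fit.sigma2), max(1e-8, 1e-4 * fit.sigma2)])

        def f(t):
            return float(c @ self._cov_beta_at(max(t[0], 0.0), t[1]) @ c)

        grad = np.zeros(2)
        for i in range(2):
            e = np.eye(2)[i] * h[i]
            grad[i] = (f(theta + e) - f(theta - e)) / (2.0 * h[i])
        denom = float(grad @ self._vcov_theta() @ grad)
        if denom <= 0:
            return float(resid_df)
        df = 2.0 * f(theta) ** 2 / denom
        return float(np.clip(df, 1.0, resid_df))

    def ftest(self, L: np.ndarray) -> tuple[float, float, float, float]:
        """Type III F test of ``L beta = 0``; returns (F, df_num, df_den, p).

        Multi-row dfs follow the eigenvector-contrast combination: each
        eigenvector of L Phi L' gets its own Satterthwaite df, and the
        denominator df solves E[F-denominator] consistency,
        ddf = 2 E / (E - q) with E = sum nu_i / (nu_i - 2).
        """
        fit = self.fit_ if self.fit_ is not None else self.fit()
        L = np.atleast_2d(np.asarray(L, dtype=float))
        q = L.shape[0]
        W = L @ fit.cov_beta @ L.T
        est = L @ fit.beta
        F = float(est @ np.linalg.solve(W, est) / q)
        if fit.singular:
            ddf = float(self.n_obs - self.p)
        else:
            d, P = np.linalg.eigh(W)
            dfs = []
            for i in range(q):
                if d[i] <= 1e-12 * d.max():
                    continue
                dfs.append(self.satterthwaite_df(P[:, i] @ L))
            E = sum(nu / (nu - 2.0) for nu in dfs if nu > 2.0)
            ddf = 2.0 * E / (E - q) if E > q else float(self.n_obs - self.p)
            ddf = float(np.clip(ddf, 1.0, self.n_obs - self.p))
        p = float(sstats.f.sf(F, q, ddf))
        return F, float(q), ddf, p
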