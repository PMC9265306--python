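"""Regression models: OLS, weighted OLS, and maximum-likelihood spatial lag
and spatial error models.

The spatial lag model,

    y = alpha + rho W y + X beta + eps,

and the spatial error model,

    y = alpha + X beta + u,   u = lambda W u + eps,

are estimated by maximising the log-likelihood concentrated in the scalar
spatial parameter, with the Jacobian term ln|I - p W| evaluated from the
cached eigenvalues of W.  Standard errors come from the asymptotic
information matrix.  OLS and weighted OLS delegate to statsmodels; every
model's ``fit()`` returns a :class:`SpatialResults` with a common surface
(params, bse, pvalues, summary, diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .diagnostics import regression_diagnostics
from .weights import SpatialWeights

__all__ = ["OLSModel", "SpatialLag", "SpatialError", "SpatialResults"]

_OPT_TOL = 1e-8
_EDGE = 1e-6  # keep the optimiser off the interval boundary


@dataclass
class SpatialResults:
    """Unified results container for the four model families."""

    model_name: str
    params: pd.Series              # constant + slopes
    bse: pd.Series
    pvalues: pd.Series
    nobs: int
    resid: np.ndarray
    fittedvalues: np.ndarray
    rsquared: float                # R^2 (OLS) or pseudo-R^2 (ML models)
    aic: float
    llf: float | None = None
    rho: float | None = None       # spatial lag parameter
    rho_se: float | None = None
    lam: float | None = None       # spatial error parameter
    lam_se: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def spatial_param(self) -> float | None:
        return self.rho if self.rho is not None else self.lam

    def compute_diagnostics(self, exog: np.ndarray,
                            exog_names: list[str] | None = None) -> "SpatialResults":
        self.diagnostics = regression_diagnostics(self.resid, exog, exog_names)
        return self

    def summary(self) -> str:
        lines = [
            f"{self.model_name}  (N = {self.nobs})",
            f"  {'R2' if self.model_name.endswith('OLS') else 'pseudo-R2'}"
            f" = {self.rsquared:.4f}   AIC = {self.aic:.2f}",
        ]
        if self.rho is not None:
            lines.append(f"  rho = {self.rho:.4f} (SE {self.rho_se:.4f})")
        if self.lam is not None:
            lines.append(f"  lambda = {self.lam:.4f} (SE {self.lam_se:.4f})")
        lines.append(f"  {'variable':<30}{'coef':>10}{'SE':>10}{'p':>10}")
        for name in self.params.index:
            lines.append(f"  {name:<30}{self.params[name]:>10.4f}"
                         f"{self.bse[name]:>10.4f}{self.pvalues[name]:>10.4f}")
        if self.diagnostics:
            jb = self.diagnostics.get("jarque_bera")
            bp = self.diagnostics.get("breusch_pagan")
            if jb:
                lines.append(f"  JB = {jb[0]:.3f} (p = {jb[1]:.3f})")
            if bp:
                lines.append(f"  BP = {bp[0]:.3f} (p = {bp[1]:.3f})")
            vif = self.diagnostics.get("vif", {})
            for k, v in vif.items():
                lines.append(f"  VIF[{k}] = {v:.3f}")
        return "\n".join(lines)


def _prepare(endog, exog) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Coerce inputs and prepend a constant column."""
    y = np.asarray(endog, dtype=float).ravel()
    if isinstance(exog, pd.DataFrame):
        names = list(exog.columns)
        X = exog.to_numpy(dtype=float)
    else:
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    Xc = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns "
                         f"among ['const'] + {names})")
    return y, Xc, ["const"] + names


class OLSModel:
    """Ordinary least squares, optionally weighted by DHS cluster weights.

    Weights are rescaled to sum to N, so the weighted and unweighted
    intercepts live on the same scale; equal weights reproduce unweighted
    OLS exactly.
    """

    def __init__(self, endog, exog, weights: np.ndarray | None = None):
        self.endog, self.exog, self.exog_names = _prepare(endog, exog)
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if np.any(weights <= 0):
                raise ValueError("weights must be positive")
            weights = weights * len(weights) / weights.sum()
        self.weights = weights

    def fit(self) -> SpatialResults:
        if self.weights is None:
            res = sm.OLS(self.endog, self.exog).fit()
            name = "Unweighted OLS"
        else:
            res = sm.WLS(self.endog, self.exog, weights=self.weights).fit()
            name = "Weighted OLS"
        idx = pd.Index(self.exog_names)
        out = SpatialResults(
            model_name=name,
            params=pd.Series(res.params, index=idx),
            bse=pd.Series(res.bse, index=idx),
            pvalues=pd.Series(res.pvalues, index=idx),
            nobs=int(res.nobs),
            resid=np.asarray(res.resid),
            fittedvalues=np.asarray(res.fittedvalues),
            rsquared=float(res.rsquared),
            aic=float(res.aic),
            llf=float(res.llf),
        )
        return out.compute_diagnostics(self.exog, self.exog_names)


class _ConcentratedML:
    """Shared machinery for the two spatial ML models."""

    def __init__(self, endog, exog, w: SpatialWeights):
        self.endog, self.exog, self.exog_names = _prepare(endog, exog)
        if w.n != len(self.endog):
            raise ValueError("W size does not match the number of observations")
        self.w = w
        lo, hi = w.param_interval
        self.interval = (lo + _EDGE * (hi - lo), hi - _EDGE * (hi - lo))

    def _optimise(self, neg_conc_ll) -> float:
        res = optimize.minimize_scalar(neg_conc_ll, bounds=self.interval,
                                       method="bounded",
                                       options={"xatol": _OPT_TOL})
        p = float(res.x)
        span = self.interval[1] - self.interval[0]
        if (p - self.interval[0] < 1e-4 * span) or (self.interval[1] - p < 1e-4 * span):
            raise RuntimeError(
                "spatial parameter estimate at the interval boundary; "
                "inspect the weights matrix W")
        return p


class SpatialLag(_ConcentratedML):
    """Maximum-likelihood spatial lag model y = rho W y + X beta + eps."""

    def fit(self) -> SpatialResults:
        y, X, w = self.endog, self.exog, self.w
        n, k = X.shape
        Wy = w.lag(y)
        XtX_inv = np.linalg.inv(X.T @ X)
        b0 = XtX_inv @ (X.T @ y)
        bL = XtX_inv @ (X.T @ Wy)
        e0 = y - X @ b0
        eL = Wy - X @ bL

        def neg_ll(rho: float) -> float:
            e = e0 - rho * eL
            sigma2 = float(e @ e) / n
            return -(-0.5 * n * (np.log(2 * np.pi) + 1)
                     - 0.5 * n * np.log(sigma2) + w.logdet(rho))

        rho = self._optimise(neg_ll)
        beta = b0 - rho * bL
        e = e0 - rho * eL
        sigma2 = float(e @ e) / n
        llf = -neg_ll(rho)

        # asymptotic information matrix in (beta, rho, sigma2)
        A = np.eye(n) - rho * w.W
        C = w.W @ np.linalg.inv(A)
        Cxb = C @ (X @ beta)
        info = np.zeros((k + 2, k + 2))
        info[:k, :k] = X.T @ X / sigma2
        info[:k, k] = X.T @ Cxb / sigma2
        info[k, :k] = info[:k, k]
        info[k, k] = np.trace(C @ C) + np.trace(C.T @ C) + float(Cxb @ Cxb) / sigma2
        info[k, k + 1] = np.trace(C) / sigma2
        info[k + 1, k] = info[k, k + 1]
        info[k + 1, k + 1] = n / (2 * sigma2 ** 2)
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.diag(cov)[:k])
        rho_se = float(np.sqrt(cov[k, k]))

        zvals = beta / bse
        pvals = 2 * stats.norm.sf(np.abs(zvals))
        predy = X @ beta + rho * Wy
        r2 = float(np.corrcoef(predy, y)[0, 1] ** 2)
        n_par = k + 1  # alpha + betas + rho
        idx = pd.Index(self.exog_names)
        out = SpatialResults(
            model_name="Spatial Lag (ML)",
            params=pd.Series(beta, index=idx),
            bse=pd.Series(bse, index=idx),
            pvalues=pd.Series(pvals, index=idx),
            nobs=n, resid=e, fittedvalues=predy,
            rsquared=r2, aic=float(2 * n_par - 2 * llf), llf=float(llf),
            rho=rho, rho_se=rho_se,
        )
        return out.compute_diagnostics(self.exog, self.exog_names)


class SpatialError(_ConcentratedML):
    """Maximum-likelihood spatial error model y = X beta + u, u = lam W u + eps."""

    def fit(self) -> SpatialResults:
        y, X, w = self.endog, self.exog, self.w
        n, k = X.shape
        Wy = w.lag(y)
        WX = w.W @ X

        def filtered_fit(lam: float):
            yf = y - lam * Wy
            Xf = X - lam * WX
            beta, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
            ef = yf - Xf @ beta
            return beta, ef, float(ef @ ef) / n

        def neg_ll(lam: float) -> float:
            _, _, sigma2 = filtered_fit(lam)
            return -(-0.5 * n * (np.log(2 * np.pi) + 1)
                     - 0.5 * n * np.log(sigma2) + w.logdet(lam))

        lam = self._optimise(neg_ll)
        beta, ef, sigma2 = filtered_fit(lam)
        llf = -neg_ll(lam)

        A = np.eye(n) - lam * w.W
        C = w.W @ np.linalg.inv(A)
        Xf = A @ X
        cov_beta = sigma2 * np.linalg.inv(Xf.T @ Xf)
        bse = np.sqrt(np.diag(cov_beta))
        # (lam, sigma2) block is orthogonal to beta
        i22 = np.array([
            [np.trace(C @ C) + np.trace(C.T @ C), np.trace(C) / sigma2],
            [np.trace(C) / sigma2, n / (2 * sigma2 ** 2)],
        ])
        lam_se = float(np.sqrt(np.linalg.inv(i22)[0, 0]))

        zvals = beta / bse
        pvals = 2 * stats.norm.sf(np.abs(zvals))
        predy = X @ beta
        r2 = float(np.corrcoef(predy, y)[0, 1] ** 2)
        resid = y - predy  # u; the filtered innovations are ef
        n_par = k + 1  # alpha + betas + lambda
        idx = pd.Index(self.exog_names)
        out = SpatialResults(
            model_name="Spatial Error (ML)",
            params=pd.Series(beta, index=idx),
            bse=pd.Series(bse, index=idx),
            pvalues=pd.Series(pvals, index=idx),
            nobs=n, resid=resid, fittedvalues=predy,
            rsquared=r2, aic=float(2 * n_par - 2 * llf), llf=float(llf),
            lam=lam, lam_se=lam_se,
        )
        out.filtered_resid = ef  # innovations after spatial filtering
        return out.compute_diagnostics(self.exog, self.exog_names)
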