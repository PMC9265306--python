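"""Spatial-dependence and regression diagnostics.

Moran's I (analytic randomisation inference or seeded permutations), the
Lagrange-multiplier test for spatial error dependence in OLS residuals, and
the classical regression battery (Jarque-Bera, Breusch-Pagan, VIF) via
statsmodels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import jarque_bera

from .weights import SpatialWeights

__all__ = ["morans_i", "lm_error_test", "regression_diagnostics"]


def morans_i(y: np.ndarray, w: SpatialWeights, inference: str = "analytic",
             n_permutations: int = 999, seed: int | None = None) -> tuple[float, float]:
    """Global Moran's I of ``y`` under W, with a two-sided p-value.

    I = (N / S0) * (z' W z) / (z' z) with z = y - mean(y).  ``analytic``
    uses the normal approximation under the randomisation assumption;
    ``permutation`` uses seeded random relabellings (pseudo p-value,
    one-tailed towards the observed side, doubled).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    z = y - y.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("Moran's I undefined for constant y")
    W = w.W
    s0 = w.s0
    i_obs = n / s0 * float(z @ W @ z) / denom
    e_i = -1.0 / (n - 1)

    if inference == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            zp = rng.permutation(z)
            ip = n / s0 * float(zp @ W @ zp) / denom
            if (ip >= i_obs) if i_obs >= e_i else (ip <= i_obs):
                count += 1
        p = min(1.0, 2.0 * (count + 1) / (n_permutations + 1))
        return i_obs, p
    if inference != "analytic":
        raise ValueError("inference must be 'analytic' or 'permutation'")

    s1 = 0.5 * np.sum((W + W.T) ** 2)
    s2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    b2 = n * np.sum(z ** 4) / denom ** 2
    num = (n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2)
           - b2 * ((n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2))
    var_i = num / ((n - 1) * (n - 2) * (n - 3) * s0 ** 2) - e_i ** 2
    zscore = (i_obs - e_i) / np.sqrt(var_i)
    p = 2 * stats.norm.sf(abs(zscore))
    return float(i_obs), float(p)


def lm_error_test(residuals: np.ndarray, w: SpatialWeights) -> tuple[float, float]:
    """Lagrange-multiplier score test for spatial error dependence.

    LM = [e'We / (e'e / N)]^2 / T with T = tr(W'W + WW); p from chi2(1).
    """
    e = np.asarray(residuals, dtype=float)
    n = e.size
    if w.n != n:
        raise ValueError("residuals and W have mismatched sizes")
    W = w.W
    sigma2 = float(e @ e) / n
    t = float(np.trace(W.T @ W + W @ W))
    stat = (float(e @ W @ e) / sigma2) ** 2 / t
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def regression_diagnostics(residuals: np.ndarray, exog: np.ndarray,
                           exog_names: list[str] | None = None) -> dict:
    """JB, BP and per-variable VIF for a fitted model.

    ``exog`` must include the constant column; VIF is reported for the
    non-constant columns only.
    """
    residuals = np.asarray(residuals, dtype=float)
    exog = np.asarray(exog, dtype=float)
    n = residuals.size
    jb_stat, jb_p, _, _ = jarque_bera(residuals)
    out: dict = {"jarque_bera": (float(jb_stat), float(jb_p)),
                 "jb_reliable": n >= 8}
    if exog.shape[1] >= 2:
        bp_stat, bp_p, _, _ = het_breuschpagan(residuals, exog)
        out["breusch_pagan"] = (float(bp_stat), float(bp_p))
    else:  # intercept-only design: no regressors to relate the variance to
        out["breusch_pagan"] = (float("nan"), float("nan"))
    const_cols = [j for j in range(exog.shape[1])
                  if np.allclose(exog[:, j], exog[0, j])]
    vif = {}
    for j in range(exog.shape[1]):
        if j in const_cols:
            continue
        name = exog_names[j] if exog_names else f"x{j}"
        vif[name] = float(variance_inflation_factor(exog, j))
    out["vif"] = vif
    return out
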