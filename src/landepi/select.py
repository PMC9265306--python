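"""Two-filter feature selection: stepwise OLS then a Spearman screen.

Filter 1 is a combined forward/backward stepwise: at each step the
candidate whose entry most reduces the residual sum of squares is added,
provided its entry p-value is at or below the threshold (0.1); after every
addition, any included variable whose p-value has drifted above the
threshold is removed.  Filter 2 keeps only selected features whose Spearman
rank correlation with the outcome has p < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SelectionTrace", "stepwise_select", "spearman_filter", "select_features"]


@dataclass
class SelectionTrace:
    steps: list[dict] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    spearman: dict[str, tuple[float, float]] = field(default_factory=dict)
    surviving: list[str] = field(default_factory=list)


def _ols_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """(params, two-sided t-test p-values, RSS) for y on X (X incl. constant)."""
    n, k = X.shape
    params, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ params
    rss = float(resid @ resid)
    df = n - k
    if df <= 0 or rank < k:
        return params, np.ones(k), rss
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, params / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    return params, pvals, rss


def stepwise_select(table: pd.DataFrame, y_col: str, candidates: list[str],
                    p_threshold: float = 0.1,
                    always_in: list[str] | None = None,
                    max_steps: int = 100) -> SelectionTrace:
    """Forward/backward stepwise selection among ``candidates``.

    ``always_in`` columns (e.g. the control variables) are present in every
    fit but never removed and never counted as selected.  Deterministic:
    ties in RSS reduction break by candidate order.
    """
    always_in = list(always_in or [])
    y = table[y_col].to_numpy(dtype=float)
    n = len(y)
    trace = SelectionTrace()
    selected: list[str] = []

    def design(cols: list[str]) -> np.ndarray:
        mat = table[always_in + cols].to_numpy(dtype=float)
        return np.column_stack([np.ones(n), mat])

    _, _, current_rss = _ols_stats(design(selected), y)

    for _ in range(max_steps):
        changed = False
        # forward: best RSS reduction among candidates entering at p <= thr
        best = None
        for cand in candidates:
            if cand in selected:
                continue
            cols = selected + [cand]
            X = design(cols)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            params, pvals, rss = _ols_stats(X, y)
            p_entry = pvals[-1]
            if p_entry <= p_threshold and (best is None or rss < best[1]):
                best = (cand, rss, p_entry)
        if best is not None:
            cand, rss, p_entry = best
            selected.append(cand)
            current_rss = rss
            trace.steps.append({"action": "add", "feature": cand,
                                "p": float(p_entry), "rss": float(rss)})
            changed = True
        # backward: drop any selected variable whose p now exceeds threshold
        while selected:
            X = design(selected)
            _, pvals, rss = _ols_stats(X, y)
            sel_p = pvals[1 + len(always_in):]
            worst = int(np.argmax(sel_p))
            if sel_p[worst] > p_threshold:
                removed = selected.pop(worst)
                _, _, current_rss = _ols_stats(design(selected), y)
                trace.steps.append({"action": "remove", "feature": removed,
                                    "p": float(sel_p[worst]),
                                    "rss": float(current_rss)})
                changed = True
            else:
                break
        if not changed:
            break
    trace.selected = selected
    return trace


def _spearman(x: np.ndarray, y: np.ndarray, seed: int = 0,
              n_permutations: int = 9999) -> tuple[float, float]:
    """Spearman rho with average-rank ties; t-approximation p for n > 20,
    seeded Monte-Carlo permutation p otherwise."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > 20:
        if abs(rho) == 1.0:
            return rho, 0.0
        t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        return rho, float(2 * stats.t.sf(abs(t), n - 2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        rp = float(np.corrcoef(rng.permutation(rx), ry)[0, 1])
        if abs(rp) >= abs(rho) - 1e-12:
            count += 1
    return rho, (count + 1) / (n_permutations + 1)


def spearman_filter(table: pd.DataFrame, y_col: str, selected: list[str],
                    p_cut: float = 0.1, seed: int = 0) -> tuple[list[str], dict]:
    """Keep selected features whose Spearman p against the outcome is < p_cut.

    The magnitude, not the sign, of rho decides; constant features are
    dropped with a warning (rho undefined).
    """
    y = table[y_col].to_numpy(dtype=float)
    results: dict[str, tuple[float, float]] = {}
    surviving = []
    for feat in selected:
        x = table[feat].to_numpy(dtype=float)
        if np.all(x == x[0]):
            warnings.warn(f"constant feature {feat!r}: Spearman rho undefined, dropped")
            continue
        rho, p = _spearman(x, y, seed=seed)
        results[feat] = (rho, p)
        if p < p_cut:
            surviving.append(feat)
    return surviving, results


def select_features(table: pd.DataFrame, y_col: str, candidates: list[str],
                    always_in: list[str] | None = None,
                    p_stepwise: float = 0.1, p_spearman: float = 0.1,
                    seed: int = 0) -> SelectionTrace:
    """Run both filters and return the full trace."""
    trace = stepwise_select(table, y_col, candidates,
                            p_threshold=p_stepwise, always_in=always_in)
    surviving, results = spearman_filter(table, y_col, trace.selected,
                                         p_cut=p_spearman, seed=seed)
    trace.spearman = results
    trace.surviving = surviving
    return trace
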