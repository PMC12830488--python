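"""DVR-vs-SUVR agreement and optimal-window selection.

For every region and static window the battery computes Pearson correlation,
intraclass correlation (two-way mixed, consistency, average measures — the
Cronbach's-alpha form), and two data-driven selectors: bidirectional stepwise
regression of DVR on the five window SUVRs, and LASSO with cross-validated
penalty followed by univariate-AIC adjudication among the retained windows.
A consensus selector tabulates the winners.

Selector estimators follow the scikit-learn protocol (``fit(X, y)`` with a
(n_subjects, 5) window matrix and a DVR vector, fitted attributes with a
trailing underscore, ``get_params``/``set_params``).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .suvr import CANONICAL_WINDOWS

__all__ = [
    "WINDOW_ORDER",
    "SelectionResult",
    "pearson_matrix",
    "icc_cronbach",
    "agreement_table",
    "StepwiseWindowSelector",
    "LassoAicWindowSelector",
    "stepwise_select",
    "lasso_aic_select",
    "consensus_optimal_window",
    "univariate_aic",
]

#: Chronological order of the canonical windows; ties always break earlier.
WINDOW_ORDER: tuple[str, ...] = tuple(w.label for w in CANONICAL_WINDOWS)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one window-selection procedure for one region."""

    method: str
    selected_window: str | None
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    aic_by_window: dict = field(default_factory=dict)
    retained_windows: tuple = ()
    region: str | None = None
    flag: str | None = None


# ---------------------------------------------------------------------------
# agreement grid
# ---------------------------------------------------------------------------

def pearson_matrix(dvr_table: pd.DataFrame, suvr_table: pd.DataFrame) -> pd.DataFrame:
    """Region x window grid of Pearson r between DVR and SUVR.

    Inputs are long tables keyed by (subject_id, region) and
    (subject_id, region, window).  p-values are two-sided from the
    t-distribution with n - 2 df.  Cells with fewer than 3 complete pairs are
    flagged with NaN.
    """
    merged = suvr_table.merge(dvr_table[["subject_id", "region", "dvr"]],
                              on=["subject_id", "region"])
    rows = []
    windows = [w for w in WINDOW_ORDER if w in set(merged["window"].astype(str))]
    for region in sorted(merged["region"].unique()):
        for window in windows:
            cell = merged[(merged["region"] == region)
                          & (merged["window"].astype(str) == window)].dropna(
                subset=["dvr", "suvr"]
            )
            if len(cell) < 3:
                rows.append(dict(region=region, window=window,
                                 pearson_r=np.nan, pearson_p=np.nan, n=len(cell)))
                continue
            r, p = stats.pearsonr(cell["dvr"], cell["suvr"])
            rows.append(dict(region=region, window=window,
                             pearson_r=float(r), pearson_p=float(p), n=len(cell)))
    return pd.DataFrame(rows)


def icc_cronbach(x, y) -> tuple[float, float]:
    """Two-way mixed, consistency, average-measures ICC for two paired
    measures, reported as Cronbach's alpha.

    For k = 2 measures, alpha = 2 (1 - (Var x + Var y) / Var(x + y)), which
    equals the ANOVA ICC(3,k) (MSR - MSE)/MSR.  The p-value comes from the
    F test MSR/MSE with (n-1, n-1) df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of >= 3 paired values")
    n = x.size
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = 2.0 * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    df_r = n - 1
    df_e = (n - 1) * (2 - 1)
    msr = ssr / df_r
    mse = sse / df_e
    if msr == 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    icc = (msr - mse) / msr
    f_stat = msr / mse if mse > 0 else np.inf
    p = float(stats.f.sf(f_stat, df_r, df_e))
    return float(icc), p


def agreement_table(dvr_table: pd.DataFrame, suvr_table: pd.DataFrame) -> pd.DataFrame:
    """Region x window grid of Pearson r and ICC with p-values."""
    grid = pearson_matrix(dvr_table, suvr_table)
    merged = suvr_table.merge(dvr_table[["subject_id", "region", "dvr"]],
                              on=["subject_id", "region"])
    iccs, icc_ps = [], []
    for _, row in grid.iterrows():
        cell = merged[(merged["region"] == row["region"])
                      & (merged["window"].astype(str) == row["window"])].dropna(
            subset=["dvr", "suvr"]
        )
        if len(cell) < 3:
            iccs.append(np.nan)
            icc_ps.append(np.nan)
            continue
        icc, p = icc_cronbach(cell["dvr"].to_numpy(), cell["suvr"].to_numpy())
        iccs.append(icc)
        icc_ps.append(p)
    grid = grid.assign(icc=iccs, icc_p=icc_ps)
    return grid


# ---------------------------------------------------------------------------
# selection procedures
# ---------------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept: returns (coefs incl. intercept, p-values, rss)."""
    n = y.size
    Xd = np.column_stack([np.ones(n), X])
    k = Xd.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("singular design matrix")
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough observations for the model")
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return beta, pvals, rss, se, dof


def univariate_aic(x, y, n_params: int = 3) -> float:
    """AIC of the univariate linear model y ~ x.

    Convention: AIC = n ln(RSS/n) + 2k with k = 3 (slope, intercept and the
    error-variance term).  Only AIC differences matter; the convention is
    fixed so tables are comparable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _, _, rss, _, _ = _ols(x[:, None], y)
    n = y.size
    rss = max(rss, n * 1e-300)  # a perfect fit stays finite (and minimal)
    return float(n * np.log(rss / n) + 2 * n_params)


def _as_window_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        cols = [str(c) for c in X.columns]
        return X.to_numpy(dtype=float), cols
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (subjects x windows)")
    cols = list(WINDOW_ORDER[: X.shape[1]])
    return X, cols


def _adjudicate_by_aic(retained: list, X: np.ndarray, cols: list, y: np.ndarray):
    """Among retained windows, pick the one whose univariate model has the
    smallest AIC; ties break toward the earlier window."""
    aic = {w: univariate_aic(X[:, cols.index(w)], y) for w in retained}
    order = {w: i for i, w in enumerate(WINDOW_ORDER)}
    best = min(retained, key=lambda w: (aic[w], order.get(w, len(order))))
    return best, aic


class StepwiseWindowSelector(BaseEstimator):
    """Bidirectional stepwise selection of the optimal SUVR window.

    Forward steps add the candidate with the smallest entry p-value (adjusted
    across the current candidate set by ``entry_adjust``) when it is below
    ``entry_p``; backward steps drop any retained predictor whose p-value
    rises to ``removal_p`` or above.  When several windows survive, the final
    window is the one whose univariate model has the smallest AIC.

    Parameters
    ----------
    entry_p, removal_p : float
        Entry (default 0.05) and removal (default 0.10) thresholds.
    entry_adjust : {"bonferroni", "none"}
        "bonferroni" (default) multiplies the candidate p-value by the number
        of candidates currently under consideration, keeping the family-wise
        false-selection rate near ``entry_p`` under a global null; "none" is
        the classical raw-p rule.

    Attributes
    ----------
    selected_window_ : str or None
    retained_windows_ : tuple of str
    result_ : SelectionResult
    """

    def __init__(self, entry_p: float = 0.05, removal_p: float = 0.10,
                 entry_adjust: str = "bonferroni"):
        self.entry_p = entry_p
        self.removal_p = removal_p
        self.entry_adjust = entry_adjust

    def fit(self, X, y):
        X, cols = _as_window_matrix(X)
        y = np.asarray(y, dtype=float)
        if y.size <= 10:
            raise ValueError("stepwise selection needs n > 10 subjects")
        if self.entry_adjust not in ("bonferroni", "none"):
            raise ValueError("entry_adjust must be 'bonferroni' or 'none'")
        selected: list[str] = []
        for _ in range(4 * len(cols)):
            changed = False
            # forward
            candidates = [c for c in cols if c not in selected]
            if candidates:
                best_c, best_p = None, np.inf
                for c in candidates:
                    idx = [cols.index(w) for w in selected + [c]]
                    try:
                        _, pvals, _, _, _ = _ols(X[:, idx], y)
                    except np.linalg.LinAlgError:
                        continue
                    if pvals[-1] < best_p:
                        best_c, best_p = c, pvals[-1]
                if best_c is not None:
                    adj = best_p * (len(candidates) if self.entry_adjust == "bonferroni" else 1)
                    if adj < self.entry_p:
                        selected.append(best_c)
                        changed = True
            # backward
            while len(selected) > 0:
                idx = [cols.index(w) for w in selected]
                _, pvals, _, _, _ = _ols(X[:, idx], y)
                worst = int(np.argmax(pvals[1:]))
                if pvals[1 + worst] >= self.removal_p:
                    del selected[worst]
                    changed = True
                else:
                    break
            if not changed:
                break
        if not selected:
            self.selected_window_ = None
            self.retained_windows_ = ()
            self.result_ = SelectionResult(method="stepwise", selected_window=None,
                                           flag="none selected")
            return self
        best, aic = _adjudicate_by_aic(selected, X, cols, y)
        j = cols.index(best)
        beta, pvals, _, se, dof = _ols(X[:, [j]], y)
        t_crit = stats.t.ppf(0.975, dof)
        self.selected_window_ = best
        self.retained_windows_ = tuple(selected)
        self.result_ = SelectionResult(
            method="stepwise",
            selected_window=best,
            estimate=float(beta[1]),
            ci_low=float(beta[1] - t_crit * se[1]),
            ci_high=float(beta[1] + t_crit * se[1]),
            p_value=float(pvals[1]),
            aic_by_window=aic,
            retained_windows=tuple(selected),
        )
        return self


class LassoAicWindowSelector(BaseEstimator):
    """LASSO window screening with univariate-AIC adjudication.

    Predictors are standardized and the L1 penalty is chosen by k-fold
    cross-validation (shuffled folds, fixed ``random_state``).  For every
    window retained at the chosen penalty, the univariate OLS AIC
    (n ln(RSS/n) + 2k, k = 3) is computed on the original scale; the window
    with the smallest AIC is selected.  If the LASSO shrinks everything to
    zero, adjudication falls back to AIC over all five windows (flagged).

    Attributes
    ----------
    selected_window_ : str
    retained_windows_ : tuple of str
    alpha_ : float         chosen penalty
    result_ : SelectionResult
    """

    def __init__(self, cv: int = 10, random_state: int = 0, lambda_rule: str = "min"):
        self.cv = cv
        self.random_state = random_state
        self.lambda_rule = lambda_rule

    def fit(self, X, y):
        X, cols = _as_window_matrix(X)
        y = np.asarray(y, dtype=float)
        if y.size <= 10:
            raise ValueError("LASSO selection needs n > 10 subjects")
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("a window column has zero variance")
        Z = (X - mu) / sd
        folds = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        model = LassoCV(cv=folds, max_iter=100000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Z, y)
        alpha = float(model.alpha_)
        coef = model.coef_
        if self.lambda_rule == "1se":
            mse = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
            best = int(np.argmin(mse))
            within = np.nonzero(mse <= mse[best] + se[best])[0]
            alpha = float(model.alphas_[within.min()])  # alphas_ descend: largest penalty
            refit = Lasso(alpha=alpha, max_iter=100000).fit(Z, y)
            coef = refit.coef_
        elif self.lambda_rule != "min":
            raise ValueError("lambda_rule must be 'min' or '1se'")
        retained = [cols[j] for j in np.nonzero(np.abs(coef) > 1e-12)[0]]
        flag = None
        if not retained:
            retained = list(cols)
            flag = "all coefficients shrunk to zero; AIC over all windows"
        best, aic = _adjudicate_by_aic(retained, X, cols, y)
        self.alpha_ = alpha
        self.coef_ = coef
        self.selected_window_ = best
        self.retained_windows_ = tuple(retained)
        self.result_ = SelectionResult(
            method="lasso_aic",
            selected_window=best,
            aic_by_window=aic,
            retained_windows=tuple(retained),
            flag=flag,
        )
        return self


def stepwise_select(dvr, suvr_matrix, region: str | None = None, **params) -> SelectionResult:
    """Functional wrapper over :class:`StepwiseWindowSelector`."""
    sel = StepwiseWindowSelector(**params).fit(suvr_matrix, dvr)
    result = sel.result_
    return SelectionResult(**{**result.__dict__, "region": region})


def lasso_aic_select(dvr, suvr_matrix, seed: int = 0, region: str | None = None,
                     **params) -> SelectionResult:
    """Functional wrapper over :class:`LassoAicWindowSelector`."""
    sel = LassoAicWindowSelector(random_state=seed, **params).fit(suvr_matrix, dvr)
    result = sel.result_
    return SelectionResult(**{**result.__dict__, "region": region})


def consensus_optimal_window(
    agreement_grid: pd.DataFrame, selection_results: dict
) -> pd.DataFrame:
    """Per-region consensus across the four window criteria.

    Winners come from (1) max Pearson r, (2) max ICC, (3) stepwise selection,
    (4) LASSO + AIC; the consensus is the modal winner, ties broken toward
    the earlier window.  ``selection_results`` maps region ->
    {"stepwise": SelectionResult, "lasso_aic": SelectionResult}.
    """
    order = {w: i for i, w in enumerate(WINDOW_ORDER)}
    rows = []
    for region in sorted(agreement_grid["region"].unique()):
        sub = agreement_grid[agreement_grid["region"] == region]
        by_r = sub.loc[sub["pearson_r"].idxmax(), "window"]
        by_icc = sub.loc[sub["icc"].idxmax(), "window"]
        sel = selection_results.get(region, {})
        winners = {
            "pearson": str(by_r),
            "icc": str(by_icc),
            "stepwise": getattr(sel.get("stepwise"), "selected_window", None),
            "lasso_aic": getattr(sel.get("lasso_aic"), "selected_window", None),
        }
        votes = Counter(w for w in winners.values() if w is not None)
        top = max(votes.values())
        tied = [w for w, c in votes.items() if c == top]
        consensus = min(tied, key=lambda w: order.get(w, len(order)))
        rows.append(dict(region=region, consensus_window=consensus, **winners))
    return pd.DataFrame(rows)
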