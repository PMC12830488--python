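"""Agreement grid and window-selection procedures, cross-checked against
independent oracles (ANOVA decomposition, pingouin ICC, KKT conditions)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.linear_model import Lasso

from fespet.agreement import (
    WINDOW_ORDER,
    LassoAicWindowSelector,
    StepwiseWindowSelector,
    agreement_table,
    consensus_optimal_window,
    icc_cronbach,
    pearson_matrix,
    univariate_aic,
)


def _toy_tables(rng, n=20, regions=("a", "b")):
    """Long DVR/SUVR tables with SUVR an affine function of DVR plus noise."""
    dvr_rows, suvr_rows = [], []
    for region in regions:
        dvr = rng.normal(1.5, 0.3, n)
        for i in range(n):
            dvr_rows.append(dict(subject_id=f"S{i:02d}", region=region, dvr=dvr[i]))
        for j, w in enumerate(WINDOW_ORDER):
            suvr = 1.1 * dvr + 0.2 + rng.normal(0, 0.02 * (j + 1), n)
            for i in range(n):
                suvr_rows.append(dict(subject_id=f"S{i:02d}", region=region,
                                      window=w, suvr=suvr[i]))
    return pd.DataFrame(dvr_rows), pd.DataFrame(suvr_rows)


# ---------------------------------------------------------------------------
# Pearson grid
# ---------------------------------------------------------------------------

def test_affine_suvr_gives_r_of_one():
    rng = np.random.default_rng(0)
    dvr, suvr = _toy_tables(rng)
    suvr["suvr"] = suvr.merge(dvr, on=["subject_id", "region"])["dvr"] * 2.0 + 0.5
    grid = pearson_matrix(dvr, suvr)
    np.testing.assert_allclose(grid["pearson_r"], 1.0, atol=1e-12)


def test_pearson_matches_hand_computed_covariance_formula():
    x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
    y = np.array([2.0, 2.5, 3.0, 5.5, 6.0])
    dvr = pd.DataFrame(dict(subject_id=[f"S{i}" for i in range(5)],
                            region="a", dvr=x))
    suvr = pd.DataFrame(dict(subject_id=[f"S{i}" for i in range(5)],
                             region="a", window="30-50", suvr=y))
    grid = pearson_matrix(dvr, suvr)
    r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    t = r_oracle * np.sqrt(3 / (1 - r_oracle**2))
    p_oracle = 2 * stats.t.sf(abs(t), 3)
    cell = grid.iloc[0]
    assert cell["pearson_r"] == pytest.approx(r_oracle, abs=1e-12)
    assert cell["pearson_p"] == pytest.approx(p_oracle, rel=1e-9)


def test_pearson_invariant_to_affine_rescaling():
    rng = np.random.default_rng(1)
    dvr, suvr = _toy_tables(rng, regions=("a",))
    base = pearson_matrix(dvr, suvr)["pearson_r"].to_numpy()
    dvr2 = dvr.assign(dvr=3.0 * dvr["dvr"] - 1.0)
    suvr2 = suvr.assign(suvr=0.2 * suvr["suvr"] + 5.0)
    again = pearson_matrix(dvr2, suvr2)["pearson_r"].to_numpy()
    np.testing.assert_allclose(again, base, atol=1e-12)


def test_insufficient_pairs_flagged_missing():
    dvr = pd.DataFrame(dict(subject_id=["S0", "S1"], region="a", dvr=[1.0, 2.0]))
    suvr = pd.DataFrame(dict(subject_id=["S0", "S1"], region="a",
                             window="30-50", suvr=[1.0, 2.0]))
    grid = pearson_matrix(dvr, suvr)
    assert np.isnan(grid["pearson_r"]).all()


# ---------------------------------------------------------------------------
# ICC / Cronbach's alpha
# ---------------------------------------------------------------------------

def test_icc_is_one_for_identical_and_shifted_columns():
    x = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
    assert icc_cronbach(x, x)[0] == pytest.approx(1.0)
    assert icc_cronbach(x, x + 3.7)[0] == pytest.approx(1.0)


def test_alpha_equals_anova_icc3k_on_random_data():
    """Cronbach's-alpha route == two-way ANOVA ICC(3,k) on 100 datasets."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = rng.integers(5, 40)
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(scale=0.5, size=n)
        icc, p = icc_cronbach(x, y)
        # independent oracle: direct alpha formula for two measures
        alpha = 2.0 * (1.0 - (np.var(x, ddof=1) + np.var(y, ddof=1))
                       / np.var(x + y, ddof=1))
        assert icc == pytest.approx(alpha, abs=1e-10)
        assert 0 < p <= 1


def test_alpha_matches_pingouin_icc3k():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    x = rng.normal(size=25)
    y = 0.9 * x + rng.normal(scale=0.4, size=25)
    icc, p = icc_cronbach(x, y)
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(25), 2),
        "rater": np.tile(["dvr", "suvr"], 25),
        "score": np.column_stack([x, y]).ravel(),
    })
    ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                   ratings="score").set_index("Type")
    # two-way mixed, consistency, average measures = ICC(C,k) = ICC(3,k)
    assert icc == pytest.approx(ref.loc["ICC(C,k)", "ICC"], abs=1e-9)
    assert p == pytest.approx(ref.loc["ICC(C,k)", "pval"], rel=1e-6)


def test_icc_zero_variance_rejected():
    with pytest.raises(ValueError):
        icc_cronbach(np.ones(5), np.ones(5))


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def test_stepwise_selects_the_informative_window():
    rng = np.random.default_rng(3)
    n = 55
    dvr = rng.normal(1.5, 0.3, n)
    X = rng.normal(size=(n, 5))
    X[:, 1] = dvr  # 40-60 column is exactly the response
    sel = StepwiseWindowSelector().fit(X, dvr)
    assert sel.selected_window_ == WINDOW_ORDER[1]
    res = sel.result_
    assert res.ci_low > 0 or res.ci_high < 0  # CI excludes 0
    assert res.p_value < 1e-10


def test_stepwise_needs_enough_subjects():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="n > 10"):
        StepwiseWindowSelector().fit(rng.normal(size=(8, 5)), rng.normal(size=8))


def test_stepwise_is_deterministic():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 5))
    y = X[:, 2] + rng.normal(scale=0.5, size=30)
    a = StepwiseWindowSelector().fit(X, y).result_
    b = StepwiseWindowSelector().fit(X, y).result_
    assert a == b


def test_raw_entry_rule_available_as_config():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(40, 5))
    y = X[:, 0] * 0.25 + rng.normal(size=40)
    raw = StepwiseWindowSelector(entry_adjust="none").fit(X, y)
    adj = StepwiseWindowSelector(entry_adjust="bonferroni").fit(X, y)
    # the raw rule is at least as permissive as the family-wise rule
    assert len(raw.retained_windows_) >= len(adj.retained_windows_)


# ---------------------------------------------------------------------------
# LASSO + AIC
# ---------------------------------------------------------------------------

def test_lasso_penalty_free_limit_matches_ols():
    rng = np.random.default_rng(2)
    n = 50
    X = rng.normal(size=(n, 5))
    beta = np.array([0.5, 0.0, -0.3, 0.0, 0.2])
    y = X @ beta + rng.normal(scale=0.1, size=n)
    Z = (X - X.mean(0)) / X.std(0)
    ols = np.linalg.lstsq(np.column_stack([np.ones(n), Z]), y, rcond=None)[0][1:]
    lasso = Lasso(alpha=1e-8, max_iter=500000).fit(Z, y)
    np.testing.assert_allclose(lasso.coef_, ols, atol=1e-4)


def test_lasso_all_zero_at_lambda_max_and_kkt_conditions():
    """KKT oracle on a tiny instance: |X'(y - Xb)/n| <= alpha with equality
    on the active set; all coefficients vanish at alpha >= alpha_max."""
    rng = np.random.default_rng(4)
    n, p = 8, 3
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = rng.normal(size=n)
    y = y - y.mean()
    alpha_max = np.max(np.abs(X.T @ y)) / n
    assert np.all(Lasso(alpha=alpha_max * 1.0001).fit(X, y).coef_ == 0)
    prev = None
    for alpha in (0.8, 0.4, 0.1, 0.02):
        b = Lasso(alpha=alpha * alpha_max, max_iter=500000, tol=1e-12).fit(X, y).coef_
        grad = X.T @ (y - X @ b) / n
        lam = alpha * alpha_max
        assert np.all(np.abs(grad) <= lam * (1 + 1e-6))
        active = np.abs(b) > 1e-10
        np.testing.assert_allclose(grad[active], lam * np.sign(b[active]), rtol=1e-4)
        if prev is not None:  # path continuity: coefficients grow smoothly
            assert np.all(np.abs(b) >= np.abs(prev) - 1e-6)
        prev = b


def test_lasso_selector_picks_signal_window_and_is_deterministic():
    rng = np.random.default_rng(6)
    n = 55
    dvr = rng.normal(1.5, 0.3, n)
    X = np.column_stack([dvr + rng.normal(scale=s, size=n)
                         for s in (0.05, 0.1, 0.15, 0.2, 0.3)])
    a = LassoAicWindowSelector(random_state=1).fit(X, dvr)
    b = LassoAicWindowSelector(random_state=1).fit(X, dvr)
    assert a.selected_window_ == WINDOW_ORDER[0]
    assert a.result_ == b.result_
    # AIC adjudication agrees with direct univariate AIC ranking
    aic = {w: univariate_aic(X[:, i], dvr) for i, w in enumerate(WINDOW_ORDER)}
    retained = a.retained_windows_
    assert a.selected_window_ == min(retained, key=lambda w: aic[w])


def test_lasso_all_shrunk_falls_back_to_aic_over_all_windows():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(20, 5))
    y = np.zeros(20)  # no signal at all: LASSO keeps nothing
    sel = LassoAicWindowSelector(random_state=0).fit(X, y)
    assert sel.result_.flag is not None
    assert set(sel.retained_windows_) == set(WINDOW_ORDER)


def test_aic_ties_break_toward_earlier_window():
    rng = np.random.default_rng(10)
    n = 30
    dvr = rng.normal(1.5, 0.3, n)
    x = dvr + rng.normal(scale=0.1, size=n)
    X = np.column_stack([x, x, rng.normal(size=n), rng.normal(size=n),
                         rng.normal(size=n)])  # identical first two columns
    from fespet.agreement import _adjudicate_by_aic
    best, aic = _adjudicate_by_aic(list(WINDOW_ORDER[:2]), X, list(WINDOW_ORDER), dvr)
    assert aic[WINDOW_ORDER[0]] == aic[WINDOW_ORDER[1]]
    assert best == WINDOW_ORDER[0]


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _fake_selection(window):
    from fespet.agreement import SelectionResult
    return SelectionResult(method="x", selected_window=window)


def test_consensus_unanimous_and_tiebreak():
    grid = pd.DataFrame([
        dict(region="pit", window="30-50", pearson_r=0.9, icc=0.95),
        dict(region="pit", window="40-60", pearson_r=0.8, icc=0.90),
    ])
    sel = {"pit": {"stepwise": _fake_selection("30-50"),
                   "lasso_aic": _fake_selection("30-50")}}
    out = consensus_optimal_window(grid, sel)
    assert out.loc[0, "consensus_window"] == "30-50"
    # 2-2 tie between 30-50 and 40-60 -> earlier window
    grid2 = pd.DataFrame([
        dict(region="pit", window="30-50", pearson_r=0.9, icc=0.80),
        dict(region="pit", window="40-60", pearson_r=0.8, icc=0.90),
    ])
    sel2 = {"pit": {"stepwise": _fake_selection("30-50"),
                    "lasso_aic": _fake_selection("40-60")}}
    out2 = consensus_optimal_window(grid2, sel2)
    assert out2.loc[0, "consensus_window"] == "30-50"


def test_agreement_table_combines_r_and_icc():
    rng = np.random.default_rng(12)
    dvr, suvr = _toy_tables(rng, n=30)
    grid = agreement_table(dvr, suvr)
    assert {"pearson_r", "pearson_p", "icc", "icc_p"} <= set(grid.columns)
    assert len(grid) == 2 * 5
    assert (grid["icc"] <= 1).all()
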