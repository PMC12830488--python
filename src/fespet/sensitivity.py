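"""Menopause-status sensitivity analyses.

Three procedures:

* interaction models — OLS of DVR on SUVR, menopause group (dummy-coded, PRE
  as reference) and their interaction, with a Wald F test on the interaction
  block, fitted separately per region x window;
* covariate-adjusted standardized group differences — OLS of SUVR on a
  POST-vs-PRE indicator plus covariates (age, SHBG); Cohen's d is the
  adjusted mean difference divided by the residual SD, with a
  normal-approximation 95% CI;
* cognition partial correlations — residualize both the standardized
  cognitive score and the SUVR on covariates (age, education) and correlate
  the residuals; p from t with n - 2 - m df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EffectSizeResult",
    "PartialCorrResult",
    "interaction_model",
    "adjusted_cohens_d",
    "partial_correlation",
    "sensitivity_report",
    "effect_size_band",
]


@dataclass(frozen=True)
class EffectSizeResult:
    """Covariate-adjusted standardized group difference."""

    cohens_d: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusters: tuple = ()
    region: str | None = None
    window: str | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.cohens_d <= self.ci_high):
            raise ValueError("CI must contain the point estimate")


@dataclass(frozen=True)
class PartialCorrResult:
    """Partial correlation of a cognitive outcome with regional SUVR."""

    partial_r: float
    p_value: float
    adjusters: tuple = ()
    region: str | None = None
    window: str | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.partial_r <= 1.0:
            raise ValueError("partial r must be in [-1, 1]")


def effect_size_band(d: float) -> str:
    """Interpretation band: small (0.2), medium (0.5), large (>= 0.8)."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def interaction_model(dvr, suvr, groups) -> dict:
    """OLS of DVR on SUVR x menopause group; Wald p for the interaction block.

    ``groups`` are labels (e.g. PRE/PERI/POST); PRE, or the alphabetically
    first label, is the reference level.  Returns a dict with the interaction
    F statistic, its p-value, per-group slopes and the fitted model.
    """
    dvr = np.asarray(dvr, dtype=float)
    suvr = np.asarray(suvr, dtype=float)
    groups = np.asarray(groups)
    if dvr.shape != suvr.shape or dvr.shape != groups.shape:
        raise ValueError("dvr, suvr and groups must be equal-length vectors")
    levels = sorted(set(groups.tolist()), key=lambda g: (g != "PRE", g))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = {g: int(np.sum(groups == g)) for g in levels}
    if min(counts.values()) < 3:
        raise ValueError(f"each group needs >= 3 subjects, got {counts}")
    n = dvr.size
    cols = [np.ones(n), suvr]
    names = ["intercept", "suvr"]
    for g in levels[1:]:
        ind = (groups == g).astype(float)
        cols += [ind, ind * suvr]
        names += [f"group[{g}]", f"suvr:group[{g}]"]
    X = np.column_stack(cols)
    model = sm.OLS(dvr, pd.DataFrame(X, columns=names)).fit()
    inter_terms = [nm for nm in names if nm.startswith("suvr:group")]
    contrast = np.zeros((len(inter_terms), len(names)))
    for i, nm in enumerate(inter_terms):
        contrast[i, names.index(nm)] = 1.0
    wald = model.f_test(contrast)
    slopes = {levels[0]: float(model.params["suvr"])}
    for g in levels[1:]:
        slopes[g] = float(model.params["suvr"] + model.params[f"suvr:group[{g}]"])
    return dict(
        interaction_f=float(wald.fvalue),
        interaction_p=float(wald.pvalue),
        slopes=slopes,
        model=model,
    )


def adjusted_cohens_d(
    suvr,
    groups,
    covariates: pd.DataFrame | None = None,
    contrast: tuple = ("POST", "PRE"),
    region: str | None = None,
    window: str | None = None,
) -> EffectSizeResult:
    """Covariate-adjusted Cohen's d for a two-group contrast (POST vs PRE).

    Fits OLS of SUVR on the group indicator plus covariates; the adjusted
    mean difference is the group coefficient (evaluated at covariate means),
    and d divides it by the residual SD of the model.  With no covariates
    this reduces exactly to the classical pooled-SD two-group d.  The 95% CI
    is the normal approximation d +/- 1.96 se(coef)/sd_resid.
    """
    suvr = np.asarray(suvr, dtype=float)
    groups = np.asarray(groups)
    keep = np.isin(groups, list(contrast))
    suvr, groups = suvr[keep], groups[keep]
    n_hi = int(np.sum(groups == contrast[0]))
    n_lo = int(np.sum(groups == contrast[1]))
    if min(n_hi, n_lo) < 3:
        raise ValueError("both contrast groups need >= 3 subjects")
    ind = (groups == contrast[0]).astype(float)
    names = ["intercept", "group"]
    cols = [np.ones(suvr.size), ind]
    adjusters: tuple = ()
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[keep] if isinstance(covariates, pd.DataFrame) else covariates[keep]
        cov = pd.DataFrame(cov).reset_index(drop=True)
        if cov.isna().any().any():
            raise ValueError("covariates must be complete")
        adjusters = tuple(map(str, cov.columns))
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates: design matrix is rank deficient")
    model = sm.OLS(suvr, pd.DataFrame(X, columns=names)).fit()
    sd_resid = float(np.sqrt(model.mse_resid))
    diff = float(model.params["group"])
    se = float(model.bse["group"])
    d = diff / sd_resid
    z = stats.norm.ppf(0.975)
    half = z * se / sd_resid
    return EffectSizeResult(
        cohens_d=d,
        ci_low=d - half,
        ci_high=d + half,
        p_value=float(model.pvalues["group"]),
        adjusters=adjusters,
        region=region,
        window=window,
    )


def partial_correlation(
    score,
    suvr,
    covariates: pd.DataFrame | None = None,
    region: str | None = None,
    window: str | None = None,
    outcome: str | None = None,
) -> PartialCorrResult:
    """Partial Pearson correlation of a cognitive score with SUVR.

    Both variables are residualized on the covariates (with intercept) and
    the residuals correlated; with no covariates this is plain Pearson r.
    p is two-sided from t with n - 2 - m df (m covariates).  Negative r means
    higher uptake goes with lower performance.
    """
    score = np.asarray(score, dtype=float)
    suvr = np.asarray(suvr, dtype=float)
    if score.shape != suvr.shape:
        raise ValueError("score and suvr must be equal-length vectors")
    n = score.size
    m = 0
    scale2 = max(float(np.var(score)), float(np.var(suvr)), 1e-300)
    if covariates is not None and np.ndim(covariates) and np.shape(covariates)[-1] > 0:
        cov = pd.DataFrame(covariates)
        if cov.isna().any().any():
            raise ValueError("covariates must be complete")
        m = cov.shape[1]
        X = np.column_stack([np.ones(n), cov.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        hat = X @ np.linalg.lstsq(X, np.column_stack([score, suvr]), rcond=None)[0]
        score = score - hat[:, 0]
        suvr = suvr - hat[:, 1]
    if n - 2 - m < 3:
        raise ValueError("need at least 5 complete cases beyond the covariates")
    sx = score - score.mean()
    sy = suvr - suvr.mean()
    # a variable fully explained by the covariates leaves only floating-point
    # residue; its partial correlation is zero by convention
    tiny = n * scale2 * 1e-24
    if sx @ sx <= tiny or sy @ sy <= tiny:
        r = 0.0
    else:
        r = float(np.clip((sx @ sy) / np.sqrt((sx @ sx) * (sy @ sy)), -1.0, 1.0))
    df = n - 2 - m
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(partial_r=r, p_value=p, adjusters=tuple(
        map(str, pd.DataFrame(covariates).columns)) if m else (),
        region=region, window=window, outcome=outcome)


COGNITIVE_OUTCOMES = ("memory_immediate", "memory_delayed", "global_cognition")


def sensitivity_report(
    subjects: pd.DataFrame,
    dvr_table: pd.DataFrame,
    suvr_table: pd.DataFrame,
    effect_windows: tuple = ("30-50", "40-60"),
    cognition_regions=None,
) -> dict:
    """Run the full sensitivity battery on a cohort.

    Returns a dict of long-format DataFrames:

    * ``interactions`` — SUVR x group interaction p per region x window;
    * ``effect_sizes`` — adjusted POST-vs-PRE Cohen's d (age + SHBG) for the
      two carried-forward windows;
    * ``cognition`` — partial correlations (age + education adjusted) of
      z-scored cognitive outcomes with SUVR;
    * ``scatter`` — subject-level DVR/SUVR/group rows for scatter plots.

    Ordering is deterministic: regions alphabetical, windows chronological.
    """
    merged = suvr_table.merge(dvr_table[["subject_id", "region", "dvr"]],
                              on=["subject_id", "region"])
    merged = merged.merge(subjects, on="subject_id")
    merged = merged.sort_values(["region", "window", "subject_id"]).reset_index(drop=True)

    regions = sorted(merged["region"].unique())
    windows = [w for w in merged["window"].astype(str).unique()]
    if cognition_regions is None:
        cognition_regions = regions

    inter_rows, d_rows, cog_rows = [], [], []
    for region in regions:
        for window in windows:
            cell = merged[(merged["region"] == region)
                          & (merged["window"].astype(str) == window)]
            res = interaction_model(cell["dvr"], cell["suvr"], cell["group"])
            inter_rows.append(dict(region=region, window=window,
                                   interaction_f=res["interaction_f"],
                                   interaction_p=res["interaction_p"]))
            if window in effect_windows:
                eff = adjusted_cohens_d(
                    cell["suvr"].to_numpy(),
                    cell["group"].to_numpy(),
                    covariates=cell[["age_years", "shbg_nmol_L"]],
                    region=region, window=window,
                )
                d_rows.append(dict(region=region, window=window,
                                   cohens_d=eff.cohens_d, ci_low=eff.ci_low,
                                   ci_high=eff.ci_high, p_value=eff.p_value,
                                   band=effect_size_band(eff.cohens_d)))
                if region in cognition_regions:
                    for outcome in COGNITIVE_OUTCOMES:
                        z = cell[outcome].to_numpy(dtype=float)
                        z = (z - z.mean()) / z.std(ddof=1)
                        pc = partial_correlation(
                            z, cell["suvr"].to_numpy(),
                            covariates=cell[["age_years", "education_years"]],
                            region=region, window=window, outcome=outcome,
                        )
                        cog_rows.append(dict(region=region, window=window,
                                             outcome=outcome,
                                             partial_r=pc.partial_r,
                                             p_value=pc.p_value))
    scatter = merged[["subject_id", "group", "region", "window", "dvr", "suvr"]].copy()
    scatter["window"] = scatter["window"].astype(str)
    empty_cols = dict(
        interactions=["region", "window", "interaction_f", "interaction_p"],
        effect_sizes=["region", "window", "cohens_d", "ci_low", "ci_high",
                      "p_value", "band"],
        cognition=["region", "window", "outcome", "partial_r", "p_value"],
    )
    out = dict(
        interactions=pd.DataFrame(inter_rows, columns=empty_cols["interactions"]),
        effect_sizes=pd.DataFrame(d_rows, columns=empty_cols["effect_sizes"]),
        cognition=pd.DataFrame(cog_rows, columns=empty_cols["cognition"]),
        scatter=scatter,
    )
    return out
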