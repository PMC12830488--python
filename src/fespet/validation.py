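"""Replicate-level validation experiments.

These experiments characterize the window-selection battery over many
simulated cohorts: how often each procedure picks the 30-50 min window when
the design makes that window's agreement genuinely highest, how the
agreement profile decays across windows, the distribution of adjusted
POST-vs-PRE effect sizes, the recovery of generated binding-cognition
associations, and the stepwise false-selection rate under a global null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import (
    WINDOW_ORDER,
    LassoAicWindowSelector,
    StepwiseWindowSelector,
    agreement_table,
    consensus_optimal_window,
)
from .logan import roi_dvr_table
from .sensitivity import adjusted_cohens_d, partial_correlation
from .simulate import Cohort, CohortDesign, selection_validation_design, simulate_cohort
from .suvr import suvr_table

__all__ = [
    "BatteryResult",
    "run_selection_battery",
    "null_stepwise_rate",
    "child_seeds",
]


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds (< 2**31) derived from one seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31)


@dataclass
class BatteryResult:
    """Aggregated outcomes of a replicate battery."""

    n_replicates: int
    selection_counts: pd.DataFrame  # region x method -> counts per window
    agreement_means: pd.DataFrame   # region x window -> mean r, mean icc
    effect_sizes: pd.DataFrame      # replicate x region x window -> cohen's d
    cognition: pd.DataFrame         # replicate-level partial correlations
    per_replicate: list = field(default_factory=list)

    def selection_rate(self, region: str, method: str, window: str) -> float:
        sub = self.selection_counts
        row = sub[(sub["region"] == region) & (sub["method"] == method)
                  & (sub["window"] == window)]
        total = sub[(sub["region"] == region) & (sub["method"] == method)]["count"].sum()
        n = int(row["count"].iloc[0]) if len(row) else 0
        return n / total if total else float("nan")


def analyze_cohort(cohort: Cohort, t_star: float = 30.0, lasso_seed: int = 0):
    """Quantify one cohort: DVR table, SUVR table, agreement grid and the
    per-region selections/consensus."""
    dvr = roi_dvr_table(cohort.tacs, t_star=t_star)
    suvr = suvr_table(cohort.static_tacs)
    grid = agreement_table(dvr, suvr)
    selections = {}
    for region in sorted(dvr["region"].unique()):
        y = dvr[dvr["region"] == region].sort_values("subject_id")["dvr"].to_numpy()
        wide = (suvr[suvr["region"] == region]
                .pivot(index="subject_id", columns="window", values="suvr")
                .sort_index())
        wide = wide[[w for w in WINDOW_ORDER if w in wide.columns]]
        step = StepwiseWindowSelector().fit(wide, y)
        lasso = LassoAicWindowSelector(random_state=lasso_seed).fit(wide, y)
        selections[region] = {"stepwise": step.result_, "lasso_aic": lasso.result_}
    consensus = consensus_optimal_window(grid, selections)
    return dict(dvr=dvr, suvr=suvr, grid=grid, selections=selections,
                consensus=consensus)


def run_selection_battery(
    n_replicates: int = 200,
    seed: int = 0,
    design_factory=selection_validation_design,
    regions=None,
    effect_windows: tuple = ("30-50", "40-60"),
    cognition_region: str = "hippocampus",
    cognition_outcome: str = "memory_delayed",
) -> BatteryResult:
    """Run the agreement/selection/sensitivity battery over many cohorts.

    ``design_factory(seed=...)`` builds the per-replicate CohortDesign;
    ``regions`` optionally restricts the simulated regions (smaller = faster).
    """
    seeds = child_seeds(seed, n_replicates)
    sel_rows, agree_rows, d_rows, cog_rows = [], [], [], []
    for rep, s in enumerate(seeds):
        design: CohortDesign = design_factory(seed=int(s))
        if regions is not None:
            from dataclasses import replace
            design = replace(design, regions={r: design.regions[r] for r in regions})
        cohort = simulate_cohort(design)
        res = analyze_cohort(cohort, lasso_seed=int(s))
        for region, sel in res["selections"].items():
            for method, r in sel.items():
                sel_rows.append(dict(replicate=rep, region=region, method=method,
                                     window=r.selected_window))
        for _, row in res["consensus"].iterrows():
            sel_rows.append(dict(replicate=rep, region=row["region"],
                                 method="consensus", window=row["consensus_window"]))
        for _, row in res["grid"].iterrows():
            agree_rows.append(dict(replicate=rep, region=row["region"],
                                   window=row["window"], pearson_r=row["pearson_r"],
                                   icc=row["icc"]))
        merged = res["suvr"].merge(cohort.subjects, on="subject_id")
        for region in res["suvr"]["region"].unique():
            for window in effect_windows:
                cell = merged[(merged["region"] == region)
                              & (merged["window"].astype(str) == window)]
                try:
                    eff = adjusted_cohens_d(
                        cell["suvr"].to_numpy(), cell["group"].to_numpy(),
                        covariates=cell[["age_years", "shbg_nmol_L"]],
                    )
                except ValueError:
                    continue
                d_rows.append(dict(replicate=rep, region=region, window=window,
                                   cohens_d=eff.cohens_d, p_value=eff.p_value))
        if cognition_region in res["suvr"]["region"].unique():
            for window in effect_windows:
                cell = merged[(merged["region"] == cognition_region)
                              & (merged["window"].astype(str) == window)]
                z = cell[cognition_outcome].to_numpy(dtype=float)
                z = (z - z.mean()) / z.std(ddof=1)
                pc = partial_correlation(
                    z, cell["suvr"].to_numpy(),
                    covariates=cell[["age_years", "education_years"]],
                )
                cog_rows.append(dict(replicate=rep, region=cognition_region,
                                     window=window, outcome=cognition_outcome,
                                     partial_r=pc.partial_r, p_value=pc.p_value))

    selections = pd.DataFrame(sel_rows)
    counts = (selections.groupby(["region", "method", "window"], dropna=False)
              .size().rename("count").reset_index())
    agreement = pd.DataFrame(agree_rows)
    means = (agreement.groupby(["region", "window"])
             .agg(pearson_r=("pearson_r", "mean"), icc=("icc", "mean"))
             .reset_index())
    return BatteryResult(
        n_replicates=n_replicates,
        selection_counts=counts,
        agreement_means=means,
        effect_sizes=pd.DataFrame(d_rows),
        cognition=pd.DataFrame(cog_rows),
    )


def null_stepwise_rate(n_replicates: int = 500, n: int = 55, seed: int = 0,
                       **selector_params) -> float:
    """Fraction of pure-noise replicates in which stepwise selects nothing.

    All five window columns are independent standard normals, as is the DVR
    response; with the family-wise entry rule the non-selection rate should
    stay near 1 - entry_p.
    """
    seeds = child_seeds(seed, n_replicates)
    none = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        X = rng.normal(size=(n, 5))
        y = rng.normal(size=n)
        sel = StepwiseWindowSelector(**selector_params).fit(X, y)
        none += sel.selected_window_ is None
    return none / n_replicates
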