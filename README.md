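# fespet

Quantification and static-window validation for brain estrogen-receptor PET
with 16α-[¹⁸F]fluoro-17β-estradiol (¹⁸F-FES).

## The problem

Dynamic 90-min ¹⁸F-FES PET with Logan reference-tissue graphical analysis is
the quantitative standard for measuring regional estrogen-receptor (ERα)
availability in the brain — the distribution volume ratio
DVR = Vt/Vt′ = 1 + BPnd, with the cerebellar crus II gray matter as the
reference tissue. For clinical use a single late static image is far more
practical: the standardized uptake value ratio (SUVR) over a 20-min window
needs no dynamic acquisition and no kinetic modeling. The question this
package addresses is *which* 20-min window (30–50, 40–60, 50–70, 60–80 or
70–90 min post-injection) yields SUVRs most consistent with DVR, and whether
that window preserves the scientifically relevant contrasts: the elevation of
pituitary binding after menopause and the negative associations between
limbic/frontal binding and memory performance.

Because dynamic cohort data of this kind are not publicly deposited, the
package ships a first-class simulator: reversible two-tissue-compartment
(2TCM) kinetics driven by a tri-exponential plasma model, framed onto the
30-frame / 90-min schedule (4 × 15, 4 × 30, 3 × 60, 2 × 120, 5 × 240,
12 × 300 s), with count-statistics noise, three menopause groups
(n = 18/18/19), a 36% postmenopausal pituitary elevation, covariates (age,
SHBG, education) and cognition scores generated with negative slopes on
hippocampal binding.

## What it computes

* **Logan reference-tissue DVR** — `LoganReferenceModel` fits the late-time
  slope of ∫C_T/C_T against ∫C_ref/C_T (optionally + C_ref/(k₂′·C_T)), with
  t\* = 30 min by default or a linearity-based selector; voxelwise maps via
  `parametric_bpnd` (only BPnd > 0 retained).
* **Static-window SUVR** — duration-weighted window means normalized to the
  cerebellar reference (`suvr_table`), for the five canonical windows.
* **Agreement & window selection** — Pearson r, ICC (two-way mixed,
  consistency, average measures ≡ Cronbach's α), bidirectional stepwise
  regression and LASSO with univariate-AIC adjudication
  (`StepwiseWindowSelector`, `LassoAicWindowSelector`, both
  scikit-learn-style estimators), and a consensus selector.
* **Sensitivity analyses** — SUVR × menopause-group interaction models,
  age/SHBG-adjusted Cohen's d for POST vs PRE, and age/education-adjusted
  partial correlations of cognitive scores with SUVR.

## Worked example

```python
import fespet

# simulate a study-conditions cohort (55 women, 9 regions + reference)
cohort = fespet.simulate_cohort(fespet.default_cohort_design(seed=7))

# quantify
dvr  = fespet.roi_dvr_table(cohort.tacs)            # Logan DVR per subject/region
suvr = fespet.suvr_table(cohort.tacs)               # SUVR per subject/region/window

# agreement grid
grid = fespet.agreement_table(dvr, suvr)
pit = grid[grid.region == "pituitary"][["window", "pearson_r", "icc"]]
print(pit.to_string(index=False))
```

```
window  pearson_r      icc
 30-50   0.991733 0.992790
 40-60   0.994216 0.985817
 50-70   0.990824 0.984121
 60-80   0.990459 0.981845
 70-90   0.983101 0.969041
```

At this low noise level every window tracks DVR closely (r > 0.98), with ICC
highest at 30–50 min and declining for later windows — later windows carry
more noise and a larger time-dependent overestimation of binding. Under the
window-graded degradation design (`fespet.selection_validation_design`),
where late static images carry accumulated-motion noise, the decline is much
steeper and the stepwise, LASSO+AIC and consensus selectors pick the
30–50 min window in ≈ 99–100% of replicate cohorts.

The same pipeline runs from the shell:

```bash
fespet run --stage all --seed 7 --outdir out/
```

writing TACs, DVR/SUVR tables, the agreement grid, selection and consensus
tables, and the sensitivity (effect-size / cognition) tables as CSV.

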