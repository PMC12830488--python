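# Methods

This note documents the models, parameter choices and numerical conventions
behind `fespet`, and what the synthetic-data experiments do and do not show.

## Kinetic model and plasma input

Tissue activity follows the reversible two-tissue compartment model (2TCM)
with rate constants K₁ (mL/cm³/min), k₂, k₃, k₄ (1/min) and a fractional
blood volume v_b (whole blood taken equal to plasma). The total distribution
volume is Vt = (K₁/k₂)(1 + k₃/k₄); the one-tissue case (k₃ = k₄ = 0) has
Vt = K₁/k₂, and k₃ > 0 with k₄ = 0 (irreversible trapping) is rejected
because the ratio methods studied here presuppose reversible binding.

No arterial input is available for this tracer in the population of
interest, and none is needed by the reference-tissue methods; a plasma model
exists only to drive the simulator. We use a Feng-type tri-exponential
(ramp-plus-exponentials) input whose absolute scale is set so that simulated
brain concentrations are a few kBq/mL, plausible for a ~222 MBq injection;
the scale cancels exactly in both DVR and SUVR, so only the shape matters.
The tissue solution is evaluated in closed form (bi-exponential impulse
response convolved analytically with each plasma term, with series-limit
fallbacks at coincident rate constants), which makes cohort-scale simulation
cheap and is verified in the tests against direct ODE integration (0.1%)
and against high-resolution numerical convolution for the one-tissue case.

Default kinetics: the cerebellar reference is a fixed one-tissue model
(K₁ = 0.2, k₂ = 0.2, Vt′ = 1) shared by all subjects — the reference region
was selected in the field precisely for uptake invariant to the exposure of
interest, so subject-level variation there is omitted. Binding regions share
K₁, k₂ with the reference and vary only k₃ (k₄ = 0.08 fixed), so a drawn DVR
maps to k₃ = k₄(DVR − 1): delivery is constant and DVR differences reflect
receptor binding, matching the receptor-density interpretation. With these
rates, tissue curves approach transient equilibrium on the time scale of the
scan; the reference-TAC-only Logan slope at t\* = 30 min recovers true DVR
within 5% over DVR ∈ [1, 2.5], the accuracy regime in which the comparison
of DVR with late static windows is meaningful. With much slower kinetics
(e.g. reference efflux k₂′ = 0.05) the omitted k₂′ term biases DVR low; the
k₂′-corrected transform is provided and demonstrably reduces that bias.

## Framing and noise

Frame values are exact time-averages of the continuous curve over each frame
(16-point Gauss–Legendre per frame, machine-precision for these smooth
curves). The acquisition grid is the 30-frame / 90-min schedule
(4 × 15, 4 × 30, 3 × 60, 2 × 120, 5 × 240, 12 × 300 s); seconds on disk,
minutes in computation, converted only at the I/O boundary.

Noise on decay-corrected data has two Gaussian components added in
quadrature:

* a count-statistics term with SD
  `noise_scale · sqrt(max(a,0) · exp(λ_phys t_mid) / Δt)`,
  λ_phys = ln 2 / 109.77 min⁻¹ (F-18): late frames are reconstructed from
  fewer true counts, so decay-corrected noise grows with the decay factor
  and shrinks with frame duration. The default `noise_scale = 0.1` yields
  ~3–5% frame-level noise on late 300-s frames, typical for ROI statistics.
* an optional multiplicative late-scan degradation term with fractional SD
  `late_noise_slope · max(0, t_mid − 30)/60` (the slope is the fractional SD
  reached at 90 min), emulating the accumulated subject motion and residual
  misregistration of long scans. It is off by default.

When the degradation term is active, the cohort carries two TAC sets: the
motion-corrected **dynamic** series (count noise only), which feeds the
Logan analysis, and an independently realized **static** series with the
degradation noise, which feeds the window SUVRs. This mirrors practice —
statically summed late images are reconstructed and registered separately
from the early-anchored, motion-corrected dynamic series — and it is what
makes the window comparison well-posed: noise in the static windows is then
genuinely window-specific rather than shared with the DVR estimate.

## Cohort designs

The **default design** encodes the study conditions: groups PRE/PERI/POST of
n = 18/18/19; true pituitary DVR means 1.50/1.77/2.04 (a 36% POST-vs-PRE
elevation) with between-subject SD 0.45; eight exploratory regions with
smaller elevations and spreads chosen so the POST-vs-PRE standardized
differences fall in the reported bands (large for amygdala, hippocampus,
frontal and posterior cingulate; medium for hypothalamus/thalamus; small for
caudate). Draws below DVR = 1 are truncated to 1 and flagged; truncation
pulls the realized POST/PRE mean ratio to ≈ 1.33. A subject-level shared
factor (correlation 0.6 between regions) makes regional binding levels
correlate within subject, as they do in real data. Covariates: age
46/50/56 ± 4 y by group (clipped to 40–65), SHBG log-normal (median
60 nmol/L, σ_log 0.4), education 17 ± 2 y. Cognition scores are generated on
a standardized scale as
`slope · z(hippocampal binding) + (−0.15) · z(age) + N(0, 0.93²)` with
slopes −0.40/−0.45/−0.40 for immediate recall, delayed recall and global
cognition — sized so the recovered binding–memory partial correlation is
≈ −0.4, the magnitude of the strongest reported associations for this
tracer.

The **selection-validation design** differs only in noise:
`noise_scale = 0.35` and `late_noise_slope = 0.55`. Under it, the DVR–SUVR
agreement is genuinely highest at 30–50 min and declines with window start
(mean Pearson r ≈ 0.93 → 0.59 for the pituitary), which is the regime the
window-selection battery is meant to detect.

What the simulator does **not** model: attenuation/scatter physics,
reconstruction, partial-volume effects, head motion as a spatial process,
metabolite kinetics, or any SHBG effect on tracer availability. Passing
tests therefore show that the estimators are correct and the selection
battery behaves as designed under 2TCM data with realistic noise — not that
any particular window is optimal for real scanners and real heads.

## Quantification conventions

* Logan cumulative integrals are rectangular (frame value × duration) —
  the data exist only as framed averages — with frame midpoints as time
  coordinates and a linear build-up before a late-starting schedule.
* Regression is unweighted OLS by default; frame-duration weighting is
  available. The k₂′ term is omitted by default (reference-TAC-only
  transform); a user-supplied k₂′ variant is provided.
* t\* defaults to 30 min — the start of the twelve 300-s frames, aligning
  the kinetic window with the earliest static window studied — with a
  linearity-based selector (`max_rel_deviation = 0.10`, fallback 30 min
  with a warning) available.
* Frames with non-positive target activity under heavy noise are dropped,
  never clamped, to avoid truncation bias; leading pre-arrival zero frames
  are dropped silently.
* Voxel maps retain only BPnd > 0; masked voxels carry NaN. ROI DVR is
  available both as the mean of retained-voxel (1 + BPnd) and as
  ROI-TAC-then-fit; the two agree on noise-free data.
* "Summed" static images are duration-weighted means (sums differ by a
  constant that cancels in the ratio). The five canonical windows align
  exactly with the 300-s frame grid; arbitrary windows require explicit
  lenient (fractional-weight) mode.
* Decay correction is assumed already applied; none is re-applied.

## Statistical conventions

* ICC is the two-way mixed, consistency, average-measures form, computed as
  Cronbach's α (for two measures α = 2(1 − (Var x + Var y)/Var(x+y))), which
  equals the ANOVA ICC(3,k); p from F = MSR/MSE with (n−1, n−1) df.
* Stepwise selection is bidirectional with entry p < 0.05 and removal
  p ≥ 0.10. The entry p-value is Bonferroni-adjusted across the candidates
  currently under consideration, keeping the family-wise false-selection
  rate near the nominal level under a global null (measured ≈ 5% at n = 55
  with five noise candidates); the classical raw-p rule is available via
  `entry_adjust="none"`. When several windows survive, the reported window
  is the one whose univariate model minimizes AIC.
* LASSO standardizes predictors and picks the penalty by 10-fold
  cross-validation with shuffled, seeded folds (λ_min default, λ_1se
  optional); among retained windows the univariate OLS AIC
  (n·ln(RSS/n) + 2k, k = 3 — slope, intercept, error variance; only
  differences matter) adjudicates. If everything is shrunk to zero, AIC runs
  over all five windows and the result is flagged.
* All AIC and consensus ties break toward the earlier window (earlier
  windows are operationally preferable).
* Adjusted Cohen's d divides the group coefficient of an OLS of SUVR on
  group + covariates (the adjusted marginal mean difference) by the model's
  residual SD; with no covariates this reduces exactly to the classical
  pooled-SD d. The 95% CI is the normal approximation
  d ± 1.96·se(coef)/sd_resid; a seeded bootstrap would be a drop-in
  alternative but is not needed at these sample sizes.
* Partial correlations residualize both variables on the covariates (with
  intercept) and correlate the residuals; p is two-sided from t with
  n − 2 − m df. Cognitive scores are z-scored within cohort before
  modeling. A variable numerically fully explained by the covariates gets
  partial r = 0 by convention.
* Interaction models regress DVR on SUVR, group dummies (PRE reference) and
  their products, with a Wald F test on the interaction block; under a
  generated equal-slopes null the p-values are uniform (KS-tested).

## Reproducibility and problem sizes

Every artifact is a deterministic function of the config + seed; per-replicate
seeds derive from a `SeedSequence` and stay below 2³¹. The CLI writes a run
manifest with a hash of the scientific configuration (output path excluded).
The replicate batteries use 200 cohorts in the test suite and 100 in
`scripts/acceptance.py`, with 500 replicates for the stepwise null; these
sizes put Monte-Carlo error well inside the asserted margins while keeping a
full run in the minutes range on one CPU.

## Known limitations

* The Logan estimator carries the usual small negative noise/t\* bias;
  accuracy statements hold for the default kinetic regime and t\* = 30 min.
* SUVR overestimates DVR increasingly with window start and with binding;
  the simulator reproduces the direction of this drift, but its magnitude
  depends on kinetic parameters that are not identifiable from the data the
  package targets.
* The cognition generative model is linear with a single driver region;
  cross-region associations arise only through the shared binding factor.
* The voxel simulator uses labelled slabs with independent voxel noise — no
  spatial correlation, no partial-volume mixing.
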