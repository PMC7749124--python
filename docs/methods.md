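# Methods

## The experiment being modelled

The package analyses a two-year factorial field experiment on young Scots
pine (*Pinus sylvestris*) subjected to two kinds of herbivory: simulated
ungulate browsing (clipping of 50% of the previous season's lateral shoots
while the tree is dormant) and defoliation by European pine sawfly larvae
(*Neodiprion sertifer*) during the growing season.  Sixty-four trees sit in
16 blocks of four neighbouring trees (blocks nested in two stands).  Year 1
is a 2 x 2 factorial (clipped/control x sawflies yes/no, one tree per cell
per block).  Between seasons half the previously clipped and half the
previously un-clipped trees are (re-)clipped and every tree receives
larvae, producing a 4-level browsing history (none / first year only /
second year only / both years) crossed with defoliation once/twice — eight
cells.  Growth is measured as seasonal increments of stem diameter at 0.2 m
and 0.75 m (mm) and of height (cm).

## Synthetic experiment generator

`design_experiment` reproduces the block-stratified randomisation.  The
year-2 escalation is assigned within (block x prior-treatment) strata, with
exactly half of each stand's blocks escalating the previously-defoliated
member of each pair, so prior insect exposure splits evenly across browsing
histories.  With the default 64-tree configuration every year-2 cell holds
exactly 8 trees.  The published treatment table reports unequal cell sizes
(6–8 trees, summing to 56); those counts cannot be derived from the stated
64-tree design and are therefore shipped only as metadata of the packaged
cell-mean table, while the generator produces the balanced allocation the
design implies.

`simulate_growth` draws, per tree, trait and year,

    increment = baseline + slope * start_size + browsing + insects
                + interaction + stand_u + block_u + residual,

with `residual ~ N(0, sd[browsing level]^2)` — the same group-wise variance
structure the inference model estimates.  Starting sizes are drawn once per
tree from the configured normals (defaults: height 172.0 ± 23.6 cm,
diameters 42.0 ± 8.2 mm and 29.5 ± 7.8 mm) and truncated at 1% of their
mean, a deterministic positivity guard preferred over redrawing so that a
(design, effects, seed) triple is bit-reproducible.  Stand and block
intercepts are drawn independently per trait-year; persistent cross-trait
block effects are not emulated, which is a deliberate simplification — the
inference models are fitted per trait-year and never pool across traits.

The default truth (`EffectConfig.field_calibrated`) sets baselines and treatment
shifts so that expected cell means at the mean starting size equal the
observed field cell means, with slopes 0.05 mm/mm (radial) and 0.10 cm/cm
(height).  Noise defaults are residual SD 2.5 mm radial and 9 cm height,
increased 10% per clipping event to emulate the heterogeneity of damaged
trees, block SD 40% and stand SD 20% of the residual SD.  These produce
standard errors of cell means close to the published figures' error bars
(≈1 mm radial, ≈3–4 cm height at 6–8 trees per cell).  What passing tests
on these simulations do *not* show: robustness to non-normal residuals,
measurement error correlated across occasions, spatial autocorrelation
beyond the block level, or determinate-growth carry-over between seasons —
none of which the generator emulates.

## Growth model

Each trait-year is analysed with the linear mixed model

    y = X beta + u_stand + v_block + e,   e_t ~ N(0, sigma_g(t)^2),

where X contains the pre-experiment starting size for that trait plus
browsing, insects and their interaction (treatment coding; reference
levels: un-clipped control, and no-sawflies in year 1 / sawflies-once in
year 2), v is nested in u, and g(t) is the tree's browsing level, giving
one residual SD per browsing group (2 groups in year 1, 4 in year 2).
Estimation is REML on log-parameterised standard deviations via L-BFGS-B
with 3-point finite-difference gradients, a Nelder–Mead polish when the
line search aborts on a flat boundary optimum, and random restarts.  The
heteroscedastic fit always starts from the homoscedastic optimum, so the
nesting property (heteroscedastic REML log-likelihood ≥ homoscedastic)
holds by construction up to optimiser monotonicity.  Variance components
may legitimately hit the lower bound (≈ e^-12 of the response scale), which
is reported as an SD near zero rather than an error.  Non-convergence after
all restarts raises; a silently non-converged fit is never returned.

Linear algebra uses the Woodbury identity on the two-level random-intercept
structure, so each likelihood evaluation is O(n q^2) with q = stands +
blocks; fits at 800 trees take well under a second.

Cross-checks: the heteroscedastic fit agrees with `nlme::lme` +
`varIdent` to ~1e-3 on estimates and log-likelihood, the homoscedastic
submodel with `statsmodels` MixedLM, and the zero-variance limit with OLS
to 1e-6; these oracles live in the test suite, never in the fit path.

### Type II tests

Each fixed term gets a Wald chi-square respecting marginality: the
hypothesis space is the span of the term's coefficient axes made orthogonal
— in the inner product of the coefficient covariance — to the axes of every
term containing it.  Main effects are thus tested without their
interaction but adjusted for other main effects; the interaction (no
higher-order relatives) is tested on its raw coefficients, making its Type
II and Type III tests identical.  Degrees of freedom are the rank of the
resulting contrast (browsing 1/3 for year 1/2, insects 1, interaction 1/3).
No small-sample correction (Kenward–Roger/Satterthwaite) is applied; the
chi-squares are asymptotic.  On null simulations the browsing-term
rejection rate at alpha = 0.05 is ≈0.07 at 128 trees (2 stands x 16
blocks, the size used in the acceptance checks) but ≈0.12 at the 64-tree
field size — a known liberality of Wald tests with group-wise variances
estimated from 16 trees per group, worth remembering when reading
small-sample p-values near the threshold.

### Percentage differences

Reported percentage reductions are computed from unweighted treatment-cell
means: the reference mean averages the cell means at the factor's reference
level over the other factor, the exposed mean pools all other levels the
same way, and the reduction is 100 (ref − exposed)/ref.  A model-adjusted
variant (`adjusted_cell_means`) evaluates the fitted fixed effects at the
mean starting size instead; raw cell means are the default because the
effect-size equations below are defined in terms of treatment means.

## Combined-effect classification

For the three cells combining clipping with repeated defoliation, per-tree
observed relative reductions `Obs = (x̄_control − y)/x̄_control` are
compared with the multiplicative-risk expectation
`Exp = Ind_i + Ind_j − Ind_i·Ind_j`, where each `Ind` is the absolute
relative difference between a single-stressor cell mean and the control
mean.  Because every year-2 tree carries larvae, the control is the
un-clipped defoliated-once cell, the browsing-only references are the
clipped defoliated-once cells, and the insect-only reference is the
un-clipped defoliated-twice cell; means are pooled across stands.  The
per-tree differences `Obs − Exp` are summarised by their mean and a
Student-t 95% CI (n−1 df; a seeded percentile bootstrap is available):
interval above zero = synergistic, below = antagonistic, otherwise
additive, with an interval touching zero counted additive.

Sign convention: written with the literal orientation, observed effects of
damaged trees are negative while Exp is a positive magnitude, which would
label every damaged treatment antagonistic; the package therefore codes
reductions positive so Obs and Exp share a scale (the literal orientation
remains available via `sign="literal"` for sensitivity analysis).

### Operating characteristics (a known limitation)

The t-interval treats Exp and the control mean as constants, but both are
estimated from cells of the same size as the combined cell.  Their
sampling error inflates the variance of mean(Obs − Exp) several-fold
relative to the interval's own standard error, and two bias terms add to
this: |·| in Ind has positive expectation under weak effects (an
antagonistic drift), and the product Ind_i·Ind_j makes the expectation of
D positive when the truth is additive on the increment scale with strong
main effects (a synergistic drift).  Measured on simulations with the
field-calibrated truth and no interaction shifts, the false non-additive
rate is ≈19–21% per trait at the 64-tree design — not the nominal 5% —
and it does not shrink with more trees, because all cells grow together.
The dedicated acceptance check records this rate against its nominal
target and is expected to exceed it; the idealised property (exact 5%
miscoverage when the references are held fixed) is verified separately.
Genuine effects well above the noise floor are still detected reliably: an
injected synergistic shift of 2 residual SDs at 400 trees is labelled
synergistic in ≈100% of replicates.

## Problem sizes and numerical choices

Simulation-based checks use: 100 replicates of the 64-tree design for
classification rates, 100 replicates at 400 trees (2 x 50 x 4) for
coefficient-recovery coverage and synergy detection, 800 trees for
variance-ratio recovery, and 200 replicates at 128 trees for the ANOVA
type-I error — sizes chosen so every Monte-Carlo bound sits several SEs
from its threshold while a full run stays in the minutes range.  Bulk
simulation fits use one restart; interactive fits default to three.
Degenerate inputs: an empty treatment cell raises naming the cell; fewer
than two trees in a classified cell raises (the CI is undefined); negative
increments are flagged as warnings, not errors, since caliper shrinkage is
plausible; a reference mean ≤ 0 makes relative effects undefined and
raises.
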