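# Methods

`meriquant` links three scales of root-meristem growth analysis: per-cell
3D geometry statistics across brassinosteroid (BR) signalling conditions,
growth dynamics from time-lapse data, and a mechanical model of radial
growth of the root cross section. Every input is emulated by the
synthetic-data module, so the full pipeline runs and is validated without
microscopy data. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic conditions do and
do not establish about real data.

## Zone classification

Within a tissue, meristematic cells stay short through repeated
divisions while elongation-zone cells lengthen rapidly, so cell length is
bimodal. A two-component Gaussian mixture is fitted to raw lengths by
expectation–maximization in each tissue × condition stratum, and a cell
is labelled *meristem* when its posterior probability of the short
component strictly exceeds 0.8.

Numerical choices: initialization splits the sample at its median and
takes each half's moments; convergence is |Δ log-likelihood| < 1e-8 with
a 500-iteration cap; components are relabeled so the short one comes
first; a component standard deviation falling below 1e-8 µm raises a
degenerate-fit error (the data do not support two components). Strata
with fewer than 10 cells are skipped with a warning. Thresholding is done
on the log posterior odds, which stays finite where the posterior itself
underflows. The posterior is monotone decreasing in length from the short
mode upward whenever the short component is no wider than the long one;
in the far short tail the wider long component regains a sliver of
density, so global monotonicity is not claimed.

## Geometry statistics

Each geometric parameter is first transformed to an approximately normal
scale — length and depth log, surface area square root, volume cube root,
width untransformed — and distance from the quiescent centre (QC) enters
as its square root. Per parameter and tissue, a linear mixed model

    transformed value ~ treatment + √distance,  random intercept per root

is fitted by REML (statsmodels MixedLM), restricted to meristem cells.
Pairwise treatment contrasts receive a single-step max-|t| (Tukey-type)
adjustment computed from the multivariate t distribution over the
contrast correlation matrix at the residual degrees of freedom; the
quasi-Monte-Carlo CDF evaluation is seeded, so results are reproducible.
Families are corrected with a two-step adaptive procedure: Benjamini–
Hochberg over the M model p-values at α; with m₁ survivors, BH over the
surviving models' contrasts at the adapted level α·m₁/M, which keeps the
false discovery rate at α across the whole experiment.

The share of variance attributed to BR signalling multiplies the
fixed-effect variance fraction — Var(Xβ̂) over Var(Xβ̂) + random-intercept
variance + residual variance — by the treatment share of the fixed Type
II sums of squares (computed from the fixed-effects ANOVA decomposition;
Type II adjusts each term for the other). With generating variances
treatment : distance : root : residual = 2:1:1:1 the analytic share is
(3/5)·(2/3) = 40%, which the pipeline recovers within Monte-Carlo
tolerance.

Two numerical caveats are handled explicitly. First, the REML optimizer
can stop at the random-variance boundary with a small positive estimate,
so "singular" is flagged relatively (random variance < 1% of residual
variance) rather than at an absolute epsilon. Second, the default scipy
optimizer occasionally collapses to a spurious boundary with a broken
Hessian; the fit falls back to Powell and keeps the best sane REML
solution.

## Kinematics

A cell's displacement rate is its endpoint distance difference over the
full imaging window (6 h at 30-minute sampling by default). Rates are
regressed linearly on position to give the velocity field v(x) = a + b·x.
The position covariate is the cell's *time-averaged* distance from the
QC: with near-exponential displacement, regressing on the start distance
inflates the fitted slope at high rates (≈ +29% at a 3-fold condition),
while the track-mean position makes rate/position an unbiased estimate of
the field slope. Regressing on the start position remains available.

Residence time between x₀ = 8 µm and x₁ = 100 µm (the meristem end) is
the closed-form integral of 1/v: (1/b)·ln((a + b·x₁)/(a + b·x₀)), with
the uniform-motion limit (x₁−x₀)/a; the forced-zero-intercept variant is
the default for residence computations. With proportional velocity
fields, residence ratios are inverse rate ratios — a 0.57-fold genotype
spends ≈75% more time traversing the meristem. For genotypes without
live imaging, relative rates come from production bookkeeping: daily root
elongation over mature cell length gives cells produced per day;
meristem length over the length leaving the meristem per day is a
residence proxy whose WT ratio is the relative displacement rate.

## 4D growth rates

Lineage-tracked cells measured at two time points yield per-hour
directional rates: (merged t₁ geometry − t₀ geometry)/Δt. When a cell
divided, daughter lengths and volumes are summed and depths and widths
averaged, so the merged geometry describes the same material as the
mother. Analysis is restricted to cells within 60 µm of the QC at t₀ and
100 µm at t₁ (inside the meristem throughout). Condition effects are
tested by ANCOVA starting from rate ~ condition × distance and dropping
the interaction when its F-test p ≥ 0.05; contrasts are evaluated at the
covariate mean and BH-adjusted within each parameter. A 4D anisotropy
display index is computed as the per-hour change of length²/(depth·width)
between t₀ and the merged t₁ — a reporting convenience, not a fitted
quantity.

## Radial growth model

The cross section is a watertight 2D tessellation: vertices, straight
walls shared by at most two cells, and cell polygons with tissue labels.
Walls are linear springs (tension = stiffness × strain, strain =
(l−l₀)/l₀); each cell pushes on its walls with its turgor pressure
(outward force P × wall length, split between the endpoints, netted over
the two adjacent cells). These forces are exactly −∇ of

    E = Σ_walls ½ k ε² l₀ − Σ_cells P·A,

so relaxation is monotone energy descent (adaptive Barzilai–Borwein
steps with backtracking, a per-iteration displacement cap of 5% of the
mean rest length, and an acceptance allowance of 1e-12·|E| for steps
whose true decrease is below double rounding) until the largest vertex
force is below tolerance. Growth is stress relaxation: per step every
wall's rest length gains extensibility × max(0, strain − threshold) × l₀,
with the wall's extensibility the mean of its adjacent cells' values,
followed by re-relaxation. Only force ratios matter: scaling all
stiffnesses and pressures together leaves equilibrium and trajectory
unchanged.

Wall classes are assigned by precedence from the incident tissues: the
outer boundary is *outer-epidermal*; other walls touching epidermis are
*epidermal-other*; endodermal walls split into *outer-endodermal*
(cortex side, including radial endodermis–endodermis walls) and
*inner-endodermal* (pericycle/stele side); remaining cortex walls are
*cortex*; everything inside is *pericycle–stele*.

Default units are arbitrary but joint: base stiffness 500 per unit
strain, turgor 1 per unit length, giving wall strains of a few percent at
the ~50 µm template radius. The WT-calibrated "dual-ring"
parameterization stiffens the epidermal walls (outer-epidermal 4×,
epidermal-other 2.5×) and both endodermal layers (2×) and softens the
pericycle–stele walls (0.4×). Because hoop tension decays toward the
axis under uniform turgor, stiffness alone cannot make the inner tissues
outgrow the outer ones; extensibility is therefore graded (stele 2.0
down to epidermis 0.1 per step), reproducing the in-vivo pattern in
which the inner tissues — the stele most of all — gain relatively more
area. Against this calibration, a uniform-parameter run overgrows the
outer group (epidermis + cortex) and undergrows the inner group
(endodermis + pericycle + stele) at matched total-area extension; the
comparison uses each run's own relaxed initial state, since different
parameter sets relax to different initial areas.

Two mechanical facts discovered during validation are worth recording.
With exactly uniform turgor the interior walls are load-free, and the
untriangulated interior quads are then finite mechanisms: their slight
compression makes the rotationally symmetric equilibrium an unstable
saddle, and relaxation settles into one of many asymmetric minima of
equal energy (interior cell areas shift by a few percent; tissue-level
results are unaffected). Vertex-level symmetry and equilibrium
uniqueness are therefore only determinate when the interior is
pre-tensioned, e.g. by an inward-graded pressure, which is what the
symmetry and oracle tests use. Second, a linear-spring pressurized cell
has a finite runaway rest length (l₀ → k/(c·P)); unbounded growth at low
stiffness legitimately ends in a simulation error rather than a
trajectory.

### Stiffness fitting

The genotype experiments reduce to two multipliers: one scaling the
inner wall group (inner-endodermal + pericycle–stele), one the outer
group (everything else). Given target inner/outer tissue-area extensions
and a growth-step budget of round(relative_time × WT steps) — a genotype
displacing at r-fold the WT rate spends 1/r of the WT time in the
meristem — Nelder–Mead searches log-multiplier space from (1, 1),
minimizing the maximum relative extension error, and stops as converged
below 0.1%. Identifiability needs a sufficient budget: over short runs
the initial-state effect of inner stiffness nearly cancels its growth
effect and the inner multiplier is poorly determined; at the budgets
used (≥ ~60 steps, or shorter when strong softening raises strains) the
two-target/two-parameter map is well conditioned and known multipliers
are recovered within a few percent.

## Synthetic data

The geometry generator draws cells per tissue, root and condition on the
transformed scales: normal residuals around a baseline plus a linear
trend in √distance, a root-level random intercept, additive condition
shifts (high BR lengthens and thins, low BR shortens and widens), and a
two-component length mixture whose short-component probability decays
logistically with distance (a sharp cut at width 0). Volume is
length × width × depth × 0.85 and surface area 0.9 × the cuboid surface,
so both are recomputable from the linear dimensions. Default sizes — 3
conditions × 4 roots × 5 tissues × 100 cells — echo a realistic segmented
atlas of several thousand cells. Track, 4D-pair and mesh generators are
described with their modules; default anatomy is 20 epidermis, 8 cortex,
8 endodermis, 12 pericycle and 18 stele cells with ring radii
18/24/31/40/50 µm, and the outer boundary carries midpoint vertices so
the polygonal ring areas match the analytic annuli to well under 1%.

What passing tests show — and what they do not. Parameter recovery,
invariants and oracle agreement on these synthetic conditions validate
the *procedures*: the mixture classifier, the mixed-model and FDR
machinery, the kinematics estimators, the merge rules, the simulator and
its fitting loop. They do not certify in-vivo numbers: real segmented
tissue has non-cuboid cell shapes, distance-dependent variance,
segmentation errors, and template-specific mechanics, so quantities tied
to the original microscopy templates (e.g. exact per-tissue extension
percentages) are checked directionally, not numerically.

## Problem sizes

Validation and the reproduction script use deliberately moderate sizes —
tracks of 30 cells per condition, geometry tables of 10³–10⁴ cells,
cross-section templates of ~38 and ~66 cells with WT reference runs of
roughly 60–130 growth steps — chosen so the whole suite reruns quickly
while keeping every estimator's sampling error well inside its test
tolerance. The growth-step size is likewise a resolution choice: halving
it (doubling step counts) changes group extensions by under 0.2%.
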