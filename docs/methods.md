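# Methods

## Maximum growth rate from OD curves

Each culture (strain × environment × replicate) is a series of optical
density readings at strictly increasing times (hours). Raw OD is
background-corrected by one of three methods: subtracting a blank-well
median, the first reading, or `min(od) − ε` (default, ε = 0.005 OD, so the
smallest corrected value is exactly ε and the log stays defined). Corrected
values are clipped at ε.

Exponential growth appears as a straight line in log OD vs time. Instead of
fitting per-culture windows, a single OD interval `[lo, hi]` is selected for
all cultures of an environment: candidate bounds are the `grid_size`
(default 25) quantiles of the pooled corrected OD values, every pair
`lo < hi` that leaves at least `min_points` (default 5) readings in every
culture is scored by the mean per-culture Pearson *r* of log OD vs time on
the retained readings, and the argmax is taken (ties: wider window, then
lower `lo`). The search is exhaustive over the candidate grid, so a
brute-force implementation must agree exactly; an `exhaustive` mode uses
every observed OD value as a candidate instead of quantiles.

Within the chosen window each culture's MGR is the OLS slope of natural-log
corrected OD on time; the same points give the quality score *r*. A culture
passes QC when it retains ≥ `min_points` readings and *r* ≥ 0.99. Natural
log is used throughout, so the slope is the instantaneous exponential rate
per hour (a base change would only rescale it by a constant).

**Numerical caveats.** On saturating (logistic) trajectories the log-slope
within any finite window underestimates the instantaneous rate by roughly
the factor `1 − OD_mid/K` (K the carrying capacity). With additive read
noise the *r*-maximizing window drifts upward in OD, because relative noise
falls with OD while the curvature penalty grows only slowly; at the
generator's default read noise the selected windows sit low enough that the
residual bias is ~3–4%. This is a property of the window objective itself,
not of the implementation. Degenerate inputs: constant series give slope 0
with undefined *r* (QC fail); windows keeping < 2 points give an undefined
MGR; a culture with zero OD variance inside a candidate window makes that
candidate infeasible.

## Heterosis

With `F` the strain × environment mean MGR over QC-passing replicates:

    MPH = F_hybrid − (F_p1 + F_p2) / 2
    BPH = F_hybrid − max(F_p1, F_p2)

Positive BPH means the hybrid beats its best parent; by construction
MPH ≥ BPH, with equality iff the parents tie. Both are invariant to adding
a constant to all fitness values of an environment. Hybrids missing either
parent's value in an environment (e.g. through QC failure) are dropped from
that environment. Crosses are classed DxD / mixed / WxW by parental origin;
for 13 domesticated + 9 wild parents the 231 unordered pairs split
78/117/36.

Class summaries report means and strict positive proportions (exact zeros
count as non-positive and are tabulated separately), either per
hybrid × environment cell or per hybrid after averaging environments — the
two readings of "proportion of hybrids better than expected".

Group comparisons use one mean per strain (averaged over environments and
replicates): heterozygotes vs homozygotes by one-way ANOVA
(F = MS_between/MS_within, df (k−1, N−k)), which for the full design gives
denominator df 251 (all), 89 (domesticated) and 43 (wild). The
wild-vs-domesticated homozygote comparison uses Welch's unequal-variance
*t* on replicate-level values. Correlations of hybrid MGR, MPH and BPH with
parental divergence are Pearson *r* with two-sided p from
`t = r√((n−2)/(1−r²))`, computed per environment (primary) or on
environment-averaged values; raw p-values carry star codes (0.05 / 0.01 /
0.001) with an optional Benjamini–Hochberg column across the grid. Note the
hybrids of a grid cell share parents, so they are not independent draws;
the p-values are descriptive, as is conventional for such designs.

## Variance components and ICC

For a balanced genotype × environment × replicate table the two-way
random-effects components come from expected mean squares:

    σ²_err = MS_within
    σ²_GE  = (MS_GE − MS_within) / n
    σ²_G   = (MS_G − MS_GE) / (e·n)
    σ²_E   = (MS_E − MS_GE) / (g·n)

Moment estimators can go negative by sampling noise; raw values are always
kept, and displayed magnitudes are absolute values. On balanced data these
estimators coincide with REML for this model, which is why the closed form
was preferred over an iterative mixed-model fit. Unbalanced input is
refused unless the caller opts into seeded subsampling to the minimum cell
count. With strain metadata the decomposition is run separately for six
panels: all/domesticated/wild × homozygote/heterozygote.

Replicate repeatability per environment is the one-way intraclass
correlation ICC(1) = (MS_b − MS_w)/(MS_b + (k₀−1) MS_w), with Searle's
k₀ = (N − Σk²ᵢ/N)/(s−1) for unbalanced groups; reported values are
truncated at 0 (raw retained), and the headline is the arithmetic mean over
environments.

## Agar stress assays

Patch reflectance intensities are converted to cell counts through an OLS
calibration line fitted on counted patches (≥ 3 pairs; the fit quality *r*
is reported). Fitness per patch is `ln(N_final/N_initial)/t` (per hour) and
doublings `log₂(N_final/N_initial)` — base 2 for the doubling rule, natural
log for the rate, since the "log ratio" convention is otherwise arbitrary.

Because inocula are pregrown under benign conditions, small initial growth
can be carry-over rather than growth under stress. A strain × condition
whose mean doublings over trials is ≤ 3 is classified nongrowing and all
its fitness values are set to zero; the strain is a grower in that
condition iff at least one trial remains positive *after* zeroing (the
zeroing-first order is the default; the reverse order is available behind a
flag for sensitivity analysis — a condition with trials (3.5, 0, 0)
illustrates the difference: mean ≈ 1.17 ≤ 3, so it is nongrowing despite
one good trial).

Survival curves report the proportion of grower strains per dose along each
agent's gradient, optionally grouped by ploidy class and origin. For the
cross-stress question, fitness at the highest dose of each agent is
normalized by the stress-specific median over growers (nongrowers stay 0),
each strain's empirical mean over the three stresses is formed, and a null
of cross-stress independence is built by drawing (with replacement, zeros
included) one value per stress and averaging, 10,000 times by default. The
empirical and null samples are compared with the two-sample
Kolmogorov–Smirnov test (asymptotic p at effective
n = n₁n₂/(n₁+n₂); adequate at the hundreds-scale sample sizes involved,
slightly conservative under heavy ties).

## The synthetic world

The generator exists so that every analysis stage can be verified against
ground truth; its defaults describe one fixed, study-scale world.

**Phylogeny.** 13 domesticated and 9 wild strains sit in two ultrametric
clades of height H = 8 (arbitrary time units) joined by short stems (0.25).
Kingman coalescent node heights are transformed by `h → H(h/H)^0.25`,
pushing coalescences toward the clade root. This emulates a rapid radiation (star-like clades
with a spread of pair distances), which is what makes the class-mean
ordering and the divergence correlation simultaneously identifiable; a
plain Kingman tree makes mean within-clade divergence almost equal to half
the full root-to-tip path, so DxD and mixed class means would nearly tie.
Pairwise sequence divergence is Poisson-sampled at 1500 substitutions per
unit branch length, giving pair distances of the ~20,000-substitution scale
typical of sequenced yeast strain collections.

**Mutation load.** Each branch receives Poisson(λ_clade × length)
deleterious mutations, λ_dom = 0.8 and λ_wild = 0 by default (the
domesticated clade accumulates load; setting the rates equal is the
negative control that removes all clade differences). Effects are
exponential with mean s = 0.03 (resampled if ≥ 1), fitness is
multiplicative across loci, and dominance h = 0 (fully recessive) so that
mutations private to one parent are completely masked in the hybrid;
mutations shared through common ancestry stay homozygous. Expected
class-mean MPH under these defaults is ≈ 0.059/0.039/0 MGR units for
DxD/mixed/WxW on a 0.2–0.65 per-hour environment baseline — the
published-study regime the world was built to resemble. Observed MGR is
`env_mean × Π(1 − h_i s_i) × exp(g + ε)` with g ~ N(0, 0.035²) per
strain × environment and ε ~ N(0, 0.02²) per replicate.

**Liquid cultures.** OD trajectories are logistic,
`OD(t) = K·od₀·e^{rt}/(K + od₀(e^{rt}−1)) + background + N(0, σ_od)`,
sampled every 0.5 h for 16 h with od₀ = 0.005, K = 2.0, background 0.08 and
σ_od = 2×10⁻⁴. Two of these choices are deliberate identifiability
conditions, not free realism: od₀ equals the analysis ε so the
min-minus-eps correction is exact at t = 0, and σ_od sits at the low end of
plate-reader noise so the *r*-maximizing window settles in the
near-exponential low-OD region (see the growth-rate caveat above). With
larger read noise the window objective prefers high-OD segments and *no*
window estimator recovers the generating rate to 5% under a logistic with
additive noise — a limitation of the objective that the synthetic world
cannot paper over, only avoid.

**Agar assays.** A strain grows at a dose iff
`load + z_agent < threshold(dose)`, with `load` the strain's summed
(expressed) selection coefficients, thresholds falling linearly from 0.6 to
−0.05 along each agent's four-dose gradient, and z_agent ~ N(0, 0.2²) a
per-strain robustness draw independent across agents — so cross-stress
performance is uncorrelated by construction and the resampling null is the
truth (a `cross_stress_correlation` parameter mixes in a shared component
for power studies). Growing patches make 4–6 doublings scaled by the
threshold margin; nongrowing patches show 0.5–2.5 carry-over doublings.
Inocula are ~3×10⁵ cells (1.5 µl of stationary culture); intensities derive
from the true calibration line (2000 cells per intensity unit) with 2%
measurement noise, and 40 counted calibration patches spanning the observed
intensity range carry 3% relative noise. The inoculum size and doubling cap
keep the calibration's intercept uncertainty small relative to initial
patch intensities; with much smaller patches the fitted intercept (whose
standard error is set by the largest patches) would corrupt initial cell
counts and the doubling rule.

**What a green test establishes — and what it does not.** The synthetic
world has exact exponential-within-window growth up to logistic bending,
homoscedastic log-scale noise, a clean two-clade history, no plate spatial
effects, no lag-phase heterogeneity, no aggregation or settling artifacts,
and divergence measured without error. Passing tests therefore establish
correctness of the estimators and the internal consistency of the pipeline
under the complementation model; they do not establish that real plate data
meet these assumptions, and the stochastic headline checks (class-mean
ordering, clade-specific divergence correlation) fail in a ~10% minority of
world realizations purely through coalescent-tree randomness — small trees
sometimes produce nearly equidistant strains with no divergence signal to
detect.

## Known limitations

- One OD window per environment is the only supported mode (per-culture
  windows rejected by design); drop-worst-culture feasibility relaxation is
  not implemented.
- Variance components carry no uncertainty estimates (no bootstrap).
- The K-S p-value is asymptotic; exact small-sample p-values are not
  offered.
- Phylogenetically independent contrasts are not applied to the divergence
  correlations, which share parents across hybrid pairs.
- Nonlinear growth models (Gompertz, logistic fitting), lag/yield
  estimation and dose–response (IC50) fitting are out of scope.
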