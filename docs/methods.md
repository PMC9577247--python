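# Methods

`nanoherit` analyses hierarchically structured material-characterisation
data with tools borrowed from quantitative genetics.  This note records the
models, the defaults and why they were chosen, the numerical decisions, and
the limitations of the synthetic evidence the test suite rests on.

## The experimental model

The data model is a balanced biomass-to-nanopaper hierarchy: biomass
**variety** (the "genetic" factor, 4 sorghum varieties by default), **plant
section** nested within variety (leaf / sheath / stem), crossed with the
mechanical **homogenisation energy** level (low / medium / high), with each
(variety, section, energy) sample fabricated into 2 **nanopaper duplicates**
and each duplicate cut into 8 tensile **strips** — 576 observations per
metric.  A response metric *y* (the headline case is nanopaper tensile
index, N·m/g) is modelled as a purely random-effects Gaussian model

    y = μ + u_variety + u_section(variety) + u_energy + u_nanopaper
        + u_strip + e,        u_i ~ N(0, σ²_i),  e ~ N(0, σ²_e).

All effects are independent zero-mean Gaussians.  Treating the ordinal
energy factor as a random draw per level mirrors the converted
random-effects form in which the headline analysis is carried out; it is a
device for variance accounting, not a claim that energy levels are sampled
from a population.

### Two codings of the duplicate/strip terms

With one measurement per strip, a strip-within-duplicate random term that
gets a fresh level for every observation is *confounded with the residual*.
The package therefore exposes two codings:

* **nested** (default for analysis): duplicates are nested within samples
  (72 duplicate levels); strip-to-strip variation *is* the residual.  This
  is the defensible description of the experiment.
* **literal**: duplicate labels (1–2) and strip labels (1–8) are factor
  levels shared across all samples (2 and 16 levels in total), which makes
  a separate strip:nanopaper component identifiable and yields the
  six-component decomposition of the headline tensile-index analysis.
  The default generator uses this coding so simulated data reproduce the
  structure of that analysis.

## Variance-component estimators

**EMS (method of moments).**  Strata are built sequentially in model-term
order: each term's incidence matrix is residualised against the span of the
grand mean and all earlier terms, and orthonormalised (SVD rank detection).
The observed quadratic form of each stratum is equated to its expectation,
which is linear in the components with coefficients tr(Zᵢᵀ Qₜ Zᵢ); the
square linear system is solved exactly.  For balanced designs this is the
classical expected-mean-squares ANOVA estimator (verified against hand
arithmetic on a one-way layout: groups {1,2,3} and {5,6,7} give between
23/3, within 1).  The raw solutions are exactly unbiased; negative
solutions are truncated to zero and flagged, with the raw values retained.
Unbiasedness checks therefore average the *raw* estimates — truncation
inflates the mean of any low-degrees-of-freedom component.  EMS refuses
unbalanced data and points the caller to REML.

**EM-REML.**  For unbalanced data the same model is fitted by EM on the
restricted likelihood: with V = σ²_e I + Σ σ²_i Zᵢ Zᵢᵀ and the REML
projection P, the updates

    σ²_i ← σ²_i + σ⁴_i (yᵀP Zᵢ Zᵢᵀ P y − tr(Zᵢᵀ P Zᵢ)) / q_i

keep every component non-negative and never decrease the restricted
log-likelihood (the per-iteration trace is kept on the result for
inspection).  Initialisation is var(y)/(k+1) for every component —
positive and scale-aware.  Convergence is declared when the largest
absolute component change drops below `tol` (default 1e-8, `max_iter`
500).  EM converges quickly at interior optima (tens of iterations) but
slows markedly when a component approaches the zero boundary; callers
fitting near-boundary data should expect to raise `max_iter` or loosen
`tol`.  On balanced data with strictly positive EMS solutions the two
estimators agree (observed to ~1e-13 relative), the classical
balanced-ANOVA/REML equivalence.

## Heritability shares

A term's share is its variance over the sum of *all* components including
the residual, so shares sum to one (the published decomposition's share
column sums to 100%).  Genetic heritability h² is the summed share of the
biomass terms, by default {Variety, Section:Variety}; the set is
configurable.  Shares are kept unrounded internally and rounded to one
decimal only for display.  Feeding the published rounded tensile-index
variances (0.01, 57.40, 6.74, 110.59, 1.28, 137.34) through the partition
reproduces the published share column to ±0.1 percentage points for every
term with variance ≥ 1; the 0.01-variance strip term's printed share
(0.004%) was evidently computed from unrounded inputs and cannot be
recovered from the rounded table, so it is excluded from that check.

**Bootstrap intervals.**  `bootstrap_share_ci` is a parametric bootstrap:
simulate from the fitted components, refit by EMS, take 2.5/97.5
percentiles of each share.  Coverage is adequate for terms with reasonable
replication (measured 92% for the 12-level section-within-variety term at
a nominal 95%), but *undercovers for 2–3-level factors* (74% for the
3-level energy factor): a variance share at 1–2 denominator degrees of
freedom is too skewed for the percentile method.  Treat intervals for such
terms as optimistic.

## Clustering

Sample and metric dendrograms come from a Lance–Williams agglomeration
written for bit-reproducibility: at equal merge distances the pair whose
smallest leaf labels sort first merges first, and child order inside a
merge puts the clade with the smaller leaf label on the left.  Merge
heights match `scipy.cluster.hierarchy.linkage` on tie-free inputs for all
four supported linkages (single, complete, average, Ward).  Defaults
follow field practice: metrics are clustered on correlation distance
(1 − Pearson r) with average linkage; samples on euclidean distance of
z-standardised metrics with Ward linkage.  Standardisation uses the sample
standard deviation (ddof = 1); zero-spread columns are mapped to zero and
flagged rather than failing.  `cut(k)` removes the k−1 highest merges and
numbers groups by their lexicographically smallest leaf.  Newick export
encodes branch lengths as parent-minus-child merge heights, so leaf-to-leaf
path lengths equal twice the cophenetic height; round-trips through an
independent parser are exact to 1e-9.

## Quality scores, selection gradients and predicted response

A quality definition is a named set of (metric, weight ≥ 0, direction ±1)
constituents; weights are normalised to sum to one.  Each constituent is
min-max rescaled to [0, 1] (reversed for direction −1) and the score is
the weighted mean, so scores live in [0, 1] and are invariant to positive
affine rescaling of any constituent.  The default definitions are Q1 =
tensile index alone and Q5 = sedimentation aspect ratio + water retention
value, equally weighted (the internal weighting of Q5 is a package choice;
alternatives are expressible through the config).

The selection gradient β_n is the OLS slope of the quality score on metric
n.  Traits are z-standardised before fitting by default so gradients of
incommensurable metrics share one axis; raw-unit slopes and mean-relative
fitness are available behind flags because the choice among them is
genuinely open.  G defaults to the correlation matrix of the metrics
(matching standardised gradients); the raw covariance is a flag away.
The predicted response is the matrix product Δz̄ = Gβ, checked in the
tests against an element-wise double-loop expansion to 1e-10 and against
the diagonal-G closed form Δz̄_n = V_n β_n.  No multi-generation
iteration is offered: a materials pipeline is not an evolving population,
so a single response step is the meaningful quantity.

## Synthetic data: what it does and does not emulate

The generator draws every random effect as an independent Gaussian — the
assumption the estimators make — with defaults fixed at the study
conditions: the 4×3×3×2×8 design, the published tensile-index components
as generating truth, and a grand mean of 60 N·m/g (a typical CNF nanopaper
tensile index; the source table does not print one).  Metric matrices are
multivariate normal; `planted_block_metrics` embeds an equicorrelated
block structure (used with within-block r = 0.85–0.9 and n ≥ 200, where
recovery is exact) whose default blocks mirror the qualitative metric
families: fine-content, fibre-length, and coarseness/content parameters.
The illustrative morphology defaults span genetic shares of 5–55% so
rankings on simulated data are non-trivial.

Passing tests on these fixtures show the estimators and pipelines are
correct *under the model's own assumptions*.  Real fibre-morphology data
are skewed, bounded and heteroscedastic, and real metric correlations are
not block-constant; none of that is emulated, so the tests say nothing
about robustness to distributional misspecification.

## Problem sizes and determinism

Monte-Carlo checks use 200 replicates of the full 576-observation design
for EMS recovery (the solver's projections are built once and reused, so
a replicate costs a few quadratic forms), 100 datasets × 100 bootstrap
refits for interval coverage, and n = 500 samples for cluster recovery.
All randomness flows through explicit integer seeds (`numpy`'s
`default_rng`); child seeds are spawned below 2³¹.  Every command of the
CLI is deterministic given its config and seed.
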