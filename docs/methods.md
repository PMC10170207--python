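# Methods

This note documents the models, rules and numerical choices implemented in
`gencontrib`, in the package's own terms.

## Expected genetic contributions

Under Mendelian expectation each parent transmits half of an offspring's
alleles.  The expected contribution of a focal individual to a descendant
is therefore the numerator-relationship (additive relatedness) coefficient
between them, computed **with the focal's parents severed** so that only
direct descent counts — contributions through shared kin ancestry are
excluded by construction.  Two routes are implemented:

* `expected_contribution_vector` — propagation over the focal's descendant
  subgraph in topological order: c(focal)=1 and
  c(d) = ½·c(sire(d)) + ½·c(dam(d)), non-descendant parents contributing
  zero.  O(descendants) per focal; used everywhere.
* `relationship_matrix` — the classical tabular method, dense O(n²);
  feasible to a few thousand individuals and used as the independent
  cross-check (the two agree to 1e-12 on random pedigrees; enforced in the
  test suite).

The gene-dropping simulator (`gene_drop`) realizes the same quantity by
Mendelian sampling of two distinguishable focal alleles down the pedigree;
its Monte-Carlo mean converges to the expectation (checked at 10⁴
replicates against 3 Monte-Carlo standard errors).

An IGC series divides the summed coefficients of everyone present in a
parish-year (the focal itself included while alive and present) by the
pool size, from the focal's birth year (arrival year for immigrants) to
the final year (default 1990).  Years with an empty pool are recorded as
missing.  A difference-array implementation
(`igc_series_from_intervals`) exploits the fact that presence is one
contiguous interval per individual; it is exactly equal to the set-based
route and is what the pipeline uses.

## Presence and migration

Individuals born and married in the same study parish are residents; born
outside but married in a parish, immigrants (arriving at marriage); born
in a parish but married outside, emigrants (leaving at marriage); born in
one study parish and married in the other, inter-parish movers (the
transition year belongs to the destination parish).  Unmarried
locally-born individuals are residents; individuals without usable place
data are unclassifiable and never enter a gene pool.  These are
operational readings of marriage-register semantics; the transition-year
convention is configurable.  Individuals with a missing death year remain
present until their last recorded event (own marriage, last offspring
birth) plus a configurable censoring horizon (default 0), then drop out.
Year intervals are closed; the pool of year *y* is evaluated at year end.

## Stabilization

Focal individuals are grouped into parish-specific 10-year birth cohorts
(≥ 2 members; smaller cohorts are excluded).  For each year *y* the
Pearson correlation across cohort members between IGC(*y*) and final-year
IGC is computed.  A cohort is **stabilized** when r ≥ 0.95 for every year
in the closed window [final − ⌈2·G⌉, final], where G is the generation
time (mean parental age at offspring birth, pooled over sexes, per
parish); the ceiling gives a reproducible integer window.  Undefined
correlations (zero cross-sectional variance) fail the check, with one
deliberate refinement: a cohort whose members are **all extinct** (IGC
identically zero across the window and at the final year) is classified
stabilized, because extinct lineages cannot recover — without this rule a
fully-extinct founding cohort would block every later cutoff.  The
per-parish cutoff is the first birth year after the latest decade such
that it and all earlier analysable decades stabilized; individuals born
before the cutoff form the stabilized focal set for the regression
models.  The cutoff is always recomputed, never hard-coded.

## Fitness proxies and eligibility

* lifespan = death year − birth year;
* LRS = offspring ever born;
* LRS_SA = offspring whose lifespan reaches the sex-specific 5th
  percentile of age at first reproduction over the whole dataset
  (linear-interpolation "type 7" percentile by default, configurable;
  offspring of unknown sex use the pooled percentile);
* grandoffspring = total offspring of the focal's offspring — all born,
  not only surviving — defined only when every offspring has a complete
  life history (known birth and death years), and 0 for non-reproducers.

Rows are flagged rather than dropped: `eligible_core` (IGC present, own
birth and death known), `eligible_grand` (offspring complete),
`eligible_model` (additionally known sex — informative for every model
predictor).  Lineage-fate accounting classifies each focal's descendants
as reproduced-in-population, alive-unreproduced at the final year, or
failed (died or emigrated without local reproduction), and reports the
emigration share of failures.  Extinction-stage tallies (died before
adulthood / no offspring / no adult-surviving offspring / no
grandoffspring / later) are reported both conditional on extinction and
over all focals, because the stage denominators are a genuine reporting
choice.

## Hierarchical zero-inflated beta regression

IGC of stabilized individuals is zero for extinct lineages and a small
positive proportion otherwise, hence the mixture likelihood

y = 0 with probability π,  y ~ Beta(μφ, (1−μ)φ) with probability 1−π,

with logit(π) and logit(μ) each linear in the proxy (raw scale), parish
and sex (optionally a sex×parish interaction), identical structure in
both parts, and φ intercept-only on a log link.  Each part carries a
random intercept and a random proxy slope per parish-specific 10-year
birth cohort, non-centered.  The random intercept and slope are
independent by default; a correlated bivariate option exists
(`correlated_random_effects=True`) but the correlation is weakly
identified with tens of cohorts and slows mixing, so independence is the
default.  The bias test is the same machinery without the zero part:
mean offspring IGC (offset by 1e-10 so the response is strictly positive)
regressed on LRS with the parent's lifespan as a covariate.

Priors: Normal(0, 100) on fixed effects (effectively flat), half-Student-t
(3, 2.5) on random-effect standard deviations, Normal(0, 4) on log φ,
uniform on the correlation when enabled.

Sampling is Hamiltonian Monte Carlo written in-package: analytic
gradients of the full posterior (finite-difference-verified in the test
suite), dual-averaging step-size adaptation, a diagonal mass matrix
estimated from a mid-warmup window (initialized from a per-block Fisher
heuristic so covariates spanning decades of years start with suitably
small steps, and shrunk toward that initialization Stan-style), and a
trajectory length jittered uniformly up to `max_leapfrog` (40).  Four
independent chains by default; R-hat, bulk ESS and Monte-Carlo s.e. are
computed across chains with arviz, and any R-hat > 1.05 logs a
convergence warning while still returning the fit with its diagnostics.
The full profile (4 chains × 2000 warmup + 4000 sampling, thinned by 10)
mirrors the production schedule; the fast profile (4 chains × 550 warmup
+ 350 sampling, unthinned, target acceptance 0.9) is used by the tests
and the acceptance script — the warmup length was set by checking that
credible intervals match converged long runs.  Simulation-based calibration at the fast profile
gives ~96% empirical coverage of the 95% credible intervals for fixed
effects at n = 2000.

The interaction-pruning rule fits the sex×parish interaction first and
drops it unless its pd reaches 0.975 in at least one model part; a
single-parish dataset makes the term inestimable and raises an error
naming it.  A pipeline-level `interaction_policy: never` switch skips the
pruning fits entirely for scaled-down runs.

### Derived quantities

* **Bayesian R²** per posterior draw: Var over observations of the
  model-implied mean (1−π)·μ divided by that variance plus the mean
  model-implied residual variance.  The default residual variance is the
  analytic zero/beta mixture variance; a draws-based alternative
  (empirical variance of simulated residuals, `method="draws"`) is
  exposed because the construction for zero-inflated responses is a
  genuine reporting choice — the two agree closely in practice.
* **ΔR²** between two models on the same observations: paired posterior
  draws, 95% percentile interval, and a kernel-density mode
  (Gaussian KDE, Silverman-type bandwidth) as the point summary;
  significant when the interval excludes 0.
* **pd** (probability of direction): share of draws sharing the sign of
  the posterior median; 0.95–0.975 trend, 0.975–0.99 significant, > 0.99
  highly significant.  Undefined (and raised) for a zero point mass.

## Synthetic study population

`simulate_population` is an individual-based yearly simulation of a
two-parish pre-industrial population and defines the package's study
conditions.  Defaults: two parishes with founding (and carrying-capacity)
sizes 380 and 240 over 1600–1990; infant mortality 0.13 applied at birth,
then annual hazards 0.04 (ages 1–4), 0.006 (5–14), 0.009 (15–49) and a
Gompertz tail 0.012·e^{0.085(age−50)}; marriage age ~ Normal(24, 4)
truncated at 19; marital fertility 0.32 per year damped by
min(1.25, (K/N)^3) crowding and by a logistic fecundity decline centred
at female age 33; remarriage after widowhood; per marrying local, 0.40
probability of marrying outside and leaving (emigrant), 0.002 of marrying
into the other parish, and a 0.30 chance that a local marriage recruits
an immigrant spouse (damped by crowding), who enters as a pedigree
founder.  After the final year, mortality-only years run until every
lifetime closes so death years are complete.  Under these defaults the
population reproduces the intended register profile: ~74% survival to age
5, median offspring among reproducers 3 (range up to ~17), generation
time ~34 years, and migration-class proportions of roughly 63–67%
residents, 16–18% immigrants, 16–20% emigrants and ~0.1–0.2% inter-parish
movers per parish.

What the generator does **not** emulate: socio-economic structure,
household formation, record-linkage error, illegitimacy, within-year
event timing, heritable variation in fitness, and multi-locus genetics
(gene dropping is single-locus).  Passing tests therefore demonstrate the
correctness of the estimators and the qualitative behaviour of the method
under realistic demography, not the numerical values any particular real
population would give.

`simulate_regression_data` draws covariates (Poisson(4) proxy by default,
count-like as offspring numbers; parish/sex Bernoulli(½); uniformly
assigned parish-specific decade cohorts) and the response from the exact
model likelihood with supplied ground truth — the basis of the
parameter-recovery, null-slope and R² calibration tests.

## Problem sizes and degenerate inputs

The shipped analyses run on desk scale by design: the default synthetic
population has a few hundred individuals alive per parish (≈ 6–7k records
over four centuries), stabilization scans walk decades in order and stop
at the first non-stabilized cohort, and test fits use the fast HMC
profile; the acceptance script skips the interaction-pruning refits.  In
small gene pools lineage extinction is stronger than in populations of a
few thousand (drift), so the synthetic extinction fraction (~80%) sits
above what larger registers show; the R² ordering of the proxies is the
robust, reproducible quantity.  Degenerate inputs are handled explicitly:
empty pedigrees give all-zero summaries; unclassifiable individuals never
enter pools; empty pool years are missing, not zero; cohorts of one are
excluded; a non-positive response, an unestimable interaction, too few
reproducers for a percentile, and φ ≤ 0 in the generator all raise typed
errors naming the problem.
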