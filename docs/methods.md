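# Methods

## Model

The Random Lab Model treats a phenotype measured for genotype g in lab l as

    y_gli = mu + beta_g + L_l + (GL)_gl + e_gli,

with genotype effects fixed and lab effects, genotype-by-lab interactions
and residuals independent Gaussians with variances sigma2_lab, sigma2_gxl
and sigma2_within.  Everything downstream follows from two consequences:
(i) in a single lab the two interaction terms of a genotype comparison are
indistinguishable from the genotype difference itself, inflating the naive
t-test; (ii) the ratio gamma = sigma_gxl/sigma_within is dimensionless and
can therefore be carried from a multi-lab database into a new lab measuring
on a different scale, where multiplying back by the lab's own pooled SD
reconstructs the locally relevant interaction SD.

With a treatment arm, treatment and treatment-by-genotype are additional
*fixed* effects (the treatment-by-genotype contrast is the estimand, so no
variance component is attached to it), while every lab-involving interaction
(TxL, GxL, TxGxL) is random.  In the four-group difference of treatment
effects between two genotypes, TxL and GxL cancel and four independent
TxGxL terms remain, giving the 4*gamma_txgxl^2 inflation.

Analyses are run per phenotype and per subpopulation stratum (sex x
treatment arm); strata are never pooled by default, matching how the
reference multi-lab design was analysed.  Phenotypes with strongly
non-Gaussian raw scales are transformed first (logit of a percentage for
centre time and immobility time, cube root for grip strength, optionally
log for strictly positive measures such as body weight, which defaults to
the identity scale); transforms are strictly monotone and applied once,
before any variance estimation.  The logit transform clips proportions to
[epsilon, 1-epsilon] with epsilon = 1e-3 because percentages of exactly 0
or 100 occur in practice; the boundary handling only matters for extreme
observations and is configurable.

## Variance-component estimation

`fit_random_lab_model` / `fit_treatment_model` estimate the components by
REML.  Because every random effect is constant within a
(genotype, lab[, treatment]) cell, the restricted likelihood depends on the
data only through the cell means and the pooled within-cell sum of squares;
the implementation evaluates it exactly on that reduction (tens of cells
instead of hundreds of animals), profiles out the residual variance, and
optimises the variance *ratios* with L-BFGS-B under a nonnegativity bound
using the analytic gradient.  Numerical choices:

- Ratios are started at the balanced-ANOVA moment estimates when available,
  else at 0.1; the bound at zero implements the standard truncation of
  negative variance estimates, and truncated components are flagged on the
  result (`truncated`).
- Data are prescaled by a power-of-two magnitude so that a pure change of
  measurement units leaves the optimisation numerically identical; gamma is
  scale-free to ~1e-10.
- Convergence: gradient norm 1e-10, ftol 1e-14; a one-animal-per-cell
  design leaves no residual df and is rejected as non-identifiable, as are
  designs with fewer than two labs or genotypes.

The balanced-design expected-mean-squares (ANOVA) estimator is kept as a
second, independent implementation (`moments_two_way`, `moments_three_way`,
unrestricted mixed-model convention).  On balanced data in the interior of
the parameter space it coincides with REML to optimiser tolerance, which the
test suite exploits; it refuses unbalanced designs.  One test additionally
cross-checks the REML components against lme4 via Rscript on a simulated
dataset.

## The adjusted test

`adjusted_t_test` computes T = (xbar - ybar) / (s_p sqrt(1/n1 + 1/n2 +
2 gamma^2)) with gamma treated as a known plug-in constant; its estimation
uncertainty enters only through the Satterthwaite degrees of freedom

    nu = (1/n1 + 1/n2 + 2 g^2)^2 /
         [ (1/n1+1/n2)^2/(n1+n2-2) + 4 g^4/((nL-1)(nS-1)) ],

where nL, nS are the labs and genotypes behind the gamma estimate.  At
gamma = 0 the statistic, df, p and CI reduce exactly to the classical pooled
t-test, and since the SE can only grow with gamma, an unadjusted
nonsignificant result can never become significant after adjustment.  Note
that nu can slightly *exceed* n1+n2-2 for small gamma (Satterthwaite
combinations are bounded by the sum of the component dfs, not by either
one); this is a property of the formula, not an implementation artefact.

The four-group treatment contrast uses the analogous formula with the
4 gamma^2 inflation, 16 gamma^4 in the interaction term and pooled error df
n1T+n1C+n2T+n2C-4.  The exact df recipe for this contrast is a
generalisation we chose (the natural extension of the two-group formula);
it is isolated in `satterthwaite_df_contrast` so sensitivity checks can
swap it out.

## Replicability calls and categories

A genotype difference is *replicable* when it is significant in the
multi-lab analysis under the Random Lab Model.  `replicability_calls` tests
the difference of across-lab genotype means against

    se^2 = sigma2 (1/N1 + 1/N2) + 2 sigma2_gxl / n_labs

with REML plug-ins.  For the df, the variance is re-expressed as a weighted
sum of the *independent* error and interaction mean squares before applying
Satterthwaite: the two component estimates themselves are negatively
correlated (both involve the interaction mean square), and pairing them
naively overstates the df and makes the call anticonservative (simulated
null call rate 0.074 instead of 0.05).  On balanced data the error weight
vanishes and the df reduce to the exact classical (nL-1)(nS-1); the
simulated null rate is then 0.056 at gamma = 0.5.  Per-pair calls are made
at alpha = 0.05 with no multiplicity adjustment by default; a Tukey-style
studentized-range family p-value is available via `multiplicity="tukey"`.

Each comparison's triple (replicable, single-lab significant, adjusted
significant) maps to categories A-F; the combination (single-lab ns,
adjusted significant) is impossible by monotonicity and raises an integrity
error.  `summarize` reports the type-I replicability error (D+E)/(D+E+F)
and D/(D+E+F) and the power (A+B)/(A+B+C) and A/(A+B+C) with Clopper-Pearson
exact 95% binomial intervals (computed as if decisions were independent,
which they are not exactly — the intervals are approximate in that sense).
Display rounding is round-half-up, percentages to one decimal and interval
endpoints to integers.  No non-replicability-rate (FDR-style) summary is
offered: that ratio depends on the powers of the particular studies pooled
and does not transfer to future experiments.

## Power and sample size

`power_of_design` evaluates the two-sided adjusted test exactly via the
noncentral t with noncentrality effect/(sigma sqrt(2/n + 2 gamma^2)) and
Satterthwaite df (a Gaussian limit replaces the noncentral t where scipy's
implementation underflows at very large df).  As n grows the SE floors at
sigma sqrt(2) gamma and the df tend to (nL-1)(nS-1), so power is capped at
`power_limit`; targets above the cap are reported as unattainable rather
than answered with a sample size.  `required_n` follows the iterative
plug-in scheme — solve the classical problem at sigma, inflate to
sigma_1 = sigma sqrt(1 + n gamma^2) (so that sigma_1^2 * 2/n reproduces the
model variance), re-solve, iterate to a fixed point (a 2-cycle returns the
larger point, flagged) — then polishes the result against the exact
adjusted power so that n is the smallest integer meeting the target.  The
inflation is sometimes written sigma_1 = sqrt(sigma^2 + n gamma^2); that
form is dimensionally inconsistent (gamma is unitless), and we default to
the consistent reading, keeping the literal one behind `literal_sigma=True`
(in that mode the raw fixed point is returned unpolished).  Equal group
sizes are assumed.

## The simulator

`simulate_multilab` draws fully crossed balanced designs from the model
exactly as written above, by default 3 labs x 6 genotypes x 10 animals per
group with sigma_within = sigma_lab = 1 and sigma_gxl = 0.5 on the analysis
scale — sample sizes and gamma in the 0.3-1.0 range typical of rodent
behavioural and physiological phenotypes, with lab shifts of the same order
as the animal-to-animal noise.  A single root seed spawns independent
substreams per random component, so outputs are reproducible and enlarging
one SD does not reshuffle the other draws.  `simulate_single_lab` returns
one lab's slice of the same realisation, so a test harness knows each
difference's across-lab truth; `drop_out` deletes animals at random to
create unbalanced designs.  If an analysis-scale transform is configured,
its inverse is applied so the delivered table is on the native scale and
the model is exactly additive after re-transformation.

What the generator does not emulate: non-Gaussian or heavy-tailed residuals,
lab-specific variances, protocol-driven systematic differences (apparatus,
session length), litter or cage structure, and selection effects among
reported comparisons.  Passing calibration tests therefore show that the
machinery is correct *under the model*, not that real phenotypes satisfy it.

## Problem sizes used in validation

Monte-Carlo checks run at the reference design (3 x 6 x 10).  The
acceptance simulations use 2,000 replicates per gamma; some unit tests use
200-1,500 replicates per property, sizes at which the asserted tolerances
(e.g. |median gamma-hat - gamma| < 0.15, rejection rates within +-0.02)
hold with comfortable margins.

## Known limitations

- gamma is a plug-in: no uncertainty interval is propagated beyond the
  Satterthwaite df term (no bootstrap/Bayes option).
- The moments estimator is balanced-only by design; REML handles unbalance
  but extreme sparsity (empty cells) is rejected rather than modelled.
- Multiplicity across many comparisons is deliberately out of scope except
  for the Tukey-style option on multi-lab pairwise calls.
- Published category counts consumed by the acceptance script are fixtures;
  the animal-level data behind them are not redistributable here, so the
  corresponding pipeline behaviour is validated by simulation instead.
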