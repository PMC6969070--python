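# Methods

## Model overview

One *community replication* proceeds in three stages:

1. **Landscape.** A 10×10 grid of ground truths is drawn fresh. In
   discovery mode each cell is 1 independently with P(H1) = .09. In
   theory-testing mode a 4×4 true-effect window is placed uniformly over
   the 7×7 feasible anchor positions, the effect count is drawn
   Binomial(100, P(H1)) — preserving the discovery-mode marginal — and
   that many distinct cells are set inside the window. The theory's
   predicted 4×4 window sits (1 − ρ) × 9 rows and columns away from the
   true window (offset rounded half-away-from-zero, direction random per
   dimension among feasible ones, anchor clipped into the grid).
2. **First round.** 100 experiments target cells sampled with replacement
   (uniform over the grid in discovery mode, uniform over the predicted
   window in theory mode). Each draws n observations from N(truth, σ) and
   is classified significant/inconclusive (frequentist) or
   effect/null/inconclusive (Bayesian).
3. **Regime.** *Notable* findings (significant effects; plus convincing
   nulls under the symmetric Bayesian option) are replicated before
   publication (private) or published and replicated only if an
   independent citation-based interest draw comes up positive (public).
   A replication succeeds when it reaches the same evidence category as
   the original; knowledge is counted when a successful, interesting
   replication also matches the ground truth.

Each condition repeats this 1000 times on independent RNG substreams and
reports per-metric means, SDs, and Monte-Carlo standard errors
(SE = SD/√1000).

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| P(H1) | .09 | prevalence of true effects on the grid |
| σ (frequentist) | 2.0 | population SD; with μ = 1, d = 0.5 |
| n | 34 / 18 | smallest n with two-tailed power ≥ .8 / ≥ .5 at d = .5, α = .05 |
| α | .05 | two-tailed significance level (.2 under p-hacking) |
| σ (Bayesian) | 1.5 | gives a BF₁₀ > 3 hit rate ≈ .88 on true effects at n = 34 |
| r | 1.0 | JZS Cauchy prior scale |
| BF threshold | 3 | evidence criterion for both BF₁₀ and BF₀₁ |
| k, σ_gpd, θ | 0.115, 8.71, 0 | generalized Pareto citation fit |
| threshold percentile | .90 | interest midpoint q = 22.9616 citations (sweepable .10–.90) |
| temperature t | 1, 5, 10 | gradedness of the logistic interest rule |
| ρ | 0.1, 0.5, 1.0 | theory quality (window overlap) |

The Cauchy scale r is a genuine modelling choice: it is not pinned by the
scenario constants, and the Bayesian hit rate on true effects moves with
it (0.883 at r = 1; smaller r gives higher rates). We fix r = 1, the
historical default for one-sample JZS tests, and treat the hit rate as a
derived quantity rather than a calibration target.

## Numerical choices

* **Bayes factor.** The JZS marginal likelihood ratio is integrated over
  the mixing variable g ∈ (0, ∞) by adaptive quadrature (relative
  tolerance 1e−8), dividing by the null likelihood *inside* the integrand
  so large |t| cannot underflow. Non-convergence raises; zero-variance
  samples are an error, not BF = ∞.
* **Fast path.** Within a simulation the Bayesian decision reduces to two
  |t| cutoffs (BF = 3 and BF = 1/3) found by root search on the exact
  quadrature; recorded BF values come from a cubic spline of
  log BF₁₀(|t|) on [0, 100] (801 knots), which the test suite verifies
  against the quadrature to better than 1e−6 relative. This changes
  nothing statistically — it only removes per-study quadrature calls.
* **Power.** Exact two-tailed noncentral-t power; the sample-size solver
  bisects for the smallest n meeting the target and is checked for
  minimality (power at n − 1 falls short).
* **Logistic rule.** The exponent is clamped at ±700 to avoid overflow;
  citation draws are continuous (the fitted distribution is sampled
  directly via the inverse CDF and the logistic rule is continuous, so
  rounding to integer counts would change nothing material).
* **Rounding.** The window offset uses half-away-from-zero rounding
  ((1 − 0.5) × 9 = 4.5 → 5), the convention of the platform the model was
  originally developed on.
* **Reproducibility.** A condition seed spawns one `SeedSequence` child
  per community replication, so any single replication can be re-run in
  isolation (`replication_rng`); all writers record the seed and a config
  hash.

## Design choices where the design was open

* **Theory-mode effect count.** Only "clustered" is specified, not how
  many; drawing Binomial(100, P(H1)) capped at the window capacity of 16
  keeps both search modes on the same marginal prevalence, which keeps
  cost comparisons between modes interpretable. Draws above 16 (≈ 0.7% of
  draws) are capped and logged.
* **Offset direction.** Only the offset magnitude and the fit constraint
  are specified; we pick the sign uniformly per dimension among directions
  in which any displacement is feasible, then clip. With ρ = 0.1 the
  predicted window always lands on a grid edge.
* **Interest timing.** Each finding gets exactly one citation draw, made
  when it first becomes a candidate for community attention (at
  publication). Re-drawing at later decision points would be
  distributionally identical because draws are iid.
* **Replication design.** Replications reuse the original cell, n, σ, and
  test; there is exactly one replication attempt per finding. No
  same-direction requirement is imposed for replication success — only
  the evidence category must match — which makes the double
  false-positive rate per null cell α² = .0025 rather than α²/2.
* **Dishonesty boundaries.** The p-hacked α applies to first-round tests
  and to private-regime replications (same investigator); public-community
  replications always use the nominal α and never use optional stopping.
  Optional stopping defaults to first-round studies only (configurable).
  Fraud (all first-round results declared significant) is only meaningful
  under the public regime and is rejected otherwise.
* **Counting.** Discoveries are counted per study event, not per unique
  cell, so the discovery count can exceed the number of true phenomena.
  Cost is measured in experiments; participants are tracked separately so
  optional stopping's extra participants are visible without changing the
  cost metric.

## What the simulations do and do not establish

The generator *is* the model: there is no external data, so a green test
establishes internal consistency of the stated world — e.g. that the
private regime's extra cost (~10 experiments per 100 in discovery mode,
~40% relative in theory mode at ρ = 1, ≥50% with symmetric Bayesian
notability) follows from the stated prevalence, power, citation
distribution, and decision rules. Real scientific communities differ in
ways the model deliberately ignores: citation dynamics over time,
correlated effect landscapes beyond a single cluster, heterogeneous study
designs, multi-round replication chains, and strategic behavior beyond
the four stylized perturbations. The editorial-workload figure
(11.75 publications × 1.6 reviews × 5 h × 2 = 188 h) is arithmetic on
survey-based constants, not a simulation output.

## Known limitations

* The Bayesian "power" depends on the unpinned prior scale r; results are
  reported at r = 1 and the acceptance band for the hit rate is wide
  ([0.70, 0.90]) for that reason.
* Theory-mode landscapes cap the effect count at the window capacity,
  truncating ~0.7% of the Binomial upper tail (mean effect count shifts by
  < 0.01).
* Matched-seed regime comparisons share the landscape and first round
  exactly (the RNG streams diverge only at the regime stage), which
  removes most but not all comparison noise; the regime-difference
  tolerances in the tests account for the remainder.
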