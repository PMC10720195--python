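# Methods

## Survival model

Each retention category (`alt_func`, `dos`, `non`) has a per-pair loss
hazard h(t) = d + f·exp(−b·t^c) with time in units of the plotted
duplication ages (the working domain is t ∈ (0, 0.5], with validation out
to t = 2).  `d + f` is the loss rate of a fully redundant pair at t = 0;
the excess rate relaxes to the background rate `d` with shape (b, c).
The shipped profile `konrad2011_adjusted` carries

| category | b | c | d | f | behavior |
|---|---|---|---|---|---|
| alt_func | 10.0 | 2.37 | 0.00054 | 5.84 | loss decelerates; near-plateau on the plotted range |
| dos | −17.0 | 0.2573 | −0.000028 | 0.000028 | loss accelerates; survival → 0 |
| non | 0 | 1 | 20 | 5 | constant hazard 25; fast exponential decay |

Note the alt_func plateau is an approximation over the plotted range: with
d > 0 the curve still tends to 0 as t → ∞.  The implementation follows the
formula, not the verbal plateau description.  The dos set has d < 0 with
d + f = 0 exactly; parameter validation therefore checks nonnegativity of
the *total* hazard numerically on (0, t_check], t_check = 2 by default
(covering every computation the package performs, not just the plotted
half-unit).

Survival comes from term-wise integration of the hazard:
S(t) = exp(−d·t − f·Σₙ (−b)ⁿ t^(cn+1)/(n!(cn+1))), truncated at
`n_max = 100`.  Numerical choices:

* terms via the recurrence term₀ = t,
  termₙ₊₁ = termₙ·(−b)t^c·(cn+1)/((n+1)(c(n+1)+1)) — no explicit factorials
  or powers, so no spurious overflow at n = 100 with |b|·t^c ≈ 14;
* Kahan-compensated summation (the b > 0 series alternates);
* early termination when |termₙ| ≤ rel_tol·|partial sum| (default 1e−12)
  on two *consecutive* terms, because a single term of an alternating
  series can be accidentally small;
* if the cap is reached while the next term still exceeds
  fail_tol·|sum| (default 1e−8), the evaluation raises a named
  convergence error rather than returning a silently truncated value.
  With the printed alt_func parameters this genuinely happens for
  t ≳ 1.6 (|b|·t^c ≳ 30): the alternating series needs more than 100
  terms there, and in float64 the cancellation would dominate anyway.
  Every computation the package performs needs the alt_func curve only on
  (0, 0.5], where the series is fully converged and accurate to ~1e−14
  against adaptive quadrature of the hazard integral;
* exponent underflow (< −745) returns 0.0 with a debug log line — the
  mathematical limit — while survival values that stray above 1 by more
  than 1e−9 raise instead of being clamped.

## The probability ratio

p_ratio = P(pair survives t2 | parent survived t1) / P(… | parent lost in
t1).  Both conditionals are normalized mixture averages:

* numerator: Σ αᵢ Sᵢ(t1) S̃ᵢ(t2) / Σ αᵢ Sᵢ(t1),
* denominator: Σ αᵢ (1−Sᵢ(t1)) Sᵢ(t2) / Σ αᵢ (1−Sᵢ(t1)),

with S̃ = S except that under mutational opportunity
S̃_alt(t2) = (1−β)·S_alt(t2) + β·S_non(t2).  The switch applies only to the
survived-t1 branch: only a gene *retained* through alternative
functionalization can lose the opportunity to functionalize again.  A
t1 survivor contributes two pairs at the second WGD; that factor of two
multiplies numerator and denominator of the normalized conditional alike
and cancels, so the closed forms omit it — the simulator and the
likelihood honor it in their pair accounting instead.  With β = 0 the
mutational-opportunity expressions are the gene-duplicability ones through
the same code path, so the nesting is bitwise.

t1 = 0 is outside the statistic's domain (the lost-in-t1 conditioning
event is empty); t2 = 0 is rejected for the ratio as a design choice even
though the limit is finite (it is 1 for every composition).  Under the
independence hypothesis a mixed composition argument is collapsed to its
dominant category — the ratio is 1 regardless of which.

## Surfaces

The default grid is 0.01–0.50 inclusive in steps of 0.01 on both axes
(50 × 50): time points "to the hundredths" with the undefined origin
excluded.  Grid values are rounded to 10 decimals so exported headers read
0.3, not 0.30000000000000004.  Exports are TSV with `repr` precision
(bitwise round trip) plus a JSON sidecar carrying composition, hypothesis,
hazard parameters, grid and package version; re-evaluating from the
sidecar reproduces the surface bitwise.  The summary reports max/min with
their grid locations (ties break toward the smallest t1, then t2) and the
fraction of points below 1; a point counts as below 1 only beyond a 1e−12
guard, since an analytically flat independence surface shows ±1 ulp of
float noise.

## Simulator

Fates are Bernoulli draws from the closed-form survival probabilities —
not hazard-process trajectories, and no continuous-time event sampling.
Per gene: category ~ Multinomial(α); the WGD1 pair survives t1 with
S_cat(t1); a survivor contributes two independent WGD2 pairs, each
surviving with S̃_cat(t2); a loser contributes the single pair of its
surviving copy, with S_cat(t2).  The mutational-opportunity switch is
drawn once per gene (the switch models the gene's realized functional
history), applied to both its pairs; the closed forms are identical either
way because pairs are conditionally independent given the category.
Randomness comes from one seeded numpy PCG64 generator consumed in a fixed
stage order (categories, t1 survival, switch, t2 survival), so identical
configs give identical counts across machines.

The empirical ratio is [n11/(n11+n10)] / [n01/(n01+n00)] with a
delta-method standard error treating the two conditional fractions as
independent binomial proportions.  The variance estimate uses
continuity-adjusted proportions (x+½)/(n+1) because the plug-in variance
is degenerate when a sampled proportion sits on the boundary — routine
when one conditioning class is small (e.g. a pure-dos genome at short t1
has only a few hundred t1 losers).  The point estimate is unadjusted.
The SE ignores the within-gene correlation of a survivor's two pairs in a
mixed genome, consistent with its definition; observed z-scores against
the closed form stay within ±4 at the panel sizes used.

What the simulator emulates — and does not: it generates sorting purely
from category heterogeneity and the β switch.  Real paralog data add
ortholog-identification error, lineage-specific rate variation,
small-scale duplications mixed in with ohnologs, and the four-redundant-
copy state when t1 is short enough that pairs have not resolved before the
second WGD (deliberately not modeled here).  Passing tests therefore
validate the mathematics and the estimator plumbing, not the fit of the
model to any real genome.

## Inference

The pair-outcome cells have unnormalized masses m11 = Σ αᵢ·2Sᵢ(t1)S̃ᵢ(t2),
m10 = Σ αᵢ·2Sᵢ(t1)(1−S̃ᵢ(t2)), m01 = Σ αᵢ(1−Sᵢ(t1))Sᵢ(t2),
m00 = Σ αᵢ(1−Sᵢ(t1))(1−Sᵢ(t2)), normalized by Σ αᵢ(1+Sᵢ(t1)) — exactly the
simulator's accounting (two pairs per t1 survivor, one per loser).  The
sampling unit is the pair, and the likelihood is multinomial over the four
cells; the mild within-gene clustering of a survivor's two pairs is
ignored by the likelihood, which costs a little calibration of standard
errors but not consistency of the point estimate.

The α simplex is handled by an additive log-ratio reparameterization
(softmax over two free coordinates), β by a logit when jointly fitted;
optimization is L-BFGS-B with 8 multi-start restarts from seeded Dirichlet
draws (the first start is the uniform composition) because mixture
likelihoods can be multimodal.  β is fixed at 0 (gene duplicability) by
default — the two mixture hypotheses are hard to distinguish except in
extreme regimes, so joint estimation is opt-in.  Counts from several
(t1, t2) designs can be combined by summing log-likelihoods when the
clades can be assumed to share α.  The fit reports the finite-difference
Hessian eigenvalues of the negative log-likelihood in the unconstrained
coordinates, so near-flat directions (alt_func vs dos at time points where
their survival products are similar) are visible rather than hidden.
Corner compositions are reachable only asymptotically under the softmax;
recovery tests accept ≥ 0.95 on the dominant component there.

## Problem sizes

Default surfaces are 50 × 50 (≈ 0.2 s); the Monte-Carlo oracle panel uses
200 000 genes per cell; recovery experiments use 10⁶-gene tables over 10
seeds.  These sizes put simulation standard errors well below the
tolerances being checked while keeping any single computation under a
minute on one CPU.

## Known limitations

* The alt_func series genuinely cannot be evaluated at t ≳ 1.6 with the
  printed truncation cap (and float64 cancellation would cap accuracy even
  with a larger one); the package raises rather than extrapolates.
* No estimation of b, c, d, f from data; the hazard parameterization is
  taken as fixed input.
* No unresolved-duplicate (four-copy) state at small t1, no
  neofunctionalization-after-subfunctionalization dynamics, no
  phylogenetic correction across clades, and no hypothesis-test machinery
  beyond reporting likelihoods.
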