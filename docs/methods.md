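# Methods

`vpalloc` models how visual-working-memory (VWM) resource is divided among
items of unequal behavioral relevance, in a memory-guided saccade task with
four targets carrying probe probabilities 0.6 ("high"), 0.3 ("medium"),
0.1 ("low") and 0.0.  This note documents the model, the estimation
machinery, the synthetic-data generator, and the design choices that were
genuinely open.

## The variable-precision observer

Memory quality is a continuous resource.  On each trial the probed item's
precision J — the inverse variance per axis of an isotropic 2-D Gaussian
report distribution, units dva⁻² — is itself random:

    J ~ Gamma(shape k = J̄/τ, scale τ),   E[J] = J̄.

Given J, the Euclidean estimation error ε = ‖report − target‖ is Rayleigh
with scale J^(−1/2):

    f(ε | J) = J ε exp(−J ε²/2).

The marginal error density integrates the Rayleigh against the gamma:

    p(ε | J̄, τ) = ∫ f(ε|J) Gamma(J; k, τ) dJ
                = ε k / (τᵏ (ε²/2 + 1/τ)^(k+1)).

The pipeline evaluates this integral numerically (mirroring the fitting
procedure's general marginalization machinery); the closed form serves as an
independent oracle in the test suite only.  Note that "precision" here is
per-axis inverse variance, so the per-axis report SD is J^(−1/2); other
conventions (e.g. Fisher information of a circular variable) differ by
constants.

Useful moments, used by the Minimizing-Error observer:

    E[ε^β] = 2^(β/2) Γ(1+β/2) τ^(−β/2) Γ(k−β/2) / Γ(k),   finite iff k > β/2.

The divergence at k ≤ β/2 is raised as an explicit `DivergentLossError`,
never returned as a silent infinity.

### Quadrature

The J-integral uses Gauss–Legendre nodes in log J.  The node range covers
the central 1 − 1e−10 of the gamma mass, *extended downward* to the
~1e−250 quantile: for large errors the integrand peaks far into the gamma's
left tail, and a mass-only range misses that peak.  The integrand is
analytic in log J, so the rule converges exponentially; 500 nodes give
≤ 1e−6 relative error against the closed form across the tested parameter
range (likelihood evaluation uses 150 nodes, plenty for optimization).
Excluded tail mass above 1e−4 triggers a warning unless it is the float
floor at J ≈ 1e−280 doing the truncating, where the density contribution is
bounded by J·ε and is negligible.

## Resource allocation strategies

Total resource J̄_total is split over the three probed conditions by a
simplex vector p; condition i gets mean precision J̄ᵢ = pᵢ·J̄_total.  The
0.0-probability quadrant is never probed and receives nothing.

* **Proportional**: p = t (the probe probabilities), no free allocation
  parameters.
* **Flexible**: p_high and p_med are free parameters; p_low is the
  remainder.
* **Minimizing Error (ME)**: p minimizes Σᵢ tᵢ E[ε^β | pᵢ J̄_total, τ].  β
  is the "sensitivity to error": large β punishes occasional huge errors,
  pushing the split flatter than proportional.  In the β = 2, τ → 0 limit
  the optimum is the √t rule, p ∝ √tᵢ — a closed form the tests check.
* **Maximizing Points (MP)**: p maximizes Σᵢ tᵢ E_J[max_r EU(r; J)], the
  expected wager points assuming the observer then picks the EU-optimal
  circle noiselessly (the decision-noise parameter shapes responses, not
  the planner).  At small budgets the MP optimum pushes the low-priority
  share to the simplex floor — the "ignore the low-priority item" signature
  that makes MP qualitatively distinguishable from ME.

Simplex optimization uses the two free coordinates with SLSQP from a
permutation-closed multistart set (uniform, powers of t, corner-leaning
points).  Proportions are floored at 1e−3 (configurable): a literal pᵢ = 0
makes the item's gamma degenerate at J = 0 and every likelihood involving
that condition improper, so "ignoring" an item means ≤ 0.1% of resource.
ME additionally bounds each pᵢ above β τ / (2 J̄_total) so the objective
stays finite; if those bounds are jointly infeasible the optimizer raises.
Flat optima (reachable only in symmetric degenerate cases) are tie-broken
toward the lexicographically smallest allocation.

Because max_r EU(r; J) depends on no fitted parameter, the MP planner reads
it from a cached dense log-J table; its expectation confines the quadrature
to J ∈ [1e−8, 1e8] (outside which the optimal value is flat at 0 or the
payoff ceiling) with explicit mass corrections for the excluded tails, which
keeps the objective accurate even when a floored allocation makes the gamma
shape minuscule.

## The post-decision wager

After the saccade, a circle centered on the endpoint is sized by the
observer; a hit (target inside) earns α·e^(−γr) points with α = 120,
γ = 0.4 dva⁻¹, a miss earns nothing.  The endpoint–target distance is
Rayleigh given J, so

    P(hit | r, J) = 1 − exp(−J r²/2),
    EU(r; J) = α e^(−γ r) (1 − e^(−J r²/2)).

The chosen radius is modeled on a discrete grid (0.1–10 dva in 0.05 steps,
configurable — the screen bounds responses and a finite set makes
normalization exact) with softmax mass P(r) ∝ exp(EU(r; J)/λ).  λ (points)
is the decision-noise temperature; the parameterization exp(EU/λ) is
equivalent to exp(β·EU) up to reparameterization.  The observer is assumed
to know the trial's J exactly when wagering (perfect metacognitive access);
metacognitive noise is out of scope.  The softmax acts on *expected*
utility, the product of utility and hit probability.

## Likelihoods and fitting

Per participant and model, parameters are estimated by maximum likelihood
with the latent J marginalized numerically.

* Estimation-only experiment: per-trial likelihood is the marginal error
  density at the trial's condition.
* Wager experiment (joint fit): per-trial likelihood is
  ∫ f(ε|J) P(r|J, λ) Gamma(J; k_c, τ) dJ — error and radius share the
  trial's J, which is exactly what produces the within-priority
  error–radius correlation.  Observed radii are snapped to the nearest grid
  node (warning if off by more than 1e−6; the 0.05-dva step keeps
  discretization error below fit noise).

Free parameters (bounds, all configurable): J̄_total ∈ [0.5, 500] dva⁻²,
τ ∈ [0.1, 200] dva⁻², allocation proportions ∈ [0.01, 0.97], β ∈ [0.01, 5],
λ ∈ [0.01, 100] points.  Parameter counts: estimation experiment 2/4/3
(Proportional/Flexible/ME); wager experiment 3/5/4/3 (+MP).

Optimization is bounded Nelder–Mead, restarted from multiple starting
points: a few *method-of-moments* starts computed from the data
(per-condition Rayleigh-median precision estimates seed J̄_total; two τ
regimes and, for the wager experiment, two λ regimes) followed by
Latin-hypercube draws, log-scaled for J̄_total, τ and λ.  The informed
starts matter: with purely random starts at desk-scale restart counts the
ME and MP models reliably find a β → 0 local basin.  The reference protocol
used 50 restarts per participant/model; the default here is 10 (restart
count is a parameter, so full-fidelity runs are one argument away).  For ME
and MP the inner allocation problem is re-solved inside every likelihood
evaluation using warm-started continuation plus a rounded-parameter cache;
the final reported allocation is always recomputed with the full multistart
planner.  ME likelihood evaluations outside the finite-expected-loss region
receive a sloped penalty rather than a flat −∞, so the optimizer can walk
back into feasibility.

Model comparison uses AICc = −2LL + 2k + 2k(k+1)/(n−k−1) and
BIC = −2LL + k ln n, with n the participant's analyzed trial count (the
natural reading; stated here because "n" is often left implicit).  Paired
model differences are summarized by the median over participants with a
percentile-bootstrap 95% CI of the median (participants resampled with
replacement).  Signed differences are always reported with the pair order
explicit in the output header, since the sign convention is otherwise
ambiguous.

## Synthetic experiments

The generator reproduces the task design: four targets, one per visual
quadrant, at 10 ± 1 dva eccentricity on a 10°-step polar grid avoiding the
cardinal axes; delays uniform over 1000–4000 ms in 500 ms steps; probed
condition drawn with probabilities (0.6, 0.3, 0.1).  The 1-dva location
jitter is applied radially with the angle kept on the grid — tangential
jitter at 10 dva spans ~5.7° and would defeat the design's cardinal-axis
avoidance.  Defaults: 600 trials per synthetic participant (per-session
counts are not published; this is an assumption), J̄_total = 3.0 dva⁻²,
τ = 0.5 dva⁻², λ = 5.0 points for "representative" observers — chosen to
reproduce the published error scale (≈1.2 dva mean error at high priority,
≈2.1 dva at low) for 10-dva targets.  Optional features: a uniform dropout
flag (1–7%) emulating exclusion screening (the package models
post-screening data), and a delay-decay hook (precision scaled by
exp(−rate·delay)) that exists to exercise the permutation machinery —
by default delay has no effect on precision.

What the generator does *not* emulate: gaze dynamics, corrective saccades,
screen-bounded responses (errors are unbounded under the model; a
degenerate allocation can produce absurdly large simulated errors),
response biases, swap errors, or any metacognitive noise.  Passing tests on
synthetic data therefore validate the estimation machinery and the model's
internal consistency, not the model's adequacy for real observers.

## Behavioral statistics

Per-priority means ± across-participant SEM of error and radius (participant
means first, then across-participant dispersion).  Within-priority
error–radius association is Spearman rank correlation after standardizing
both variables within participant (M = 0, SD = 1) to remove
participant-specific main effects before pooling; per-participant
correlations are also reported (cells under 3 trials omitted with a
warning).  Repeated-measures ANOVA is deliberately not reimplemented; the
tidy participant × priority table it needs is exported instead.

The permutation controls ask whether the error–radius coupling survives
removal of location- and delay-driven structure: within each participant ×
priority cell, radii are shuffled only among trials in the same covariate
stratum — identical delay (7 levels), or the same polar-angle bin of the
target.  This preserves covariate-driven association while destroying
trial-level coupling.  The location bin defaults to 30° (three obliqueness
levels per quadrant): strata at the stimulus grid's native 10° leave only
1–2 trials each at realistic trial counts, so the shuffle would preserve
most of the observed pairing and the null would hug the observed
correlation rather than centering near zero; the width is configurable for
sensitivity analyses.  Observed correlations are compared to per-cell null
medians with a Wilcoxon signed-rank test; the all-zero-difference case is
flagged as degenerate rather than tested.

## Recovery protocols

Parameter recovery simulates participants from known parameters and refits
the generating model; the headline checks use the Flexible model at the
fitted group-mean allocations — (0.49, 0.28, 0.23) for the estimation
experiment (20 synthetic participants) and (0.44, 0.31, 0.25) for the
joint wager fit (scaled to one participant) — with recovery judged on the
allocation proportions.  Model recovery fits all candidate strategies to
data simulated from each one and tabulates AICc winners as a confusion
matrix.  All four generators share the representative precision budget
(J̄_total = 3.0, τ = 0.5), at which the MP optimum is interior
(≈ 0.62/0.32/0.06) — a budget small enough that MP visibly shortchanges
the low-priority item, but not so small that its optimum collapses onto
the numerical simplex floor and the simulated data degenerate.  Generating
allocations are chosen well-separated: the Flexible generator uses
p = (0.40, 0.25, 0.35), an ordering (low above medium) that no ME observer
can produce, because nested and near-equivalent generating allocations are
*expected* to confuse — when Flexible generates data at exactly p = t,
Proportional rightly wins on parsimony, and that nesting case is verified
separately.

## Numerical and degenerate-input conventions

* Densities are floored at 1e−300 before logs; impossible parameter regions
  yield −∞ log-likelihood (flagged), never NaN.
* Simulated precisions are floored at 1e−12 so degenerate allocations
  cannot emit J = 0.
* Gamma quantiles below float range fall back to an asymptotic small-shape
  formula.
* All randomness flows through explicit seeds (`numpy` `SeedSequence`
  children for cohorts); identical seeds give byte-identical trial tables.

## Known limitations

* The ME/MP planners assume three probed conditions in testing; the API
  accepts any length-n probability vector but only n = 3 is exercised.
* β is bounded at 5 and the expected-loss feasibility constraint couples β
  to J̄_total/τ, so extremely error-sensitive observers with tiny resource
  are not representable.
* The wager model has no lapse/guessing component; real observers'
  occasional arbitrary circles would bias λ upward.
* Problem sizes in the test-suite recovery runs (participants, datasets,
  restart counts) are desk-scale choices; conclusions about borderline
  model discriminability deserve the full 50-restart protocol.
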