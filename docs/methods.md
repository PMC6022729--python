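# Methods

This note records the model as implemented, the choices made where the
formulation was genuinely open, and what the packaged tests do and do not
establish.

## Model

Choice sets are described by raw attribute magnitudes; nothing is normalized
or unit-matched.  Working memory on dimension *i* is the multiset of all
present alternative values on *i* plus any context values on *i* (prior
trials, phantom/unavailable options, long-term-memory samples).  One
comparison step selects an evaluation target cell (alternative × dimension),
selects a partner from that dimension's pool, and runs a soft ordinal
comparison; a win adds one evidence unit to the target's alternative.
Accumulation stops when the leading evidence count exceeds the mean count by
θ (relative stopping rule).

**Distance.**  D(a, x) = |a − x| / |x|, a Weber fraction.  It is asymmetric
(the comparator sets the denominator) and undefined at zero, so all
magnitudes must be strictly positive; quoted £0 values are encoded as a
configurable placeholder (default 0.01), which preserves the property that a
vanishing amount is beaten by everything.  Fractional distances make every
output invariant to rescaling a dimension's units; the suite asserts this to
1e−12.

**Attention (target selection).**  A cell's weight is Σ exp(−α·D) over its
comparator pool; weights are normalized over all cells of choosable
alternatives.  Context values are never targets.  A cell whose value is
missing, or whose pool is empty after self-exclusion, has zero probability —
this single rule produces both the missing-value handling behind the
intransitive-cycle prediction and the inertness of non-aligned (unique)
attributes.

**Self-exclusion.**  The target's own value instance is removed from its
comparator pool.  Other pool entries that merely equal the target in value
remain: they attract attention maximally (distance zero) but can never be
beaten (ties win with probability zero).  This matters for near-clone and
shared-value stimuli, where unwinnable near-ties soak up comparisons.

**Partner selection.**  The functional form is not pinned down by the
verbal theory; we select partners with the same similarity weighting as
attention, p(X | A_i) ∝ exp(−α·D(A_i, X)).  A consequence worth stating
plainly: with identical weights for attention and partner choice, the
attention term cancels from the accumulation rate, which reduces to

rate(A) = Σ_cells Σ_X exp(−α·D(A_i, X)) · win(A_i, X) / W,

with W the total attention weight.  Evaluation *frequency* therefore only
matters through the comparisons it brings — an alternative profits from
being attended only if it wins some of those comparisons.  This is exactly
why the phantom-decoy preset reports a null under the standard rule: a
phantom that dominates its neighbour A contributes attention but no winnable
comparisons, so p(A) can never rise above one half, at any α.  All core
functions accept a `partner_alpha` override (0 = uniform partner choice)
that breaks the cancellation; under uniform partners the phantom effect
emerges, weakly at α = 3 and strongly at α = 10, which the preset reports
alongside the standard-rule null.

**Soft comparison.**  Win probability F(β₁·(D − β₀)) when the target is
strictly preferable under the dimension's polarity, else zero.  β₀ = 0.1 is
the fractional advantage won at even odds; β₁ = 50 sets how sharply
recognition rises (a 20 % advantage is won with probability .993).  Ties and
disadvantages never win.

**Stopping and choice probabilities.**  For n alternatives and
θ ≤ 1 − 1/n the first evidence unit satisfies the criterion, so choice
probabilities are the normalized rates and the expected number of comparison
steps is 1/Σrates (the geometric wait for the first unit).  For larger θ the
evidence walk is solved exactly as an absorbing chain over count vectors:
null steps (no evidence) are self-loops that stretch time without moving the
walk, so the embedded chain conditions them out and the expected step count
folds them back in.  Only an increment that creates a strict unique maximum
can trigger the stop, so the absorbing winner is always well defined.  The
state space is truncated at 200 total evidence units; residual transient
mass below 1e−12 is renormalized (with a warning), more than 1e−3 raises a
no-decision error.  The solver reproduces the two-alternative gambler's-ruin
closed form exactly and matches seeded Monte Carlo within three binomial
standard errors across a randomized battery.

**Time pressure.**  Fixed-horizon choice runs the same walk for a set
number of comparison steps (null steps included), absorbing early when the
relative criterion is met and breaking remaining ties uniformly among
evidence maxima.  Exact dynamic programming up to 25 steps, seeded
simulation beyond.  Because adding a never-winning attribute to one
alternative scales all rates down equally, it leaves untimed choice
probabilities untouched while strictly lowering that alternative's rate —
the less-is-more preset therefore reports both the rate drop and the
fixed-horizon probability drop, which is where the behavioural effect lives
in this model.

**Commensurable collapsing (attribute balance).**  When rating dimensions
share a scale, the collapsing option pools them into one joint *attention*
space: a value's attention weight sums similarity to all values of the
group, across dimensions and alternatives.  Ordinal comparisons (partner and
win) remain within the original dimension.  We examined full collapsing —
cross-dimension partners and wins as well — and it systematically favours
the *spread* alternative instead of the balanced one (its high value beats
both of the balanced option's middle values at high partner weight), i.e. it
destroys the effect the collapsing is meant to produce.  Coupling
cross-dimension attention with within-dimension comparison yields the
balanced alternative as the modal choice in all three rating triads, via the
compromise mechanism (the balanced option's middle values are similar to
everything and attract the most evaluations while the win counts stay
symmetric).

## Fixtures and the synthetic generator

- **Synthetic cars** (price USD lower-better, mpg higher-better):
  A = (24000, 32) and B = (16000, 24) are calibrated so their winning cells
  carry identical similarity weight and identical win probability, giving
  exact binary indifference at the defaults.  Decoys: D = (28000, 29)
  dominated by A; C = (32000, 40) extending the B→A line past A;
  S = (16500, 23) a near-clone of B whose fractional distances to B
  (≈ .03, .04) sit below β₀; R = (28000, 32) worsening only A's weak
  dimension (range decoy); F = (24000, 29) worsening only its strong one
  (frequency decoy); E = (36000, 23), the far end of the A–D line used by
  the decoy-distance sweep (off that line the swept profile loses its
  brief-strengthening phase).
- **Decoy constructors** implement the experiment-style rules: attraction
  = favored alternative worsened by 25 % of the per-dimension |A−B| in the
  utility direction; similarity = the rival perturbed ∓2 % of |A−B| (the
  subtraction lands on the first declared dimension, overridable, since the
  assignment is not specified); compromise = the rival→favored line extended
  past the favored end by a factor of 1.0 (symmetric spacing; the magnitude
  is exposed as a parameter because no canonical value exists).
- **Long-term-memory pools** are correlated normals (mean at car A's
  values, per-dimension sd = |A−B|, correlation −0.2), truncated to positive
  values by rejection; a marginal with more than 99 % nonpositive mass is
  refused.  Scenario means use 500 seeded replicates in the acceptance
  battery (150 in the fast unit tests), scaled down from a 5000-replicate
  design; at these sizes the dilution trend is stable to well under the
  asserted margins.
- **Background-contrast computers** honour the three printed trade-off
  rates (0.22, 2.50, 17.50 $ per KB): the focal pair A = (600 $, 320 KB),
  B = (400 $, 240 KB) mirrors the car calibration (binary .5/.5); the
  shallow prior pair (450/500, 428/400) leaves B's price rank at 1.0 while
  cutting A's RAM rank from 1.0 to 1/3; the steep pair (350/310, 280/306)
  does the reverse.
- **Monetary pools** are the quoted skewed and uniform sets and 1-unit
  grids for gains (0–40) and losses (0–20).

What the generator does *not* emulate: response-time distributions,
trial-order or learning dynamics, attribute-value noise, and individual
heterogeneity beyond the α sweep.  Passing tests show the mechanisms produce
the documented directions under these study conditions, not that the fixture
magnitudes match any particular market.

## Inference

Closed-form probabilities make the multinomial log-likelihood immediate;
zero-probability observed choices are clipped at 1e−12 with a warning.
Fitting is bounded multi-start L-BFGS-B (α ∈ [0, 10], β₀ ∈ [0, 1],
β₁ ∈ (0, 500], θ ∈ (0, 5]), deterministic given the seed; parameter points
where the walk cannot absorb within the evidence cap are penalized rather
than raised.  θ is fixed by default: whenever θ ≤ 1 − 1/n for every design
problem, choice probabilities are normalized rates and contain no
information about θ (and β₁ is only weakly identified), which the recovery
report flags analytically.  Recovery over the four packaged car choice sets
at 10⁴ choices brings α̂ within ±0.5 and β̂₀ within ±0.03 of the generating
values on average, with the replicate interquartile range covering the
truth.

## Numerical choices

- Stopping comparisons use a 1e−12 tie tolerance so integer-count states at
  the exact threshold count as stopped.
- The Monte Carlo simulator draws the per-step marginal (gain for
  alternative j with probability rate_j, else null) rather than the
  target/partner/win triple; the marginal is exactly the same distribution,
  and waiting times between evidence units are drawn geometrically, which
  keeps trials vectorized without changing any statistic.
- Probability normalizations raise explicit errors (degenerate problem,
  no decision) instead of returning NaN.
- Subjective value curves are *locally non-monotone* under
  similarity-weighted partners: approaching a pool value the target cannot
  beat, that value soaks up partner probability and the curve sags.  This is
  a real property of the model (the same mechanism bends the predicted value
  functions near the top of the money sets), documented by a dedicated test.

## Known limitations

- The phantom-decoy effect is not produced under the standard partner rule
  (see the cancellation argument above); the preset demonstrates it only
  under the uniform-partner override.
- Millisecond response times are out of scope; the comparison-step horizon
  is the only temporal quantity.
- A max-minus-next-best stopping variant exists as a config hook on the
  stopping rule and the closed-form solver, but the scenario battery and
  all documented results use max-minus-mean only.
- Endowment and polarization phenomena are outside the model's reach by
  design (no ownership or dimension-specific mechanisms exist).
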