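# mdbs — multialternative decision by sampling

A sequential-sampling model of multiattribute choice for researchers in
decision science and mathematical psychology.  `mdbs` is for anyone who needs
closed-form or simulated choice probabilities for choice sets described by
raw attribute magnitudes — to reproduce and probe multialternative context
effects (attraction, compromise, similarity, and a long tail of related
phenomena), to generate experiment-style decoy stimuli, or to fit the model's
parameters to observed choice frequencies.

## The model

A decision between alternatives described on attribute dimensions (each with
a preference polarity: higher-better like fuel efficiency, or lower-better
like price) proceeds as a series of pairwise **ordinal comparisons** of single
attribute values.  Working memory holds the choice set's values plus any
*context* values (prior trials, unavailable options, samples from long-term
memory).  On each comparison step:

1. **Target selection.**  The value A_i of alternative A on dimension i is
   selected for evaluation with probability proportional to its summed
   similarity to the other values in that dimension's working-memory pool,

   p(evaluate A_i) ∝ Σ_{X ≠ A_i} exp(−α·D(A_i, X)),

   where the distance is the Weber fraction D(a, x) = |a − x| / |x| and
   α ≥ 0 is the similarity decay.

2. **Partner selection.**  A comparison partner X is drawn from the same
   pool, again with probability ∝ exp(−α·D(A_i, X)).

3. **Soft ordinal comparison.**  If A_i is strictly preferable to X under
   the dimension's polarity, A gains one evidence unit with probability
   F(β₁·(D(A_i, X) − β₀)), a logistic in the fractional advantage; otherwise
   the step yields nothing.  With the default calibration (β₀ = 0.1,
   β₁ = 50) a 10 % advantage wins with probability exactly .50 and a 20 %
   advantage with more than .99.

4. **Relative stopping rule.**  Accumulation stops when
   max(evidence) − mean(evidence) ≥ θ.  With the default θ = 0.1 the first
   evidence unit decides, and choice probabilities are exactly the
   normalized accumulation rates; for larger θ the package solves the
   absorbing random walk over evidence counts exactly.

Defaults throughout: α = 3.0, β₀ = 0.1, β₁ = 50, θ = 0.1.  Because all
distances are fractions, every prediction is invariant to rescaling the
units of any dimension.

## Worked example

```python
from mdbs import load_fixture, predict_choice

cars = load_fixture("synthetic_big_three")   # price (USD), mpg
pair = cars.subset(["A", "B"])
triad = cars.subset(["A", "B", "D"])         # D is dominated by A

print(predict_choice(pair).probabilities)
print(predict_choice(triad).probabilities)
```

prints

```
{'A': 0.5, 'B': 0.5}
{'A': 0.5340052885054779, 'B': 0.2550526818057485, 'D': 0.21094202968877362}
```

Cars A (24 000 USD, 32 mpg) and B (16 000 USD, 24 mpg) are calibrated to an
exact .5/.5 split.  Adding the dominated decoy D (28 000 USD, 29 mpg) lifts
A to .534 — *above* its binary share, a regularity violation no simple
scalable choice model can produce — because A wins its comparisons against
the similar decoy while D itself rarely wins anything.

The scenario battery wraps each phenomenon as a named, parameterized run:

```python
from mdbs.scenarios import run_scenario
res = run_scenario("alpha_sweep")     # or: big_three, ltm_dilution,
print(res.effects)                    # time_pressure, attribute_balance,
                                      # intransitivity, background_contrast, ...
```

and a thin CLI exposes the same operations
(`mdbs predict --fixture synthetic_big_three:ABD`, `mdbs scenario
intransitivity`, `mdbs simulate --trials 10000 --seed 7 ...`).  The
`examples/` directory holds one short narrative script per capability.

## Layout

| module | contents |
|---|---|
| `mdbs.types` | problem containers: dimensions, alternatives, context pools, parameters |
| `mdbs.core` | distances, soft comparisons, attention weights, accumulation rates, relative ranks |
| `mdbs.process` | stopping rule, closed-form absorption, Monte Carlo simulator, fixed-horizon choice |
| `mdbs.fixtures` | packaged attribute tables, decoy constructors, long-term-memory sampling |
| `mdbs.scenarios` | named context-effect scenarios returning choice tables and effect sizes |
| `mdbs.inference` | multinomial likelihood, multi-start MLE, parameter-recovery report |
| `mdbs.io` / `mdbs.cli` | JSON/CSV choice-set schema, tidy result tables, command-line verbs |

See `docs/methods.md` for the modeling assumptions, numerical choices, and
known limitations.
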