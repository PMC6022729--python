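"""Two moderators of the context effects: comparison horizon and memory.

Left: limiting the number of pairwise comparisons (time pressure) shrinks
all three effects toward random choice.  Right: sampling attribute values
from long-term memory (familiarity with the domain) dilutes the immediate
context and also weakens the effects.
"""

from mdbs.scenarios import dilute_with_ltm, sweep_horizon

hz = sweep_horizon(horizons=(0, 1, 2, 5, 10))
print("comparisons allowed ->", hz.extras["horizons"])
for effect, curve in hz.extras["curves"].items():
    print(f"  {effect:<12}", "  ".join(f"{v:.3f}" for v in curve))

lt = dilute_with_ltm(sample_counts=(0, 4, 16, 64), n_reps=200, seed=0)
print("\nmemory samples ->", lt.extras["sample_counts"],
      f"(mean of {lt.extras['n_reps']} seeded replicates)")
for effect, curve in lt.extras["curves"].items():
    print(f"  {effect:<12}", "  ".join(f"{v:.3f}" for v in curve))

# Reading: every row is the effect size p(A) - p(B).  Effects are zero with
# no comparisons, grow with the horizon, and shrink as long-term-memory
# values crowd out the choice-set context.
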