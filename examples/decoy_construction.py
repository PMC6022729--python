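"""Experiment-style decoy generation for a consumer-product pair.

Takes the packaged mouthwash pair (hours of fresh breath, percent of germs
killed) and constructs the three decoy types used to assemble attraction,
similarity, and compromise choice sets around a favored alternative.
"""

from mdbs import (
    load_fixture,
    make_attraction_decoy,
    make_compromise_decoy,
    make_similarity_decoy,
    predict_choice,
)
from mdbs.types import DecisionProblem

problem = load_fixture("products:mouthwash")
A, B = problem.alternative("A"), problem.alternative("B")
print(f"A = {dict(A.values)}")
print(f"B = {dict(B.values)}")
base = predict_choice(problem)
print("binary baseline:",
      {k: round(v, 3) for k, v in base.probabilities.items()})

decoys = {
    "attraction (25% worse than A)": make_attraction_decoy(
        A, B, problem.dimensions, favored="A"
    ),
    "similarity (B perturbed by 2%)": make_similarity_decoy(
        A, B, problem.dimensions, favored="A"
    ),
    "compromise (line extended past A)": make_compromise_decoy(
        A, B, problem.dimensions, favored="A"
    ),
}
for label, d in decoys.items():
    triad = DecisionProblem(problem.dimensions, [A, B, d])
    dist = predict_choice(triad)
    vals = {k: round(v, 3) for k, v in d.values.items()}
    print(f"\n{label}: {vals}")
    print("  choice probabilities:",
          {k: round(v, 3) for k, v in dist.probabilities.items()})

# Reading: relative to the binary baseline, the dominated decoy and the
# near-clone of B both raise A's share relative to B's.  The compromise decoy makes
# A the intermediate option, but with these raw attribute magnitudes the
# extreme decoy's own advantage on germs killed is large and fully
# recognized, so the decoy itself profits -- decoy effects depend on the
# value magnitudes, not only on the geometry.
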