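"""A deterministic preference cycle from systematically missing values.

Three options each lack one attribute; every pair shares exactly one
dimension, and on that shared dimension one option is clearly better.  The
model never evaluates an option on a missing dimension, so each pairwise
choice is decided by the single shared comparison.
"""

from mdbs.scenarios import intransitivity_suite

res = intransitivity_suite()
for pair in ("VY", "YZ", "ZV"):
    probs = {k: round(v, 2) for k, v in res.tables[pair].probabilities.items()}
    print(f"choice between {pair[0]} and {pair[1]}: {probs}")
print("ternary choice:",
      {k: round(v, 3) for k, v in res.tables["VYZ"].probabilities.items()})

# Reading: Y beats V, Z beats Y, V beats Z -- each with probability one,
# because the loser's only shared-dimension comparison is a disadvantage and
# its accumulation rate is exactly zero.  With all three present the
# evidence spreads and no option is strongly preferred.
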