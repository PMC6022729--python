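"""Maximum-likelihood fitting and a small parameter-recovery check.

Generates synthetic choice counts from the closed-form probabilities over
the four packaged car choice sets, then refits the similarity decay alpha
and the comparison threshold beta0 by bounded multi-start MLE.
"""

import numpy as np

from mdbs import ModelParams, generate_choice_data, load_fixture
from mdbs.inference import ChoiceDataset, fit_mle, recovery_report

true = ModelParams()  # alpha=3.0, beta0=0.1, beta1=50, theta=0.1
fx = load_fixture("synthetic_big_three")
design = [fx.subset(list(s)) for s in ("AB", "ABD", "ABC", "ABS")]

dataset = ChoiceDataset()
rng = np.random.default_rng(0)
for problem in design:
    counts = generate_choice_data(
        problem, true, n_trials=2500, seed=int(rng.integers(2**31 - 1))
    )
    dataset.add(problem, counts)

fit = fit_mle(dataset, free=("alpha", "beta0"), seed=0)
print("single fit:", fit)

report = recovery_report(true, design, n_trials=10_000, n_replicates=10, seed=1)
print("\nrecovery over 10 replicates:")
print(report.to_string(index=False))

# Reading: the estimates cluster around the generating values (alpha=3,
# beta0=0.1).  The note column records that theta is analytically
# unidentifiable from choice frequencies here: below the relative-stopping
# boundary, choice probabilities are normalized accumulation rates and do
# not depend on theta.
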