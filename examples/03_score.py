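"""Build a chemoresistance score: GA selection + LDA classification.

On a labeled cohort with a planted 7-variable linear rule, run the GA
many times, rank variables by selection frequency, cut nested subsets,
pick the most accurate subset and score held-out samples with the
fitted linear discriminant.
"""

import warnings

from ublsig.score import (GAConfig, build_nested_subsets, classify_sample,
                          evaluate_subsets, ga_select, lda_fit)
from ublsig.simulate import simulate_score_cohort

warnings.filterwarnings("ignore")

X, labels, informative = simulate_score_cohort(
    n_variables=12, informative=5, n_samples=120, rng_seed=3)
train, test = X.index[:90], X.index[90:]

cfg = GAConfig(population=30, generations=30, n_runs=20, rng_seed=3)
scheme = ("split", 0.75, 8)
solutions = ga_select(X.loc[train], labels.loc[train], config=cfg,
                      scheme=scheme)
print("selection frequencies (top 6):")
print(solutions.frequencies.sort_values(ascending=False).head(6))

nested = build_nested_subsets(solutions, cut_points=(3, 5, 8, None),
                              X=X.loc[train], labels=labels.loc[train],
                              scheme=scheme)
table, best = evaluate_subsets(X.loc[train], labels.loc[train], nested,
                               scheme=("split", 0.75, 40))
print(table.to_string(index=False))
winning = nested.subsets[best]
print(f"winning subset ({len(winning)} variables): {winning}")
print(f"planted informative variables: {informative}")

model = lda_fit(X.loc[train, winning], labels.loc[train])
correct = 0
for sid in test:
    pred = classify_sample(model, X.loc[sid, winning].values, sample_id=sid)
    correct += pred.predicted_class == labels[sid]
print(f"held-out accuracy: {correct}/{len(test)}")
# A sample is called sensitive when its posterior probability of the
# resistant class is below 50% and resistant above; the score itself is
# the linear combination coef . x + intercept of the winning variables.
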