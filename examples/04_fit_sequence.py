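"""Fit the event-based model and quantify ordering uncertainty.

A planted cohort (P=12 regions, N=300 subjects, 2 SD component separation)
is fitted with the joint event model; 50 stratified bootstraps give the
positional-variance matrix, event centres and the randomness test. The
Kendall tau compares the recovered order against the planted truth.
"""

import numpy as np
from scipy.stats import kendalltau

from disconseq import (
    GeneratorConfig,
    bootstrap_sequences,
    default_region_ids,
    make_biomarker_cohort,
    randomness_test,
)

ids = default_region_ids(12)
sequence = [ids[j] for j in np.random.default_rng(1).permutation(12)]
cohort, truth = make_biomarker_cohort(
    GeneratorConfig(n_subjects=300, n_regions=12, seed=3), sequence
)

result = bootstrap_sequences(
    cohort.matrix, cohort.group_labels, n_boot=50, seed=0, region_ids=ids
)
true_pos = {r: i for i, r in enumerate(truth.sequence)}
tau = kendalltau([true_pos[r] for r in result.sequence_ids], range(12)).statistic

print("recovered order:", " -> ".join(result.sequence_ids))
print("planted order:  ", " -> ".join(truth.sequence))
print(f"Kendall tau vs truth: {tau:.3f}  (1.0 = identical order)")
print(f"log-likelihood of the fitted sequence: {result.log_likelihood:.1f}")

rnd = randomness_test(result.positional_variance, result.sequence)
print(f"randomness test: t = {rnd.t:.2f}, one-sided p = {rnd.p_one_sided:.2g} "
      "(small p: the order is reproducibly non-random across bootstraps)")
print("\nevent centres (mean bootstrap position, 1-based) +/- SE:")
for j in result.sequence:
    print(f"  {ids[j]}: {result.event_centres[j]:5.2f} +/- {result.event_centre_se[j]:.2f}")
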