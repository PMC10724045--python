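"""Data-driven region selection by bootstrapped t-statistic ranks.

A +2 SD group mean shift is planted in 20 of 86 regions. Each of 100
stratified bootstraps re-runs the two-sample t-test and ranks regions by t;
the 20 regions with the best average rank are selected. With this effect
size the planted set is recovered exactly.
"""

import numpy as np

from disconseq import bootstrap_rank_selection

rng = np.random.default_rng(0)
groups = np.array([0] * 200 + [1] * 200)
matrix = rng.standard_normal((400, 86))
matrix[groups == 1, :20] += 2.0  # planted group difference in regions 0..19

result = bootstrap_rank_selection(matrix, groups, n_boot=100, top_k=20, seed=1)

print(f"selected (best mean rank first): {result.selected_regions}")
planted = {str(j) for j in range(20)}
print(f"planted regions recovered: {len(planted & set(result.selected_regions))} / 20")
print(f"effective bootstraps: {result.n_boot_effective}")
print("\ntop rows of the per-region table:")
print(result.to_frame().sort_values("mean_rank").head(5).to_string(index=False))
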