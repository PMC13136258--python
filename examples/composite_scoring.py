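"""PCA composite scores and elite-accession screening.

Standardizes the traits, retains principal components with eigenvalue
> 1, weights each retained component by its share of the cumulative
variance contribution (W_i = c_i / sum c_j), and scores every accession
as F = sum W_i F_i.  Accessions with F > 1.00 are flagged elite.
"""

import numpy as np

from germdiv import (
    PhenoSimConfig,
    component_weights,
    screen_elite,
    simulate_phenotypes,
)
from germdiv.evaluation import evaluate, score_trait_correlations

table, _, _ = simulate_phenotypes(PhenoSimConfig(seed=42))
res, cs = evaluate(table)

print(f"Retained {res.retained} components (eigenvalue > 1), cumulative "
      f"contribution {res.cumulative[res.retained - 1]:.1f}%")
print("Weights:", np.round(cs.weights, 3))
print("Top 5 accessions by composite score F:")
top5 = cs.f.sort_values(ascending=False).head()
print(top5.round(3).to_string())

elite = screen_elite(cs, mode="threshold", threshold=1.0)
print(f"\n{len(elite)} accessions exceed F = 1.00 "
      "(overall performance above the panel mean).")

corr = score_trait_correlations(cs.f, table.values)
n_sig = (corr["p"] < 0.01).sum()
print(f"{n_sig}/{len(corr)} traits correlate with F at p < 0.01, so F summarizes "
      "many traits at once.")
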