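"""PCA of carapace landmarks and the Treatment x Molt model on PC1.

Landmarks are standardized and decomposed on the correlation matrix; for
juvenile crabs a single size axis dominates, and the sign convention makes
larger crabs score lower on PC1. Treatment and molt effects on PC1 are then
tested with crab-within-treatment intercepts.
"""

from oacrab import (CohortConfig, LANDMARKS, filter_molts, normalize,
                    pc_anova, pca, simulate_cohort)

exp = simulate_cohort(CohortConfig.red_king_crab(seed=0))
landmarks = LANDMARKS["red_king_crab"]
# almost no pH 7.5 crab survives to molt at its 0.025/day hazard, so that
# treatment is excluded from the score model (it would leave the design
# saturated); sparsely-reached late molts are dropped as well
molts = exp.molts[exp.molts["treatment"] != "ph75"]
kept = filter_molts(molts)

result = pca(normalize(kept, landmarks))
print(result.to_frame().head(2).to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print("\nPC1 loadings (all negative: bigger crab -> lower score):")
print(result.loadings["PC1"].to_string(float_format=lambda v: f"{v:.3f}"))

scores = kept[["crab_id", "treatment", "molt_number"]].reset_index(drop=True)
scores = scores.join(result.scores.reset_index(drop=True))
tests = pc_anova(scores)
print("\nPC1 fixed-effects table:")
print(tests["anova"].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
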