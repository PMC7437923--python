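"""Explain one pair's score by median ablation, and global importance.

Replacing a feature with its cohort-wide median approximates "this feature
contributed nothing"; the drop in the raw score (delta) is that feature's
contribution for this particular pair. Global importance (normalized total
gain of the ensemble) says what the model relies on overall.
"""

from catnip.explain import ablation_profile, model_feature_importance
from catnip.features import build_feature_table
from catnip.model import train
from catnip.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=1))
table = build_feature_table(cohort.records, cohort.resources)
model = train(table, seed=1)

# pick the highest-scoring shared pair
scores = model.score(table.features)
best = scores.argmax()
pair = tuple(table.features.index[best])
profile = ablation_profile(model, table.features.iloc[best], pair=pair)

print(f"pair {pair}, raw score {scores[best]:.2f}")
print("\ntop contributing features (delta = original - ablated score):")
print(profile.top_features(5).round(3).to_string())

imp = model_feature_importance(model).sort_values(ascending=False)
print("\nglobal feature importance (total gain, sums to 1):")
print(imp.head(5).round(3).to_string())
# Positive deltas pushed this pair's score up; the importance ranking shows
# which similarity channels the ensemble uses across all pairs.
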