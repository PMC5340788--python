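"""Cross-validated AUC for a panel of score sets on synthetic data.

Generates a default-condition universe, balances non-DDI pairs 1:1 per
query drug, scores every pair orientation, and compares logistic
models built from different score subsets by 4-fold cross-validation.
"""

from ddinet import (
    GeneratorConfig,
    SCORE_SETS,
    balanced_sample,
    evaluate_sets,
    generate,
    label_pairs,
    score_matrix,
)

synth = generate(GeneratorConfig(seed=0))
print(
    f"universe: {len(synth.universe.drugs)} drugs, "
    f"{len(synth.universe.ddi)} known DDI pairs"
)

pairs = label_pairs(synth.universe, restrict="annotated")
balanced = balanced_sample(pairs, seed=1)
features = score_matrix(balanced, synth.universe)
print(f"feature table: {len(features)} (Dq, De) rows, "
      f"{features['label'].mean():.2f} DDI fraction")

panel = ["Set1", "Set2", "Set3", "Set7", "Set11", "Set14", "Set19"]
table = evaluate_sets(features, panel, seed=3)
print("\n4-fold cross-validated AUC (higher is better):")
for row in table.itertuples(index=False):
    desc = SCORE_SETS[row.set_id].description
    print(f"  {row.set_id:6s} {row.mean_auc:.3f} +/- {row.sd_auc:.3f}   {desc}")

print(
    "\nIntegrated sets (Set1: direct + PK + PD) outrank single-information\n"
    "models (Set19: direct similarity only; Set14: target information\n"
    "only) — the network carries signal that drug structure alone misses."
)
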