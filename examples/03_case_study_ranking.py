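"""Leave-one-drug-out case study: rank DDI candidates for one drug.

Retrains the full-score model with every pair involving the subject
drug excluded, then ranks all other drugs by predicted interaction
probability — the package's analogue of a prospective case study.
"""

from ddinet import (
    GeneratorConfig,
    ScoreEngine,
    generate,
    leave_out_drug,
    rank_candidates,
)

synth = generate(GeneratorConfig(n_drugs=150, seed=4))
universe = synth.universe
engine = ScoreEngine(universe)

# choose the most DDI-annotated drug as the case-study subject
counts: dict[str, int] = {}
for a, b in universe.ddi:
    counts[a] = counts.get(a, 0) + 1
    counts[b] = counts.get(b, 0) + 1
subject = max(sorted(counts), key=counts.get)
print(f"subject: {subject} with {counts[subject]} known DDI partners")

model = leave_out_drug(universe, subject, "Set1", seed=2, engine=engine)
top = rank_candidates(model, universe, subject, k=10, engine=engine)

print("\ntop-10 predicted DDI candidates (subject's pairs never trained on):")
for i, row in enumerate(top.itertuples(index=False), start=1):
    marker = "known DDI" if row.known_ddi else ""
    print(f"  {i:2d}. {row.candidate}  p={row.probability:.3f}  {marker}")

hits = int(top["known_ddi"].sum())
print(
    f"\n{hits}/10 top candidates are known partners the model never saw —\n"
    "the rest are novel predictions driven by shared network mechanisms."
)
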