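"""Score one ordered drug pair over the examined drug's network.

Builds a seven-drug universe by hand — an examined drug DE with one
enzyme, one transporter, one target and one PPI partner of that target
— and prints the seven structural-similarity scores for a query drug
DA against DE.
"""

import numpy as np

from ddinet import AssociationUniverse, Drug, build_network, compute_scores


def fp(bits: str) -> np.ndarray:
    return np.array([c == "1" for c in bits], dtype=bool)


universe = AssociationUniverse(
    drugs={
        "DE": Drug("DE", fp("11110000")),
        "DA": Drug("DA", fp("11100000")),  # query drug, similar to DE
        "DB": Drug("DB", fp("01110001")),  # shares DE's enzyme
        "DC": Drug("DC", fp("00111100")),  # shares DE's transporter
        "DD": Drug("DD", fp("11000011")),  # shares DE's target
        "DF": Drug("DF", fp("00001111")),  # targets a PPI partner of DE's target
        "DG": Drug("DG", fp("10101010")),  # pharmacogenetic associations
    },
    drug_protein={
        ("DE", "E1", "enzyme"), ("DB", "E1", "enzyme"),
        ("DE", "Tr1", "transporter"), ("DC", "Tr1", "transporter"),
        ("DE", "T1", "target"), ("DD", "T1", "target"),
        ("DF", "P1", "target"),
    },
    drug_gene_pg={("DG", "E1")},
    ppi={("P1", "T1")},
    ddi=set(),
)

network = build_network("DE", universe)
print("network of DE (drugs per category):")
for category, members in network.category_drugs.items():
    print(f"  {category:16s} {sorted(members) or '-'}")

scores = compute_scores("DA", "DE", universe)
print("\nscores for the ordered pair (Dq=DA, De=DE):")
for name, value in scores.as_dict().items():
    print(f"  {name:6s} {value:+.4f}")

print(
    "\ns_d is the direct Tanimoto similarity of DA and DE; each other score\n"
    "is DA's best similarity to the drugs of one network category; -10\n"
    "marks a category with no drugs (here the transporter/target\n"
    "pharmacogenetic layers, since DG is only linked to the enzyme gene)."
)
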