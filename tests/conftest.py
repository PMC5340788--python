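import numpy as np
import pytest

from ddinet import AssociationUniverse, Drug, GeneratorConfig, generate


def fp(bits: str) -> np.ndarray:
    return np.array([c == "1" for c in bits], dtype=bool)


def make_universe(drugs, drug_protein=(), drug_gene_pg=(), ppi=(), ddi=()):
    """Build a universe from literal tuples; pairs are canonicalized."""
    return AssociationUniverse(
        drugs={d: Drug(d, fp(bits)) for d, bits in drugs.items()},
        drug_protein=set(drug_protein),
        drug_gene_pg=set(drug_gene_pg),
        ppi={tuple(sorted(p)) for p in ppi},
        ddi={tuple(sorted(p)) for p in ddi},
    )


@pytest.fixture
def toy_universe():
    """Six drugs, 8-bit fingerprints, all three protein layers, PPI, pg.

    Laid out after the canonical one-De sketch: DE has enzyme E1,
    transporter Tr1 and target T1; T1 physically interacts with P1.
    DA/DB share E1, DC is transported by Tr1, DD targets T1, DF targets
    the PPI neighbour P1, and DG carries pharmacogenetic associations.
    """
    return make_universe(
        drugs={
            "DE": "11110000",
            "DA": "11100000",
            "DB": "01110001",
            "DC": "00111100",
            "DD": "11000011",
            "DF": "00001111",
            "DG": "10101010",
        },
        drug_protein=[
            ("DE", "E1", "enzyme"),
            ("DA", "E1", "enzyme"),
            ("DB", "E1", "enzyme"),
            ("DE", "Tr1", "transporter"),
            ("DC", "Tr1", "transporter"),
            ("DE", "T1", "target"),
            ("DD", "T1", "target"),
            ("DF", "P1", "target"),
        ],
        drug_gene_pg=[("DG", "E1"), ("DG", "T1")],
        ppi=[("T1", "P1")],
        ddi=[("DE", "DA"), ("DE", "DD")],
    )


def random_universe(rng: np.random.Generator, n_drugs=None, n_proteins=None):
    """A small random universe for oracle-equivalence sweeps."""
    n = int(n_drugs if n_drugs is not None else rng.integers(3, 11))
    n_prot = int(n_proteins if n_proteins is not None else rng.integers(1, 7))
    n_bits = 16
    drugs = {}
    for i in range(n):
        bits = rng.random(n_bits) < 0.4
        if not bits.any():
            bits[int(rng.integers(0, n_bits))] = True
        drugs[f"d{i:02d}"] = Drug(f"d{i:02d}", bits)
    ids = sorted(drugs)
    proteins = [f"p{j}" for j in range(n_prot)]
    roles = ["enzyme", "transporter", "target"]
    drug_protein = {
        (d, p, r)
        for d in ids
        for p in proteins
        for r in roles
        if rng.random() < 0.25
    }
    drug_gene_pg = {(d, p) for d in ids for p in proteins if rng.random() < 0.15}
    ppi = {
        tuple(sorted((a, b)))
        for i, a in enumerate(proteins)
        for b in proteins[i + 1 :]
        if rng.random() < 0.3
    }
    ddi = {
        tuple(sorted((a, b)))
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
        if rng.random() < 0.2
    }
    return AssociationUniverse(
        drugs=drugs, drug_protein=drug_protein, drug_gene_pg=drug_gene_pg,
        ppi=ppi, ddi=ddi,
    )


@pytest.fixture(scope="session")
def small_synth():
    """A quick synthetic universe for pipeline tests."""
    return generate(GeneratorConfig(n_drugs=120, bit_length=128, seed=3))


@pytest.fixture(scope="session")
def default_synth():
    """The default-condition synthetic universe (seed 0)."""
    return generate(GeneratorConfig(seed=0))
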