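"""Per-drug interaction networks and structural-similarity scores.

For an ordered drug pair (Dq, De) — a query drug against a drug under
examination — the network of De collects the other drugs connected to
De's proteins:

* ``enzyme_int`` / ``enzyme_pg``: drugs interacting with, or
  pharmacogenetically associated with, De's metabolizing enzymes;
* ``transporter_int`` / ``transporter_pg``: likewise for De's
  transporters;
* ``target_int`` / ``target_pg``: likewise for De's target proteins
  *and* their one-hop partners in the protein-protein interaction (PPI)
  graph — the pharmacodynamic neighbourhood.

Seven scores summarize the pair: ``s_d`` is the Tanimoto similarity of
the two fingerprints, and each of ``s_e``, ``s_eg``, ``s_tr``,
``s_trg``, ``s_ta``, ``s_tag`` is the *maximum* Tanimoto similarity
between Dq and the drugs of the corresponding category, after removing
Dq and De themselves from the category.  An empty category yields the
sentinel value −10, which downstream models consume as a literal
number.  The rationale for the maximum: structurally similar drugs tend
to engage the same protein, and the most similar drug in a
sub-network is the most likely to mediate an interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .store import AssociationUniverse, canonical_pair

SENTINEL = -10.0

SCORE_NAMES = ("s_d", "s_e", "s_eg", "s_tr", "s_trg", "s_ta", "s_tag")

#: network category -> score column it feeds
CATEGORIES = {
    "enzyme_int": "s_e",
    "enzyme_pg": "s_eg",
    "transporter_int": "s_tr",
    "transporter_pg": "s_trg",
    "target_int": "s_ta",
    "target_pg": "s_tag",
}

FEATURE_COLUMNS = ["dq_id", "de_id", *SCORE_NAMES, "s_max", "label"]


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two bit vectors."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    if not a.any() or not b.any():
        raise ValueError("all-zero fingerprint has no defined Tanimoto similarity")
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    return inter / union


@dataclass
class DrugNetwork:
    """The network of one examined drug De: proteins and attached drugs."""

    de_id: str
    category_drugs: dict[str, set[str]]
    proteins: dict[str, set[str]]  # enzymes / transporters / targets / ppi_neighbors

    @property
    def network_drugs(self) -> set[str]:
        """Union of all category drugs (De itself is never a member)."""
        out: set[str] = set()
        for members in self.category_drugs.values():
            out |= members
        return out

    @property
    def is_empty(self) -> bool:
        return not self.network_drugs


@dataclass(frozen=True)
class ScoreVector:
    """The seven similarity scores for one ordered (Dq, De) pair."""

    dq_id: str
    de_id: str
    s_d: float
    s_e: float
    s_eg: float
    s_tr: float
    s_trg: float
    s_ta: float
    s_tag: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SCORE_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SCORE_NAMES}


def whole_network_max(scores: ScoreVector) -> float:
    """Maximum over the seven scores; sentinels compete as literal −10."""
    return float(scores.as_array().max())


class ScoreEngine:
    """Vectorized scorer over one universe.

    Precomputes the full pairwise Tanimoto matrix and caches per-De
    networks, so scoring all query drugs against one De is a handful of
    column-max reductions.  The incremental cost per De is
    O(n_drugs x network size).
    """

    def __init__(self, universe: AssociationUniverse):
        self.universe = universe
        mat, ids = universe.fingerprint_matrix()
        self.ids = ids
        self.index = {d: i for i, d in enumerate(ids)}
        counts = mat.sum(axis=1).astype(np.int64)
        inter = np.dot(mat.astype(np.float32), mat.astype(np.float32).T)
        inter = np.asarray(np.rint(inter), dtype=np.int64)
        union = counts[:, None] + counts[None, :] - inter
        self.tanimoto_matrix = inter / union
        self._networks: dict[str, DrugNetwork] = {}
        self._score_cache: dict[str, np.ndarray] = {}
        self._by_protein_role: dict[tuple[str, str], set[str]] = {}
        for d, p, role in universe.drug_protein:
            self._by_protein_role.setdefault((p, role), set()).add(d)
        self._pg_by_gene: dict[str, set[str]] = {}
        for d, g in universe.drug_gene_pg:
            self._pg_by_gene.setdefault(g, set()).add(d)
        self._ppi_adj: dict[str, set[str]] = {}
        for a, b in universe.ppi:
            self._ppi_adj.setdefault(a, set()).add(b)
            self._ppi_adj.setdefault(b, set()).add(a)
        self._de_proteins: dict[tuple[str, str], set[str]] = {}
        for d, p, role in universe.drug_protein:
            self._de_proteins.setdefault((d, role), set()).add(p)

    # -- network construction -----------------------------------------
    def network(self, de_id: str) -> DrugNetwork:
        if de_id not in self.index:
            raise KeyError(f"unknown drug {de_id!r}")
        cached = self._networks.get(de_id)
        if cached is not None:
            return cached

        enzymes = set(self._de_proteins.get((de_id, "enzyme"), ()))
        transporters = set(self._de_proteins.get((de_id, "transporter"), ()))
        targets = set(self._de_proteins.get((de_id, "target"), ()))
        neighbors: set[str] = set()
        for t in targets:
            neighbors |= self._ppi_adj.get(t, set())
        neighbors -= targets
        pd_proteins = targets | neighbors

        def interacting(proteins: set[str], role: str) -> set[str]:
            out: set[str] = set()
            for p in proteins:
                out |= self._by_protein_role.get((p, role), set())
            return out - {de_id}

        def pharmacogenetic(proteins: set[str]) -> set[str]:
            out: set[str] = set()
            for p in proteins:
                out |= self._pg_by_gene.get(p, set())
            return out - {de_id}

        net = DrugNetwork(
            de_id=de_id,
            category_drugs={
                "enzyme_int": interacting(enzymes, "enzyme"),
                "enzyme_pg": pharmacogenetic(enzymes),
                "transporter_int": interacting(transporters, "transporter"),
                "transporter_pg": pharmacogenetic(transporters),
                "target_int": interacting(pd_proteins, "target"),
                "target_pg": pharmacogenetic(pd_proteins),
            },
            proteins={
                "enzymes": enzymes,
                "transporters": transporters,
                "targets": targets,
                "ppi_neighbors": neighbors,
            },
        )
        self._networks[de_id] = net
        return net

    # -- scoring -------------------------------------------------------
    def scores_for_de(self, de_id: str) -> np.ndarray:
        """Scores of every drug as Dq against this De.

        Returns an (n_drugs, 7) array in the order of :attr:`ids`; the
        row for De itself is meaningless (a pair requires Dq != De).
        Dq-removal is applied per row: a drug that belongs to a category
        of De's network is never compared against itself.  The returned
        block is cached per De; treat it as read-only.
        """
        cached = self._score_cache.get(de_id)
        if cached is not None:
            return cached
        net = self.network(de_id)
        de_idx = self.index[de_id]
        n = len(self.ids)
        T = self.tanimoto_matrix
        out = np.full((n, len(SCORE_NAMES)), SENTINEL)
        out[:, 0] = T[:, de_idx]
        for col, (category, _score) in enumerate(CATEGORIES.items(), start=1):
            members = net.category_drugs[category]
            if not members:
                continue
            m_idx = np.array(sorted(self.index[d] for d in members), dtype=np.int64)
            sub = T[:, m_idx]
            out[:, col] = sub.max(axis=1)
            # a Dq inside the category is scored against the others only
            for pos, dq_idx in enumerate(m_idx):
                if m_idx.size == 1:
                    out[dq_idx, col] = SENTINEL
                else:
                    mask = np.ones(m_idx.size, dtype=bool)
                    mask[pos] = False
                    out[dq_idx, col] = sub[dq_idx, mask].max()
        self._score_cache[de_id] = out
        return out

    def compute_scores(self, dq_id: str, de_id: str) -> ScoreVector:
        if dq_id == de_id:
            raise ValueError("a pair requires two distinct drugs")
        if dq_id not in self.index:
            raise KeyError(f"unknown drug {dq_id!r}")
        row = self.scores_for_de(de_id)[self.index[dq_id]]
        return ScoreVector(dq_id, de_id, *map(float, row))


def build_network(de_id: str, universe: AssociationUniverse) -> DrugNetwork:
    """Construct the interaction network of one examined drug."""
    return ScoreEngine(universe).network(de_id)


def compute_scores(dq_id: str, de_id: str, universe: AssociationUniverse) -> ScoreVector:
    """Score one ordered (Dq, De) pair; see the module docstring."""
    return ScoreEngine(universe).compute_scores(dq_id, de_id)


def score_matrix(
    pairs: pd.DataFrame,
    universe: AssociationUniverse | None = None,
    orientation: str = "both",
    engine: ScoreEngine | None = None,
) -> pd.DataFrame:
    """Score a labeled unordered-pair table into a feature table.

    ``pairs`` needs columns ``drug_a``, ``drug_b``, ``label``.  DDI
    labels are unordered while scores are ordered, so an orientation
    policy decides which (Dq, De) rows each pair emits:

    * ``both`` (default): one row per orientation whose De has a
      non-empty network;
    * ``de_richer``: a single row with De the drug whose network holds
      more drugs, ties broken toward the lexicographically smaller id.

    Under either policy, a De whose network contains no other drug
    contributes no row; a pair may therefore emit zero rows.
    """
    if orientation not in ("both", "de_richer"):
        raise ValueError(f"unknown orientation policy {orientation!r}")
    if engine is None:
        if universe is None:
            raise ValueError("either a universe or a prepared engine is required")
        engine = ScoreEngine(universe)

    wanted: dict[str, list[tuple[str, int]]] = {}  # de_id -> [(dq_id, label)]
    for drug_a, drug_b, label in zip(pairs["drug_a"], pairs["drug_b"], pairs["label"]):
        if drug_a == drug_b:
            continue
        size_a = len(engine.network(drug_a).network_drugs)
        size_b = len(engine.network(drug_b).network_drugs)
        if orientation == "both":
            if size_b > 0:
                wanted.setdefault(drug_b, []).append((drug_a, int(label)))
            if size_a > 0:
                wanted.setdefault(drug_a, []).append((drug_b, int(label)))
        else:
            if size_a == 0 and size_b == 0:
                continue
            if size_a > size_b:
                de, dq = drug_a, drug_b
            elif size_b > size_a:
                de, dq = drug_b, drug_a
            else:
                de, dq = canonical_pair(drug_a, drug_b)
            wanted.setdefault(de, []).append((dq, int(label)))

    records: list[tuple] = []
    for de_id in sorted(wanted):
        score_block = engine.scores_for_de(de_id)
        for dq_id, label in wanted[de_id]:
            row = score_block[engine.index[dq_id]]
            records.append((dq_id, de_id, *row, row.max(), label))
    df = pd.DataFrame(records, columns=FEATURE_COLUMNS)
    df["label"] = df["label"].astype(np.int64)
    return df


def write_feature_table(df: pd.DataFrame, path: str) -> None:
    """Write a feature table as TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
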