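"""Drugs, fingerprints and association layers.

The universe of evidence the scoring engine consumes:

* drugs with fixed-length binary structural fingerprints,
* drug-protein associations typed by protein role (enzyme, transporter,
  target),
* drug-gene pharmacogenetic associations (gene identifiers share the
  protein namespace, so a pharmacogenetic edge grounds on a network
  protein when its gene id equals the protein id),
* an undirected protein-protein physical-interaction (PPI) graph,
* undirected known drug-drug interaction (DDI) pairs.

Any drug pair absent from the DDI layer is treated as a non-interacting
pair: there is no "unknown" tier.  All layers load from plain
tab-delimited text with one header line; ``#`` starts a comment line.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("enzyme", "transporter", "target")

#: default fingerprint width, matching the PubChem 2D substructure keys
DEFAULT_BIT_LENGTH = 881

FILE_NAMES = {
    "drugs": "drugs.tsv",
    "drug_protein": "drug_protein.tsv",
    "drug_gene_pg": "drug_gene_pg.tsv",
    "ppi": "ppi.tsv",
    "ddi": "ddi.tsv",
}


class UniverseError(ValueError):
    """Raised when association data violate the universe contracts."""


@dataclass(frozen=True, eq=False)
class Drug:
    """A drug: an opaque identifier plus a binary structural fingerprint."""

    drug_id: str
    fingerprint: np.ndarray  # 1-D bool array

    def __post_init__(self) -> None:
        fp = np.asarray(self.fingerprint, dtype=bool)
        object.__setattr__(self, "fingerprint", fp)
        if fp.ndim != 1:
            raise UniverseError(f"drug {self.drug_id!r}: fingerprint must be 1-D")
        if not fp.any():
            raise UniverseError(f"drug {self.drug_id!r}: all-zero fingerprint")

    @property
    def n_bits(self) -> int:
        return int(self.fingerprint.size)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical form of an unordered pair (sorted tuple)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class AssociationUniverse:
    """All drugs and typed association layers, validated and deduplicated.

    Edge layers are stored as sets of tuples; undirected layers (PPI, DDI)
    store each unordered pair once in canonical (sorted) order.
    """

    drugs: dict[str, Drug]
    drug_protein: set[tuple[str, str, str]] = field(default_factory=set)
    drug_gene_pg: set[tuple[str, str]] = field(default_factory=set)
    ppi: set[tuple[str, str]] = field(default_factory=set)
    ddi: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        lengths = {d.n_bits for d in self.drugs.values()}
        if len(lengths) > 1:
            raise UniverseError(f"inconsistent fingerprint lengths: {sorted(lengths)}")
        for did, drug in self.drugs.items():
            if did != drug.drug_id:
                raise UniverseError(f"drug key {did!r} != drug_id {drug.drug_id!r}")
        for did, pid, role in self.drug_protein:
            if role not in ROLES:
                raise UniverseError(f"unknown protein role {role!r} on ({did}, {pid})")
            self._require_drug(did, "drug_protein")
        for did, _gid in self.drug_gene_pg:
            self._require_drug(did, "drug_gene_pg")
        for a, b in self.ppi:
            if a == b:
                raise UniverseError(f"PPI self-loop on {a!r}")
            if (a, b) != canonical_pair(a, b):
                raise UniverseError(f"non-canonical PPI pair ({a!r}, {b!r})")
        for a, b in self.ddi:
            if a == b:
                raise UniverseError(f"DDI self-pair on {a!r}")
            if (a, b) != canonical_pair(a, b):
                raise UniverseError(f"non-canonical DDI pair ({a!r}, {b!r})")
            self._require_drug(a, "ddi")
            self._require_drug(b, "ddi")

    def _require_drug(self, drug_id: str, layer: str) -> None:
        if drug_id not in self.drugs:
            raise UniverseError(f"{layer}: unknown drug_id {drug_id!r}")

    # -- convenience ---------------------------------------------------
    @property
    def n_bits(self) -> int:
        if not self.drugs:
            raise UniverseError("empty universe has no fingerprint length")
        return next(iter(self.drugs.values())).n_bits

    def drug_ids(self) -> list[str]:
        """Drug identifiers in sorted (deterministic) order."""
        return sorted(self.drugs)

    def has_ddi(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.ddi

    def ddi_annotated_drugs(self) -> set[str]:
        """Drugs appearing in at least one known DDI pair."""
        out: set[str] = set()
        for a, b in self.ddi:
            out.add(a)
            out.add(b)
        return out

    def fingerprint_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Stacked fingerprints (n_drugs x n_bits, bool) in sorted id order."""
        ids = self.drug_ids()
        mat = np.stack([self.drugs[d].fingerprint for d in ids])
        return mat, ids


# ---------------------------------------------------------------------
# fingerprint dialects
# ---------------------------------------------------------------------

def parse_bitstring(text: str) -> np.ndarray:
    arr = np.frombuffer(text.strip().encode("ascii"), dtype=np.uint8)
    if not np.isin(arr, (ord("0"), ord("1"))).all():
        raise UniverseError(f"bitstring contains characters other than 0/1: {text[:20]!r}...")
    return arr == ord("1")


def parse_hex(text: str, n_bits: int | None = None) -> np.ndarray:
    """Hex fingerprint, 4 bits per character, most-significant bit first.

    ``n_bits`` trims trailing pad bits when the true width is not a
    multiple of 4 (e.g. 881-bit keys encoded in 221 hex characters).
    """
    text = text.strip()
    try:
        nibbles = [int(c, 16) for c in text]
    except ValueError as exc:
        raise UniverseError(f"invalid hex fingerprint {text[:20]!r}...") from exc
    bits = np.zeros(4 * len(nibbles), dtype=bool)
    for i, nib in enumerate(nibbles):
        for j in range(4):
            bits[4 * i + j] = bool((nib >> (3 - j)) & 1)
    if n_bits is not None:
        if n_bits > bits.size:
            raise UniverseError(f"hex fingerprint shorter than {n_bits} bits")
        bits = bits[:n_bits]
    return bits


def smiles_fingerprinter(n_bits: int = DEFAULT_BIT_LENGTH) -> Callable[[str], np.ndarray]:
    """Return a SMILES -> bit-vector function backed by RDKit.

    RDKit is imported lazily so the core package carries no chemistry
    dependency; any callable with the same signature may be used instead.
    """
    from rdkit import Chem  # noqa: PLC0415
    from rdkit.Chem import rdFingerprintGenerator  # noqa: PLC0415

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)

    def fingerprint(smiles: str) -> np.ndarray:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise UniverseError(f"unparsable SMILES {smiles!r}")
        fp = gen.GetFingerprint(mol)
        return np.array(fp, dtype=bool)

    return fingerprint


# ---------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------

def _read_tsv(path: str, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise UniverseError(f"{path}: cannot parse as TSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise UniverseError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        for col, value in zip(df.columns, row):
            if col in columns and value == "":
                raise UniverseError(f"{path}: line {row_idx}: empty {col!r} field")
    return df


def _resolve_paths(paths: Mapping[str, str] | str | os.PathLike) -> dict[str, str]:
    if isinstance(paths, (str, os.PathLike)):
        base = os.fspath(paths)
        return {k: os.path.join(base, v) for k, v in FILE_NAMES.items()}
    return dict(paths)


def load_universe(
    paths: Mapping[str, str] | str | os.PathLike,
    fingerprint_dialect: str = "bitstring",
    n_bits: int | None = None,
    fingerprinter: Callable[[str], np.ndarray] | None = None,
) -> AssociationUniverse:
    """Load and validate an :class:`AssociationUniverse` from TSV files.

    ``paths`` is either a directory containing the canonical file names
    (``drugs.tsv``, ``drug_protein.tsv``, ``drug_gene_pg.tsv``,
    ``ppi.tsv``, ``ddi.tsv``) or a mapping from layer name to path.  Only
    the drugs file is mandatory; absent layers load as empty.

    ``fingerprint_dialect`` selects how the structure column of
    ``drugs.tsv`` is interpreted: a 0/1 ``bitstring``, a ``hex`` string
    (``n_bits`` trims hex padding), or ``smiles`` rendered to bits by
    ``fingerprinter`` (default: an RDKit Morgan fingerprint of width
    ``n_bits`` or 881).
    """
    if fingerprint_dialect not in ("bitstring", "hex", "smiles"):
        raise UniverseError(f"unknown fingerprint dialect {fingerprint_dialect!r}")
    path_map = _resolve_paths(paths)
    drugs_path = path_map.get("drugs")
    if drugs_path is None or not os.path.exists(drugs_path):
        raise UniverseError(f"drugs file not found: {drugs_path!r}")

    if fingerprint_dialect == "smiles":
        fp_col = "smiles"
        if fingerprinter is None:
            fingerprinter = smiles_fingerprinter(n_bits or DEFAULT_BIT_LENGTH)
    else:
        fp_col = "fingerprint"

    df = _read_tsv(drugs_path, ["drug_id", fp_col])
    drugs: dict[str, Drug] = {}
    for row_idx, (drug_id, raw) in enumerate(
        zip(df["drug_id"], df[fp_col]), start=2
    ):
        if drug_id in drugs:
            raise UniverseError(f"{drugs_path}: line {row_idx}: duplicate drug_id {drug_id!r}")
        if fingerprint_dialect == "bitstring":
            fp = parse_bitstring(raw)
        elif fingerprint_dialect == "hex":
            fp = parse_hex(raw, n_bits=n_bits)
        else:
            fp = fingerprinter(raw)
        try:
            drugs[drug_id] = Drug(drug_id, fp)
        except UniverseError as exc:
            raise UniverseError(f"{drugs_path}: line {row_idx}: {exc}") from exc

    def load_layer(name: str, columns: list[str]) -> list[tuple[str, ...]]:
        path = path_map.get(name)
        if path is None or not os.path.exists(path):
            return []
        layer_df = _read_tsv(path, columns)
        return [tuple(row) for row in layer_df[columns].itertuples(index=False)]

    dp_rows = load_layer("drug_protein", ["drug_id", "protein_id", "role"])
    for row_idx, (_d, _p, role) in enumerate(dp_rows, start=2):
        if role not in ROLES:
            raise UniverseError(
                f"{path_map['drug_protein']}: line {row_idx}: "
                f"unknown role {role!r} (expected one of {ROLES})"
            )
    drug_protein = set(dp_rows)

    pg_rows = load_layer("drug_gene_pg", ["drug_id", "gene_id"])
    drug_gene_pg = set(pg_rows)
    ppi_rows = load_layer("ppi", ["protein_id_a", "protein_id_b"])
    ddi_rows = load_layer("ddi", ["drug_id_a", "drug_id_b"])
    ppi = {canonical_pair(a, b) for a, b in ppi_rows if a != b}
    ddi = {canonical_pair(a, b) for a, b in ddi_rows if a != b}
    if any(a == b for a, b in ppi_rows):
        raise UniverseError("ppi: self-loop rows are not allowed")
    if any(a == b for a, b in ddi_rows):
        raise UniverseError("ddi: self-pair rows are not allowed")

    for name, raw_rows, kept in (
        ("drug_protein", dp_rows, drug_protein),
        ("drug_gene_pg", pg_rows, drug_gene_pg),
        ("ppi", ppi_rows, ppi),
        ("ddi", ddi_rows, ddi),
    ):
        dupes = len(raw_rows) - len(kept)
        if dupes:
            logger.info("%s: collapsed %d duplicate edge(s)", name, dupes)

    universe = AssociationUniverse(
        drugs=drugs,
        drug_protein=drug_protein,
        drug_gene_pg=drug_gene_pg,
        ppi=ppi,
        ddi=ddi,
    )
    logger.info(
        "loaded universe: %d drugs, %d drug-protein, %d pharmacogenetic, %d PPI, %d DDI",
        len(drugs), len(drug_protein), len(drug_gene_pg), len(ppi), len(ddi),
    )
    return universe


# ---------------------------------------------------------------------
# writing (round-trip and CLI output)
# ---------------------------------------------------------------------

def format_bitstring(fp: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in np.asarray(fp, dtype=bool))


def write_universe(universe: AssociationUniverse, directory: str | os.PathLike) -> dict[str, str]:
    """Write the five layer TSVs; rows sorted for byte-reproducibility."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {k: os.path.join(directory, v) for k, v in FILE_NAMES.items()}

    def dump(path: str, header: list[str], rows: Iterable[tuple[str, ...]]) -> None:
        buf = io.StringIO()
        buf.write("\t".join(header) + "\n")
        for row in sorted(rows):
            buf.write("\t".join(row) + "\n")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(buf.getvalue())

    dump(
        paths["drugs"],
        ["drug_id", "fingerprint"],
        ((d, format_bitstring(universe.drugs[d].fingerprint)) for d in universe.drug_ids()),
    )
    dump(paths["drug_protein"], ["drug_id", "protein_id", "role"], universe.drug_protein)
    dump(paths["drug_gene_pg"], ["drug_id", "gene_id"], universe.drug_gene_pg)
    dump(paths["ppi"], ["protein_id_a", "protein_id_b"], universe.ppi)
    dump(paths["ddi"], ["drug_id_a", "drug_id_b"], universe.ddi)
    return paths


# ---------------------------------------------------------------------
# pair labelling
# ---------------------------------------------------------------------

def label_pairs(
    universe: AssociationUniverse,
    restrict: str = "all",
) -> pd.DataFrame:
    """Label every unordered drug pair: 1 if a known DDI, else 0.

    ``restrict='annotated'`` keeps only pairs where at least one member
    carries a DDI annotation, mirroring a query set of DDI-annotated drugs
    scored against the full fingerprinted drug set; ``'all'`` keeps every
    pair.  Self-pairs are never emitted.
    """
    if restrict not in ("all", "annotated"):
        raise ValueError(f"unknown restrict policy {restrict!r}")
    ids = universe.drug_ids()
    n = len(ids)
    ia, ib = np.triu_indices(n, k=1)
    drug_a = np.array(ids, dtype=object)[ia]
    drug_b = np.array(ids, dtype=object)[ib]
    df = pd.DataFrame({"drug_a": drug_a, "drug_b": drug_b})
    if restrict == "annotated":
        annotated = universe.ddi_annotated_drugs()
        keep = df["drug_a"].isin(annotated) | df["drug_b"].isin(annotated)
        df = df.loc[keep].reset_index(drop=True)
    pair_keys = set(universe.ddi)
    labels = [
        1 if (a, b) in pair_keys else 0
        for a, b in zip(df["drug_a"], df["drug_b"])
    ]
    df["label"] = np.array(labels, dtype=np.int64)
    return df
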