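"""Synthetic association universes with planted ground truth.

The generator emulates the statistical structure the scoring method
assumes rather than any real chemistry:

1. *Scaffolds.* A small number of prototype bit vectors play the role
   of chemical scaffolds; each drug is a prototype with independent
   per-bit flips, so drugs of one scaffold are structurally similar
   (within-scaffold Tanimoto well above between-scaffold Tanimoto
   whenever the flip rate is below one half).
2. *Mechanism realism.* Every protein (enzyme, transporter, target, or
   PPI neighbour of a target) has a home scaffold — assigned round-robin
   so each scaffold is covered by every layer — and attaches to drugs
   of that scaffold with the layer's edge density, and to other drugs
   at a strongly reduced rate — similar drugs hit the same proteins.
   A fraction of proteins (``promiscuity``) additionally serve a second,
   random scaffold: such proteins bridge structurally unrelated drug
   families, the mechanism by which a query drug can interact with an
   examined drug it does not resemble.  Which families a protein
   bridges varies independently across layers, so no single score type
   sees every mechanism.
3. *PPI and pharmacogenetics.* Dedicated neighbour proteins link to
   targets at ``ppi_density``, preferentially within the same scaffold
   neighbourhood (pathway coherence), grounding the one-hop
   pharmacodynamic expansion; pharmacogenetic drug-gene edges attach to
   every protein at ``pg_rate`` with the same scaffold preference.
4. *Labels.* For every ordered pair the seven network-similarity scores
   are computed with the real scoring engine and the interaction
   probability is the logistic function of a planted linear score
   combination (sentinels entering as the literal −10).  DDI labels are
   unordered, so the pair probability is the mean of its two
   orientations and the universe's DDI label is a Bernoulli draw from
   it.  The truth table additionally records a per-orientation
   Bernoulli draw (``row_label``) from the ordered probability itself:
   the unordered projection discards which orientation carries the
   mechanism, so coefficient-recovery checks — which probe the
   estimator, not the label projection — are made against the ordered
   draws, the model's exact generative frame.

The emitted truth table doubles as the exact feature table of the
universe, so recovery tests can compare fitted coefficients against
the planted ones directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .model import FittedModel
from .scoring import SCORE_NAMES, ScoreEngine
from .store import AssociationUniverse, Drug

TRUTH_COLUMNS = [
    "dq_id", "de_id", *SCORE_NAMES, "s_max",
    "p_ordered", "p_pair", "label", "row_label",
]

#: planted log-odds coefficients: strong pharmacokinetic (s_e, s_tr) and
#: pharmacodynamic (s_ta) network effects, a modest direct-similarity
#: effect, weak pharmacogenetic effects, and a deep intercept so that
#: unrelated drug pairs rarely interact.
DEFAULT_TRUE_BETAS = {
    "intercept": -15.5,
    "s_d": 2.0,
    "s_e": 8.0,
    "s_eg": 1.2,
    "s_tr": 6.8,
    "s_trg": 1.0,
    "s_ta": 8.0,
    "s_tag": 1.2,
}

DEFAULT_EDGE_DENSITY = {"enzyme": 0.75, "transporter": 0.70, "target": 0.70}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic universe; defaults give a dense regime."""

    n_drugs: int = 300
    n_enzymes: int = 30
    n_transporters: int = 20
    n_targets: int = 20
    n_ppi_neighbors: int | None = None  # defaults to n_targets
    n_scaffolds: int = 15
    bit_length: int = 881
    prototype_density: float = 0.30
    flip_rate: float = 0.08
    edge_density: dict = field(default_factory=lambda: dict(DEFAULT_EDGE_DENSITY))
    cross_scaffold_factor: float = 0.01
    promiscuity: float = 0.5
    ppi_density: float = 0.25
    pg_rate: float = 0.08
    true_betas: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETAS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.flip_rate < 0.5):
            raise ValueError("flip_rate must lie in [0, 0.5) to keep scaffolds coherent")
        densities = {
            "prototype_density": self.prototype_density,
            "ppi_density": self.ppi_density,
            "pg_rate": self.pg_rate,
            "cross_scaffold_factor": self.cross_scaffold_factor,
            "promiscuity": self.promiscuity,
            **{f"edge_density.{k}": v for k, v in self.edge_density.items()},
        }
        for name, value in densities.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} outside [0, 1]")
        unknown = set(self.edge_density) - {"enzyme", "transporter", "target"}
        if unknown:
            raise ValueError(f"unknown edge_density layers {sorted(unknown)}")
        unknown_b = set(self.true_betas) - {"intercept", *SCORE_NAMES}
        if unknown_b:
            raise ValueError(f"unknown true_betas entries {sorted(unknown_b)}")

    @property
    def resolved_ppi_neighbors(self) -> int:
        return self.n_targets if self.n_ppi_neighbors is None else self.n_ppi_neighbors

    # -- flat key=value config files (CLI) -----------------------------
    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "GeneratorConfig":
        kwargs: dict = {}
        edge_density = dict(DEFAULT_EDGE_DENSITY)
        true_betas = dict(DEFAULT_TRUE_BETAS)
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: line {line_no}: expected key=value")
                key, value = (part.strip() for part in line.split("=", 1))
                if key.startswith("edge_density."):
                    edge_density[key.split(".", 1)[1]] = float(value)
                elif key.startswith("true_betas."):
                    true_betas[key.split(".", 1)[1]] = float(value)
                elif key in (
                    "n_drugs", "n_enzymes", "n_transporters", "n_targets",
                    "n_ppi_neighbors", "n_scaffolds", "bit_length", "seed",
                ):
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = float(value)
        return cls(edge_density=edge_density, true_betas=true_betas, **kwargs)


def preset(name: str, **overrides) -> GeneratorConfig:
    """Named generator regimes: ``dense`` (few sentinels) or ``sparse``."""
    if name == "dense":
        cfg = GeneratorConfig()
    elif name == "sparse":
        cfg = GeneratorConfig(
            edge_density={"enzyme": 0.35, "transporter": 0.25, "target": 0.30},
            ppi_density=0.10,
            pg_rate=0.15,
        )
    else:
        raise ValueError(f"unknown preset {name!r} (expected 'dense' or 'sparse')")
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SyntheticUniverse:
    """A generated universe plus its exact generative ground truth."""

    universe: AssociationUniverse
    truth: pd.DataFrame  # one row per ordered pair, TRUTH_COLUMNS
    config: GeneratorConfig

    @property
    def planted_betas(self) -> dict[str, float]:
        return dict(self.config.true_betas)


def _drug_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"D{i + 1:0{width}d}" for i in range(n)]


def _protein_ids(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate(config: GeneratorConfig) -> SyntheticUniverse:
    """Generate a synthetic universe; deterministic under ``config.seed``."""
    seed = config.seed
    rng_fp = np.random.default_rng(derive_seed(seed, "fingerprints"))
    rng_edges = np.random.default_rng(derive_seed(seed, "edges"))
    rng_labels = np.random.default_rng(derive_seed(seed, "labels"))

    n = config.n_drugs
    ids = _drug_ids(n)
    scaffold_of = np.arange(n) % config.n_scaffolds

    prototypes = rng_fp.random((config.n_scaffolds, config.bit_length)) < config.prototype_density
    for s in range(config.n_scaffolds):
        if not prototypes[s].any():
            prototypes[s, s % config.bit_length] = True
    flips = rng_fp.random((n, config.bit_length)) < config.flip_rate
    fingerprints = prototypes[scaffold_of] ^ flips
    for i in range(n):
        if not fingerprints[i].any():
            fingerprints[i, i % config.bit_length] = True

    drugs = {d: Drug(d, fingerprints[i]) for i, d in enumerate(ids)}

    enzymes = _protein_ids("E", config.n_enzymes)
    transporters = _protein_ids("Tr", config.n_transporters)
    targets = _protein_ids("T", config.n_targets)
    neighbors = _protein_ids("P", config.resolved_ppi_neighbors)

    def protein_scaffolds(proteins: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Primary home (round-robin: every scaffold covered) and, for a
        ``promiscuity`` fraction of proteins, a second random scaffold."""
        m = len(proteins)
        primary = np.arange(m) % config.n_scaffolds
        secondary = np.full(m, -1, dtype=np.int64)
        promiscuous = rng_edges.random(m) < config.promiscuity
        offsets = rng_edges.integers(1, max(config.n_scaffolds, 2), size=m)
        secondary[promiscuous] = (primary + offsets)[promiscuous] % config.n_scaffolds
        return primary, secondary

    def _serve_prob(homes: tuple[np.ndarray, np.ndarray], k: int, density: float):
        primary, secondary = homes
        served = (scaffold_of == primary[k]) | (scaffold_of == secondary[k])
        return np.where(served, density, density * config.cross_scaffold_factor)

    def attach(proteins: list[str], homes, density: float, role: str):
        edges = set()
        for k, p in enumerate(proteins):
            hits = rng_edges.random(n) < _serve_prob(homes, k, density)
            for i in np.flatnonzero(hits):
                edges.add((ids[i], p, role))
        return edges

    def attach_pg(proteins: list[str], homes):
        # pharmacogenetic associations are structurally diffuse: only a
        # weak scaffold preference, unlike physical drug-protein edges
        primary, secondary = homes
        edges = set()
        for k, p in enumerate(proteins):
            served = (scaffold_of == primary[k]) | (scaffold_of == secondary[k])
            prob = np.where(served, min(3.0 * config.pg_rate, 1.0), config.pg_rate)
            hits = rng_edges.random(n) < prob
            for i in np.flatnonzero(hits):
                edges.add((ids[i], p))
        return edges

    homes = {
        "enzyme": protein_scaffolds(enzymes),
        "transporter": protein_scaffolds(transporters),
        "target": protein_scaffolds(targets),
        "neighbor": protein_scaffolds(neighbors),
    }
    drug_protein = set()
    drug_protein |= attach(enzymes, homes["enzyme"], config.edge_density["enzyme"], "enzyme")
    drug_protein |= attach(
        transporters, homes["transporter"], config.edge_density["transporter"], "transporter"
    )
    drug_protein |= attach(targets, homes["target"], config.edge_density["target"], "target")
    drug_protein |= attach(neighbors, homes["neighbor"], config.edge_density["target"], "target")

    ppi = set()
    neighbor_primary = homes["neighbor"][0]
    for t, t_home in zip(targets, homes["target"][0]):
        # pathway coherence: PPI partners mostly share the scaffold family
        prob = np.where(
            neighbor_primary == t_home,
            config.ppi_density,
            config.ppi_density * config.cross_scaffold_factor,
        )
        hits = rng_edges.random(len(neighbors)) < prob
        for j in np.flatnonzero(hits):
            a, b = sorted((t, neighbors[j]))
            ppi.add((a, b))

    drug_gene_pg = set()
    for proteins, home in (
        (enzymes, homes["enzyme"]),
        (transporters, homes["transporter"]),
        (targets, homes["target"]),
        (neighbors, homes["neighbor"]),
    ):
        drug_gene_pg |= attach_pg(proteins, home)

    bare = AssociationUniverse(
        drugs=drugs,
        drug_protein=drug_protein,
        drug_gene_pg=drug_gene_pg,
        ppi=ppi,
        ddi=set(),
    )

    # scores for every ordered pair, via the real scoring engine
    engine = ScoreEngine(bare)
    order = engine.ids  # sorted == generation order for zero-padded ids
    beta0 = float(config.true_betas.get("intercept", 0.0))
    beta = np.array([config.true_betas.get(s, 0.0) for s in SCORE_NAMES])

    prob = np.empty((n, n))  # prob[dq, de]
    score_blocks = np.empty((n, n, len(SCORE_NAMES)))
    for j, de in enumerate(order):
        block = engine.scores_for_de(de)
        score_blocks[:, j, :] = block
        prob[:, j] = 1.0 / (1.0 + np.exp(-(beta0 + block @ beta)))

    pair_prob = 0.5 * (prob + prob.T)
    rng_rows = np.random.default_rng(derive_seed(seed, "row-labels"))
    row_label_mat = (rng_rows.random((n, n)) < prob).astype(np.int64)
    draws = rng_labels.random((n, n))
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    label_mat = np.zeros((n, n), dtype=np.int64)
    label_mat[upper] = (draws[upper] < pair_prob[upper]).astype(np.int64)
    label_mat = label_mat + label_mat.T

    ddi = {
        (order[i], order[j])
        for i, j in zip(*np.nonzero(np.triu(label_mat, k=1)))
    }
    if not ddi and n >= 100:
        raise ValueError(
            "no DDI-positive pairs were generated; raise true_betas/intercept "
            "or edge densities"
        )

    universe = AssociationUniverse(
        drugs=drugs,
        drug_protein=drug_protein,
        drug_gene_pg=drug_gene_pg,
        ppi=ppi,
        ddi=ddi,
    )

    off_diag = ~np.eye(n, dtype=bool)
    dq_idx, de_idx = np.nonzero(off_diag)
    truth = pd.DataFrame(
        {
            "dq_id": np.array(order, dtype=object)[dq_idx],
            "de_id": np.array(order, dtype=object)[de_idx],
            **{
                name: score_blocks[dq_idx, de_idx, k]
                for k, name in enumerate(SCORE_NAMES)
            },
        }
    )
    truth["s_max"] = score_blocks[dq_idx, de_idx, :].max(axis=1)
    truth["p_ordered"] = prob[dq_idx, de_idx]
    truth["p_pair"] = pair_prob[dq_idx, de_idx]
    truth["label"] = label_mat[dq_idx, de_idx]
    truth["row_label"] = row_label_mat[dq_idx, de_idx]
    return SyntheticUniverse(universe=universe, truth=truth, config=config)


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.12g")


def recovery_report(synthetic: SyntheticUniverse, fitted: FittedModel) -> pd.DataFrame:
    """Compare fitted coefficients with the planted generative ones.

    The comparison is made on the raw score scale: each fitted
    (standardized-space) coefficient is divided by the stored column
    scale.  Rows carry the planted value, the estimate, its standard
    error, the relative error and sign agreement.  The intercept row is
    reported but flagged non-comparable whenever the model was fitted
    on an outcome-dependent (balanced) sample, which shifts it.
    """
    if tuple(fitted.members) != SCORE_NAMES:
        raise ValueError(
            f"recovery needs the full seven-score model; got {fitted.members}"
        )
    planted = synthetic.planted_betas
    raw_betas = fitted.raw_scale_betas()
    if fitted.standard_errors is not None:
        raw_ses = fitted.standard_errors[1:] / fitted.stats.scales
        intercept_se = float(fitted.standard_errors[0])
    else:
        raw_ses = np.full(len(SCORE_NAMES), np.nan)
        intercept_se = np.nan

    rows = [
        {
            "term": "intercept",
            "planted": planted.get("intercept", 0.0),
            "estimate": fitted.raw_scale_intercept(),
            "se": intercept_se,
            "comparable": False,
        }
    ]
    for k, name in enumerate(SCORE_NAMES):
        true_val = planted.get(name, 0.0)
        est = float(raw_betas[k])
        rows.append(
            {
                "term": name,
                "planted": true_val,
                "estimate": est,
                "se": float(raw_ses[k]),
                "comparable": True,
                "sign_match": bool(np.sign(est) == np.sign(true_val))
                if true_val != 0.0
                else bool(abs(est) <= 3.0 * raw_ses[k]),
                "rel_error": abs(est - true_val) / abs(true_val)
                if true_val != 0.0
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
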