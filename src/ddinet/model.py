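"""Logistic-regression DDI models over score sets.

A *score set* is a named subset of the eight feature columns (the seven
network-similarity scores plus the whole-network maximum ``s_max``)
entering a logistic regression

    P(DDI) = F(t) = 1 / (1 + exp(-t)),    t = b0 + b1*s1 + ... + bn*sn,

fitted on standardized scores (centered to mean 0, scaled to sample
standard deviation 1, with the −10 sentinels treated as ordinary
numbers).  The 21 built-in sets span direct structural similarity (DR),
pharmacokinetic information from enzymes (PKe) and transporters (PKtr),
pharmacodynamic target information (PD), and their combinations, with
and without pharmacogenetic ("g") scores.

Fitting maximizes the binomial log-likelihood by iteratively reweighted
least squares (IRLS, Newton–Raphson): zero-initialized coefficients,
convergence when the log-likelihood improves by less than 1e-8, at most
100 iterations.  Perfectly separated data (common on tiny inputs) are
handled by capping coefficient magnitudes at 30 with a warning rather
than failing.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import SCORE_NAMES, ScoreEngine, score_matrix
from .store import AssociationUniverse, label_pairs

FEATURES = (*SCORE_NAMES, "s_max")

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
BETA_CAP = 30.0


@dataclass(frozen=True)
class ScoreSet:
    """A named, ordered subset of score columns used as model features."""

    set_id: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.set_id}: empty score set")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"{self.set_id}: duplicate members")
        unknown = [m for m in self.members if m not in FEATURES]
        if unknown:
            raise ValueError(f"{self.set_id}: unknown score columns {unknown}")


def _builtin_sets() -> dict[str, ScoreSet]:
    raw = {
        "Set1": (("s_d", "s_e", "s_eg", "s_tr", "s_trg", "s_ta", "s_tag"), "DR + PK + PD"),
        "Set2": (("s_e", "s_tr", "s_ta"), "(PK + PD)_nog"),
        "Set3": (("s_e", "s_eg", "s_tr", "s_trg", "s_ta", "s_tag"), "PK + PD"),
        "Set4": (("s_d", "s_e", "s_tr", "s_ta"), "DR + (PK + PD)_nog"),
        "Set5": (("s_d", "s_e", "s_eg", "s_ta", "s_tag"), "DR + PKe + PD"),
        "Set6": (("s_e", "s_eg", "s_ta", "s_tag"), "PKe + PD"),
        "Set7": (("s_max",), "maximum score in the whole network"),
        "Set8": (("s_tr", "s_trg", "s_ta", "s_tag"), "PKtr + PD"),
        "Set9": (("s_d", "s_tr", "s_trg", "s_ta", "s_tag"), "DR + PKtr + PD"),
        "Set10": (("s_d", "s_e", "s_eg", "s_tr", "s_trg"), "DR + PK"),
        "Set11": (("s_e", "s_eg", "s_tr", "s_trg"), "PK"),
        "Set12": (("s_d", "s_tr", "s_trg"), "DR + PKtr"),
        "Set13": (("s_tr", "s_trg"), "PKtr"),
        "Set14": (("s_ta", "s_tag"), "PD"),
        "Set15": (("s_ta",), "PD_nog"),
        "Set16": (("s_d", "s_e", "s_eg"), "DR + PKe"),
        "Set17": (("s_d", "s_ta", "s_tag"), "DR + PD"),
        "Set18": (("s_tr",), "PKtr_nog"),
        "Set19": (("s_d",), "DR"),
        "Set20": (("s_e", "s_eg"), "PKe"),
        "Set21": (("s_e",), "PKe_nog"),
    }
    return {sid: ScoreSet(sid, members, desc) for sid, (members, desc) in raw.items()}


SCORE_SETS: dict[str, ScoreSet] = _builtin_sets()


def get_score_set(set_id: str | ScoreSet) -> ScoreSet:
    if isinstance(set_id, ScoreSet):
        return set_id
    try:
        return SCORE_SETS[set_id]
    except KeyError:
        raise KeyError(
            f"unknown score set {set_id!r}; built-ins are Set1..Set21"
        ) from None


# ---------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessStats:
    """Per-column center (mean) and scale (sample standard deviation)."""

    members: tuple[str, ...]
    centers: np.ndarray
    scales: np.ndarray


def preprocess(
    table: pd.DataFrame,
    members: tuple[str, ...] | list[str],
    stats: PreprocessStats | None = None,
) -> tuple[np.ndarray, PreprocessStats]:
    """Center and scale the member columns of a feature table.

    At fit time (``stats is None``) the statistics are computed from the
    given rows with the sample (n−1) standard-deviation convention; at
    prediction time the stored statistics are applied unchanged.
    Sentinel values standardize like any number.
    """
    members = tuple(members)
    missing = [m for m in members if m not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    X = table.loc[:, list(members)].to_numpy(dtype=float)
    if stats is None:
        centers = X.mean(axis=0)
        scales = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        for j, m in enumerate(members):
            if not np.isfinite(scales[j]) or scales[j] <= 0.0:
                raise ValueError(f"zero-variance column {m!r} at fit time")
        stats = PreprocessStats(members, centers, scales)
    else:
        if tuple(stats.members) != members:
            raise ValueError("stored statistics cover different columns")
    return (X - stats.centers) / stats.scales, stats


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------

class SeparationWarning(UserWarning):
    """Signal that the likelihood is unbounded (perfect separation)."""


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class FittedModel:
    """One fitted logistic model: coefficients plus preprocessing stats."""

    set_id: str
    members: tuple[str, ...]
    beta0: float
    betas: np.ndarray
    stats: PreprocessStats
    standard_errors: np.ndarray | None = None
    log_likelihood: float = np.nan
    n_iter: int = 0
    n_obs: int = 0
    separated: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        X, _ = preprocess(table, self.members, self.stats)
        return self.beta0 + X @ self.betas

    def raw_scale_betas(self) -> np.ndarray:
        """Coefficients mapped back to the unstandardized score scale."""
        return self.betas / self.stats.scales

    def raw_scale_intercept(self) -> float:
        """Intercept on the unstandardized score scale."""
        return float(
            self.beta0 - np.sum(self.betas * self.stats.centers / self.stats.scales)
        )


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+e^eta) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    members: tuple[str, ...],
    stats: PreprocessStats,
    set_id: str = "custom",
) -> FittedModel:
    """Fit a logistic regression by IRLS on standardized features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("feature matrix and labels are misaligned")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or classes.size < 2:
        raise ValueError("labels must contain both classes 0 and 1")

    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    trace: list[float] = []
    separated = False
    ll_old = _loglik(y, design @ beta)
    n_iter = 0
    for n_iter in range(1, IRLS_MAX_ITER + 1):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        xtw = design.T * w
        hessian = xtw @ design
        gradient = design.T @ (y - mu)
        try:
            step = np.linalg.solve(hessian, gradient)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hessian, gradient, rcond=None)[0]
        beta = beta + step
        ll_new = _loglik(y, design @ beta)
        trace.append(ll_new)
        if np.abs(beta).max() > BETA_CAP:
            beta = np.clip(beta, -BETA_CAP, BETA_CAP)
            separated = True
            warnings.warn(
                "perfect or quasi-perfect separation: coefficients capped at "
                f"|beta| <= {BETA_CAP:g}",
                SeparationWarning,
                stacklevel=2,
            )
            ll_new = _loglik(y, design @ beta)
            break
        if abs(ll_new - ll_old) < IRLS_TOL:
            break
        ll_old = ll_new
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {IRLS_MAX_ITER} iterations", trace
        )

    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    fisher = (design.T * w) @ design
    try:
        cov = np.linalg.inv(fisher)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(p + 1, np.nan)

    return FittedModel(
        set_id=set_id,
        members=tuple(members),
        beta0=float(beta[0]),
        betas=beta[1:].copy(),
        stats=stats,
        standard_errors=ses,
        log_likelihood=_loglik(y, design @ beta),
        n_iter=n_iter,
        n_obs=n,
        separated=separated,
    )


def fit_score_set(
    features: pd.DataFrame,
    score_set: str | ScoreSet,
    label_column: str = "label",
) -> FittedModel:
    """Preprocess a feature table and fit the given score set's model."""
    sset = get_score_set(score_set)
    X, stats = preprocess(features, sset.members)
    y = features[label_column].to_numpy(dtype=float)
    return fit_logistic(X, y, sset.members, stats, set_id=sset.set_id)


def predict(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Interaction probabilities F(t) for the rows of a feature table."""
    eta = model.linear_predictor(table)
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------
# persistence (plain-text, diffable)
# ---------------------------------------------------------------------

def save_model(model: FittedModel, path: str | os.PathLike) -> None:
    lines = [
        f"set_id\t{model.set_id}",
        "members\t" + ",".join(model.members),
        f"intercept\t{model.beta0:.17g}",
    ]
    for kind, values in (
        ("beta", model.betas),
        ("center", model.stats.centers),
        ("scale", model.stats.scales),
    ):
        for m, v in zip(model.members, values):
            lines.append(f"{kind}\t{m}\t{v:.17g}")
    if model.standard_errors is not None:
        for name, v in zip(("intercept", *model.members), model.standard_errors):
            lines.append(f"se\t{name}\t{v:.17g}")
    lines.append(f"log_likelihood\t{model.log_likelihood:.17g}")
    lines.append(f"n_obs\t{model.n_obs}")
    lines.append(f"n_iter\t{model.n_iter}")
    lines.append(f"separated\t{int(model.separated)}")
    lines.append("sd_convention\tsample")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path: str | os.PathLike) -> FittedModel:
    entries: dict[str, str] = {}
    triples: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 2:
                entries[parts[0]] = parts[1]
            elif len(parts) == 3:
                triples.append(tuple(parts))
    members = tuple(entries["members"].split(","))
    by_kind: dict[str, dict[str, float]] = {}
    for kind, name, value in triples:
        by_kind.setdefault(kind, {})[name] = float(value)

    def vec(kind: str) -> np.ndarray:
        return np.array([by_kind[kind][m] for m in members])

    ses = None
    if "se" in by_kind:
        ses = np.array([by_kind["se"][n] for n in ("intercept", *members)])
    stats = PreprocessStats(members, vec("center"), vec("scale"))
    return FittedModel(
        set_id=entries["set_id"],
        members=members,
        beta0=float(entries["intercept"]),
        betas=vec("beta"),
        stats=stats,
        standard_errors=ses,
        log_likelihood=float(entries.get("log_likelihood", "nan")),
        n_iter=int(entries.get("n_iter", 0)),
        n_obs=int(entries.get("n_obs", 0)),
        separated=bool(int(entries.get("separated", "0"))),
    )


# ---------------------------------------------------------------------
# leave-one-drug-out case studies
# ---------------------------------------------------------------------

def leave_out_drug(
    universe: AssociationUniverse,
    drug_id: str,
    score_set: str | ScoreSet = "Set1",
    seed: int = 0,
    orientation: str = "both",
    restrict: str = "annotated",
    engine: ScoreEngine | None = None,
) -> FittedModel:
    """Fit a model on all data excluding every pair involving one drug.

    The training table is built exactly as in cross-validated
    evaluation: unordered pairs labeled against the DDI layer, balanced
    per query drug to a 1:1 DDI:non-DDI ratio, then scored under the
    orientation policy.  Excluding the drug leaves its candidate pairs
    untouched for honest case-study ranking.
    """
    from .evaluation import balanced_sample  # local import avoids a cycle

    if drug_id not in universe.drugs:
        raise KeyError(f"unknown drug {drug_id!r}")
    if engine is None:
        engine = ScoreEngine(universe)
    pairs = label_pairs(universe, restrict=restrict)
    keep = (pairs["drug_a"] != drug_id) & (pairs["drug_b"] != drug_id)
    pairs = pairs.loc[keep].reset_index(drop=True)
    balanced = balanced_sample(pairs, seed=seed)
    features = score_matrix(balanced, orientation=orientation, engine=engine)
    model = fit_score_set(features, score_set)
    model.metadata.update(
        left_out=drug_id, orientation=orientation, restrict=restrict, seed=seed
    )
    return model


def rank_candidates(
    model: FittedModel,
    universe: AssociationUniverse,
    drug_id: str,
    k: int = 10,
    orientation: str = "both",
    engine: ScoreEngine | None = None,
) -> pd.DataFrame:
    """Rank all partner candidates of one drug by predicted probability.

    Each candidate pair (drug, candidate) is scored under the
    orientation policy; when both orientations are evaluable their
    probabilities are averaged.  Candidates with no evaluable
    orientation (both networks empty) are dropped.  Ties are broken by
    ascending candidate id; the top-``k`` rows are returned together
    with the known-DDI flag for inspection.
    """
    if drug_id not in universe.drugs:
        raise KeyError(f"unknown drug {drug_id!r}")
    if engine is None:
        engine = ScoreEngine(universe)
    candidates = [d for d in universe.drug_ids() if d != drug_id]
    pairs = pd.DataFrame(
        {
            "drug_a": [drug_id] * len(candidates),
            "drug_b": candidates,
            "label": [0] * len(candidates),
        }
    )
    features = score_matrix(pairs, orientation=orientation, engine=engine)
    if features.empty:
        return pd.DataFrame(columns=["candidate", "probability", "known_ddi"])
    features = features.assign(probability=predict(model, features))
    features["candidate"] = np.where(
        features["dq_id"] == drug_id, features["de_id"], features["dq_id"]
    )
    agg = (
        features.groupby("candidate", as_index=False)["probability"].mean()
        .sort_values(["probability", "candidate"], ascending=[False, True])
        .reset_index(drop=True)
    )
    agg["known_ddi"] = [universe.has_ddi(drug_id, c) for c in agg["candidate"]]
    return agg.head(k).reset_index(drop=True)
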