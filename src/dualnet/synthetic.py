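"""Planted structural models for end-to-end testing and benchmarking.

A :class:`PlantedSEM` is a linear-Gaussian structural equation model over
a DAG: latent node values are ancestral-sampled in topological order
(child = sum of beta * parent + Gaussian noise), then mapped onto observed
scales — threshold ordinalization for categorical/ordinal/bounded-score
variables (clipping-free: every level is attainable by construction) and
monotone exponential warping for skewed measures.  The generating DAG is
returned alongside the data so structure recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CohortTable, VariableSchema
from .structure import Blacklist, DAGStructure

__all__ = [
    "PlantedSEM",
    "RecoveryReport",
    "sample_sem",
    "make_cohort20",
    "score_recovery",
]


@dataclass(frozen=True)
class ObservationMap:
    """How a latent standard-normal value becomes an observed one.

    ``kind``: 'identity' (affine: loc + scale*z), 'thresholds' (cut at
    strictly increasing z-thresholds, emit ``values[i]`` for bin i), or
    'lognormal' (exp(loc + scale*z), right-skewed).
    """

    kind: str = "identity"
    loc: float = 0.0
    scale: float = 1.0
    thresholds: tuple[float, ...] = ()
    values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "thresholds", "lognormal"):
            raise ValueError(f"unknown observation kind {self.kind!r}")
        if self.kind == "thresholds":
            t = np.asarray(self.thresholds)
            if len(t) and not np.all(np.diff(t) > 0):
                raise ValueError("thresholds must be strictly increasing")
            if len(self.values) != len(self.thresholds) + 1:
                raise ValueError("need len(thresholds) + 1 level values")

    def apply(self, z: np.ndarray) -> np.ndarray:
        if self.kind == "identity":
            return self.loc + self.scale * z
        if self.kind == "lognormal":
            return np.exp(self.loc + self.scale * z)
        bins = np.searchsorted(np.asarray(self.thresholds), z)
        return np.asarray(self.values, dtype=float)[bins]


def even_thresholds(n_levels: int) -> tuple[float, ...]:
    """Equiprobable z-thresholds for `n_levels` ordered categories."""
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    qs = np.arange(1, n_levels) / n_levels
    return tuple(stats.norm.ppf(qs))


def score_thresholds(n_levels: int, span: float = 2.8) -> tuple[float, ...]:
    """Equally spaced z-thresholds over [-span, span]: bell-shaped level
    frequencies, suitable for integer questionnaire totals."""
    return tuple(np.linspace(-span, span, n_levels - 1))


@dataclass
class PlantedSEM:
    """A planted DAG with standardized arc coefficients and per-node
    noise SDs chosen so every latent variable has (near) unit variance."""

    dag: DAGStructure
    coefficients: dict = field(default_factory=dict)   # (u, v) -> beta
    noise_sd: dict = field(default_factory=dict)       # node -> sigma
    observation: dict = field(default_factory=dict)    # node -> ObservationMap
    schema: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.dag.is_acyclic():
            raise ValueError("planted dag must be acyclic")
        missing = self.dag.arcs - set(self.coefficients)
        if missing:
            raise ValueError(f"arcs without coefficients: {sorted(missing)}")

    def standardize_noise(self) -> None:
        """Set noise SDs so every latent node has unit marginal variance
        (floored at 0.3 when parent effects already explain most of it)."""
        order = self.dag.topological_order()
        assert order is not None
        idx = {v: i for i, v in enumerate(order)}
        p = len(order)
        cov = np.zeros((p, p))
        for v in order:
            i = idx[v]
            ps = sorted(self.dag.parents(v))
            if ps:
                pi = [idx[u] for u in ps]
                beta = np.array([self.coefficients[(u, v)] for u in ps])
                explained = float(beta @ cov[np.ix_(pi, pi)] @ beta)
                sigma2 = max(1.0 - explained, 0.09)
                self.noise_sd[v] = float(np.sqrt(sigma2))
                cov[i, :] = cov[:, i] = (beta[None, :] @ cov[pi, :]).ravel()
                cov[i, i] = explained + sigma2
            else:
                self.noise_sd.setdefault(v, 1.0)
                cov[i, i] = self.noise_sd[v] ** 2


def sample_sem(model: PlantedSEM, n: int, seed: int | np.random.Generator = 0) -> CohortTable:
    """Ancestral sampling of `n` rows; deterministic given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = model.dag.topological_order()
    if order is None:
        raise ValueError("cyclic dag")
    latent: dict[str, np.ndarray] = {}
    for v in order:
        val = rng.normal(0.0, model.noise_sd.get(v, 1.0), size=n)
        for u in sorted(model.dag.parents(v)):
            val = val + model.coefficients[(u, v)] * latent[u]
        latent[v] = val
    names = [s.name for s in model.schema] if model.schema else list(model.dag.nodes)
    cols = {}
    for name in names:
        obs = model.observation.get(name, ObservationMap())
        cols[name] = obs.apply(latent[name])
    schema = model.schema or [VariableSchema(name=v) for v in model.dag.nodes]
    return CohortTable(pd.DataFrame(cols), schema)


# ---------------------------------------------------------------------------
# 20-variable cohort-like preset


def _cohort20_model() -> PlantedSEM:
    schema = [
        VariableSchema("age", "continuous", blacklist_sink_forbidden=True),
        VariableSchema("gender", "categorical", ordinal_levels=("women", "men"),
                       discretization_exempt=True, blacklist_sink_forbidden=True),
        VariableSchema("education", "ordinal",
                       ordinal_levels=tuple(str(i) for i in range(1, 6)),
                       discretization_exempt=True, blacklist_sink_forbidden=True),
        VariableSchema("marital_status", "ordinal",
                       ordinal_levels=tuple(str(i) for i in range(1, 8)),
                       discretization_exempt=True),
        VariableSchema("irsad_decile", "ordinal",
                       ordinal_levels=tuple(str(i) for i in range(1, 11)),
                       discretization_exempt=True),
        VariableSchema("recent_stressors", "continuous", admissible_range=(0, 10),
                       blacklist_sink_forbidden=True),
        VariableSchema("chronic_stress", "continuous", admissible_range=(0, 36)),
        VariableSchema("perceived_stress", "continuous", admissible_range=(0, 40)),
        VariableSchema("anxiety", "continuous", admissible_range=(0, 21)),
        VariableSchema("depression", "continuous", admissible_range=(0, 21)),
        VariableSchema("resilient_coping", "continuous", admissible_range=(4, 20)),
        VariableSchema("social_support", "continuous", admissible_range=(0, 90)),
        VariableSchema("cognitive_activity", "continuous", admissible_range=(0, 55)),
        VariableSchema("physical_activity", "continuous", admissible_range=(1, 15000)),
        VariableSchema("bmi", "continuous", admissible_range=(13, 90)),
        VariableSchema("mind_diet", "continuous", admissible_range=(0, 14)),
        VariableSchema("alcohol", "continuous", admissible_range=(0, 69)),
        VariableSchema("blood_pressure", "continuous", admissible_range=(0, 8)),
        VariableSchema("cholesterol", "continuous", admissible_range=(0, 8)),
        VariableSchema("diabetes", "continuous", admissible_range=(0, 8)),
    ]
    arcs = {
        ("recent_stressors", "chronic_stress"): 0.70,
        ("age", "chronic_stress"): 0.60,
        ("chronic_stress", "perceived_stress"): 0.75,
        ("perceived_stress", "anxiety"): 0.75,
        ("anxiety", "depression"): 0.75,
        ("depression", "social_support"): -0.65,
        ("cognitive_activity", "social_support"): 0.55,
        ("resilient_coping", "cognitive_activity"): 0.70,
        ("education", "cognitive_activity"): 0.65,
        ("social_support", "physical_activity"): 0.70,
        ("physical_activity", "bmi"): -0.65,
        ("bmi", "blood_pressure"): 0.70,
        ("cholesterol", "blood_pressure"): 0.50,
        ("cholesterol", "diabetes"): 0.65,
        ("gender", "alcohol"): 0.80,
        ("gender", "mind_diet"): -0.70,
        ("physical_activity", "mind_diet"): 0.50,
        ("education", "irsad_decile"): 0.75,
        ("age", "marital_status"): 0.65,
    }
    nodes = [s.name for s in schema]
    dag = DAGStructure(nodes, set(arcs))
    obs = {
        "age": ObservationMap("identity", loc=66.0, scale=7.5),
        "gender": ObservationMap("thresholds", thresholds=(0.6,), values=(1, 2)),
        "education": ObservationMap("thresholds", thresholds=even_thresholds(5),
                                    values=tuple(range(1, 6))),
        "marital_status": ObservationMap("thresholds", thresholds=even_thresholds(7),
                                         values=tuple(range(1, 8))),
        "irsad_decile": ObservationMap("thresholds", thresholds=even_thresholds(10),
                                       values=tuple(range(1, 11))),
        "recent_stressors": ObservationMap("thresholds",
                                           thresholds=score_thresholds(9, 2.5),
                                           values=tuple(range(0, 9))),
        "chronic_stress": ObservationMap("thresholds", thresholds=score_thresholds(37),
                                         values=tuple(range(0, 37))),
        "perceived_stress": ObservationMap("thresholds", thresholds=score_thresholds(41),
                                           values=tuple(range(0, 41))),
        "anxiety": ObservationMap("thresholds", thresholds=score_thresholds(22),
                                  values=tuple(range(0, 22))),
        "depression": ObservationMap("thresholds", thresholds=score_thresholds(22),
                                     values=tuple(range(0, 22))),
        "resilient_coping": ObservationMap("thresholds", thresholds=score_thresholds(17),
                                           values=tuple(range(4, 21))),
        "social_support": ObservationMap("thresholds", thresholds=score_thresholds(91),
                                         values=tuple(range(0, 91))),
        "cognitive_activity": ObservationMap("thresholds", thresholds=score_thresholds(56),
                                             values=tuple(range(0, 56))),
        "physical_activity": ObservationMap("lognormal", loc=7.6, scale=0.7),
        "bmi": ObservationMap("identity", loc=27.0, scale=5.0),
        "mind_diet": ObservationMap("thresholds", thresholds=score_thresholds(15),
                                    values=tuple(range(0, 15))),
        "alcohol": ObservationMap("lognormal", loc=1.2, scale=0.9),
        "blood_pressure": ObservationMap("thresholds", thresholds=score_thresholds(9),
                                         values=tuple(range(0, 9))),
        "cholesterol": ObservationMap("thresholds", thresholds=score_thresholds(9),
                                      values=tuple(range(0, 9))),
        "diabetes": ObservationMap("thresholds", thresholds=score_thresholds(9),
                                   values=tuple(range(0, 9))),
    }
    model = PlantedSEM(dag=dag, coefficients=dict(arcs), observation=obs, schema=schema)
    model.standardize_noise()
    return model


def make_cohort20(n: int, seed: int | np.random.Generator = 0) -> tuple[CohortTable, PlantedSEM]:
    """A 20-variable cohort-like dataset: bounded integer scale scores,
    ordinal demographics, skewed activity/alcohol measures, and four
    sink-forbidden (blacklisted) variables, generated from a documented
    planted DAG with a stress -> mental-health -> behavior spine."""
    if n < 50:
        raise ValueError("n must be >= 50 for a 20-variable cohort")
    model = _cohort20_model()
    table = sample_sem(model, n, seed)
    # threshold-mapped variables respect their ranges by construction;
    # unbounded ones (bmi, activity, alcohol) may stray and get screened
    for s in model.schema:
        if s.admissible_range and model.observation[s.name].kind == "thresholds":
            lo, hi = s.admissible_range
            col = table.data[s.name]
            assert col.between(lo, hi).all(), f"{s.name} breached its range"
    bl = Blacklist.from_sinks(table.sink_forbidden)
    bl.audit(model.dag)
    return table, model


def default_blacklist(model_or_table) -> Blacklist:
    schema = getattr(model_or_table, "schema", None)
    names = [s.name for s in schema if s.blacklist_sink_forbidden]
    return Blacklist.from_sinks(names)


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryReport:
    skeleton_precision: float
    skeleton_recall: float
    skeleton_f1: float
    shd: int
    orientation_accuracy: float | None

    def validate(self) -> None:
        for v in (self.skeleton_precision, self.skeleton_recall, self.skeleton_f1):
            assert 0.0 <= v <= 1.0
        assert self.shd >= 0


def _as_arcs(graph) -> tuple[list[str], set[tuple[str, str]]]:
    if isinstance(graph, DAGStructure):
        return list(graph.nodes), set(graph.arcs)
    # ConsensusGraph duck-typing
    return list(graph.nodes), {(a.from_, a.to) for a in graph.arcs}


def score_recovery(estimated, truth: DAGStructure) -> RecoveryReport:
    """Skeleton precision/recall/F1, structural Hamming distance, and
    orientation accuracy among correctly recovered skeleton edges."""
    est_nodes, est_arcs = _as_arcs(estimated)
    if set(est_nodes) != set(truth.nodes):
        raise ValueError("estimated and true graphs have different node sets")
    est_skel = {frozenset(a) for a in est_arcs}
    true_skel = truth.skeleton()
    tp = len(est_skel & true_skel)
    prec = tp / len(est_skel) if est_skel else 0.0
    rec = tp / len(true_skel) if true_skel else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    # SHD: one edit per pair present in exactly one skeleton, one per
    # shared pair with opposite orientation
    shd = len(est_skel ^ true_skel)
    correct = 0
    shared = est_skel & true_skel
    for pair in shared:
        u, v = sorted(pair)
        est_dir = (u, v) in est_arcs
        true_dir = (u, v) in truth.arcs
        if est_dir == true_dir:
            correct += 1
        else:
            shd += 1
    orient_acc = correct / len(shared) if shared else None
    report = RecoveryReport(
        skeleton_precision=prec, skeleton_recall=rec, skeleton_f1=f1,
        shd=shd, orientation_accuracy=orient_acc,
    )
    report.validate()
    return report
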