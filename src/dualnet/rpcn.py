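"""Regularized partial correlation network (RPCN) estimation.

Pipeline: a correlation matrix (rank-latent by default), an L1-penalized
Gaussian graphical model selected by the Extended Bayesian Information
Criterion along a log-spaced penalty path, node centrality and
predictability statistics, and two bootstrap diagnostics — non-parametric
edge accuracy and case-dropping centrality stability (CS-coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.covariance import graphical_lasso
from sklearn.linear_model import LogisticRegression

from .schema import SchemaError
from .transforms import TransformedDataset

__all__ = [
    "RPCNConfig",
    "CorrelationMatrix",
    "RPCNetwork",
    "CentralityReport",
    "EdgeBootstrap",
    "StabilityReport",
    "correlation_auto",
    "ebic_glasso",
    "fit_rpcn",
    "centrality",
    "predictability",
    "bootstrap_edges",
    "case_drop_stability",
    "CS_INTERPRETABLE",
    "CS_GOOD",
]

#: CS-coefficient interpretation thresholds
CS_INTERPRETABLE = 0.25
CS_GOOD = 0.50

#: case-dropping proportion grid
DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


@dataclass(frozen=True)
class RPCNConfig:
    """EBIC-glasso tuning parameters.

    ``ebic_gamma`` is the EBIC sparsity hyperparameter (0.5 = restrictive);
    the penalty path has ``n_lambda`` log-spaced values from the smallest
    penalty yielding an empty graph down to ``lambda_min_ratio`` times it.
    """

    ebic_gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    correlation_method: str = "rank_latent"

    def __post_init__(self) -> None:
        if self.ebic_gamma < 0:
            raise ValueError("ebic_gamma must be >= 0")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.correlation_method not in ("rank_latent", "pearson"):
            raise ValueError(f"unknown correlation method {self.correlation_method!r}")


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray
    method: str
    n: int
    psd_repaired: bool = False

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if np.linalg.eigvalsh(m).min() < -1e-8:
            raise ValueError("correlation matrix is not PSD after repair")


@dataclass
class RPCNetwork:
    """Symmetric signed partial-correlation weight matrix (zero diagonal)."""

    weights: np.ndarray
    selected_lambda: float
    nodes: list[str]
    ebic_path: list[tuple[float, float, int]] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_pairs(self) -> set[frozenset]:
        iu, ju = np.triu_indices(self.p, 1)
        return {
            frozenset((self.nodes[i], self.nodes[j]))
            for i, j in zip(iu, ju)
            if self.weights[i, j] != 0
        }

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        iu, ju = np.triu_indices(self.p, 1)
        for i, j in zip(iu, ju):
            w = self.weights[i, j]
            if w != 0:
                g.add_edge(self.nodes[i], self.nodes[j], weight=float(w), dist=1.0 / abs(w))
        return g


# ---------------------------------------------------------------------------
# correlation


def _nearest_psd(m: np.ndarray) -> tuple[np.ndarray, bool]:
    vals, vecs = np.linalg.eigh(m)
    if vals.min() >= -1e-8:
        return m, False
    vals = np.clip(vals, 0.0, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2, True


def correlation_auto(
    dataset: TransformedDataset | np.ndarray, method: str = "rank_latent"
) -> CorrelationMatrix:
    """Correlation matrix for network estimation.

    ``rank_latent`` maps Spearman rank correlations to the latent-Gaussian
    scale via 2*sin(pi*rho/6); ``pearson`` is plain product-moment.  Exact
    off-diagonal 1s are clipped to 1 - 1e-12 for downstream stability and a
    nearest-PSD repair is applied (and flagged) when needed.
    """
    x = dataset.matrix() if isinstance(dataset, TransformedDataset) else np.asarray(dataset, float)
    if np.isnan(x).any():
        raise SchemaError("correlation requires a complete-case matrix")
    n, p = x.shape
    for j in range(p):
        if np.ptp(x[:, j]) == 0:
            raise SchemaError(f"column {j}: constant column has undefined correlation")
    if method == "rank_latent":
        ranks = np.apply_along_axis(stats.rankdata, 0, x)
        rho = np.corrcoef(ranks, rowvar=False)
        m = 2.0 * np.sin(np.pi * rho / 6.0)
    elif method == "pearson":
        m = np.corrcoef(x, rowvar=False)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    off = ~np.eye(p, dtype=bool)
    m[off] = np.clip(m[off], -1 + 1e-12, 1 - 1e-12)
    np.fill_diagonal(m, 1.0)
    m = (m + m.T) / 2
    m, repaired = _nearest_psd(m)
    out = CorrelationMatrix(matrix=m, method=method, n=n, psd_repaired=repaired)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# EBIC glasso


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(precision), 1e-300, None))
    r = -precision / np.outer(d, d)
    np.fill_diagonal(r, 0.0)
    return (r + r.T) / 2


def fit_glasso(corr: np.ndarray, lam: float) -> np.ndarray:
    """Single graphical-lasso fit; returns the precision matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, precision = graphical_lasso(corr, alpha=lam, max_iter=200)
    return precision


def _gaussian_loglik(S: np.ndarray, theta: np.ndarray, n: int) -> float:
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.trace(S @ theta) - p * np.log(2 * np.pi))


def ebic_glasso(
    corr: CorrelationMatrix, n: int | None = None, config: RPCNConfig = RPCNConfig(),
    nodes: list[str] | None = None,
) -> RPCNetwork:
    """EBIC-selected graphical lasso over a log-spaced penalty path.

    EBIC = -2*loglik + E*log(n) + 4*gamma*E*log(p) with E the nonzero
    upper-triangle edge count of the estimated precision matrix.
    """
    S = corr.matrix
    n = corr.n if n is None else n
    p = S.shape[0]
    if nodes is None:
        nodes = [f"v{j}" for j in range(p)]
    off = np.abs(S[~np.eye(p, dtype=bool)])
    lam_max = float(off.max()) if off.size else 0.0
    if lam_max <= 1e-12:
        return RPCNetwork(np.zeros((p, p)), selected_lambda=0.0, nodes=list(nodes))
    lambdas = np.exp(
        np.linspace(np.log(lam_max), np.log(lam_max * config.lambda_min_ratio), config.n_lambda)
    )
    best = None
    path: list[tuple[float, float, int]] = []
    for lam in lambdas:
        try:
            theta = fit_glasso(S, float(lam))
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            raise RuntimeError(f"graphical lasso failed at lambda={lam:.6g}: {exc}") from exc
        iu = np.triu_indices(p, 1)
        E = int(np.count_nonzero(np.abs(theta[iu]) > 1e-10))
        ebic = -2.0 * _gaussian_loglik(S, theta, n) + E * np.log(n) + 4.0 * config.ebic_gamma * E * np.log(p)
        path.append((float(lam), float(ebic), E))
        if best is None or ebic < best[0]:
            best = (ebic, float(lam), theta)
    assert best is not None
    _, sel_lam, theta = best
    r = partial_correlations(theta)
    r[np.abs(r) < 1e-10] = 0.0
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return RPCNetwork(r, selected_lambda=sel_lam, nodes=list(nodes), ebic_path=path)


def fit_rpcn(dataset: TransformedDataset, config: RPCNConfig = RPCNConfig()) -> RPCNetwork:
    """Convenience: correlation_auto then ebic_glasso on a dataset view."""
    corr = correlation_auto(dataset, config.correlation_method)
    return ebic_glasso(corr, config=config, nodes=dataset.table.columns)


# ---------------------------------------------------------------------------
# centrality / predictability


@dataclass
class CentralityReport:
    nodes: list[str]
    strength: np.ndarray
    expected_influence: np.ndarray
    closeness: np.ndarray
    betweenness: np.ndarray
    predictability: np.ndarray | None = None
    closeness_convention: str = "harmonic (sum of inverse distances; unreachable = 0)"

    def as_matrix(self) -> np.ndarray:
        return np.column_stack(
            [self.strength, self.expected_influence, self.closeness, self.betweenness]
        )

    INDICES = ("strength", "expected_influence", "closeness", "betweenness")

    def index(self, name: str) -> np.ndarray:
        return getattr(self, name)


def centrality(net: RPCNetwork) -> CentralityReport:
    """Strength, expected influence, harmonic closeness, and betweenness.

    Path lengths use the inverse absolute edge weight as distance;
    betweenness is the unnormalized shortest-path count.
    """
    if net.p < 1:
        raise ValueError("network must have at least one node")
    w = net.weights
    strength = np.abs(w).sum(axis=1)
    ei = w.sum(axis=1)
    g = net.to_graph()
    close = np.zeros(net.p)
    for i, u in enumerate(net.nodes):
        dists = nx.single_source_dijkstra_path_length(g, u, weight="dist")
        close[i] = sum(1.0 / d for v, d in dists.items() if v != u and d > 0)
    btw_dict = nx.betweenness_centrality(g, weight="dist", normalized=False)
    btw = np.array([btw_dict[u] for u in net.nodes])
    return CentralityReport(
        nodes=list(net.nodes), strength=strength, expected_influence=ei,
        closeness=close, betweenness=btw,
    )


def predictability(dataset: TransformedDataset, net: RPCNetwork) -> np.ndarray:
    """Per-node variance explained by its network neighbors.

    Numeric nodes: R^2 of an unpenalized regression on RPCN neighbors.
    Categorical nodes: classification accuracy normalized above the
    marginal mode, (acc - mode)/(1 - mode), floored at 0.  Isolated
    nodes score 0.
    """
    x = dataset.matrix()
    names = dataset.table.columns
    out = np.zeros(net.p)
    for i, name in enumerate(names):
        nbrs = [j for j in range(net.p) if j != i and net.weights[i, j] != 0]
        if not nbrs:
            continue
        y, X = x[:, i], x[:, nbrs]
        role = dataset.table.variable(name).role
        if role == "categorical" and not dataset.is_discrete:
            yc = y.astype(int)
            mode_acc = np.bincount(yc).max() / len(yc)
            clf = LogisticRegression(max_iter=500).fit(X, yc)
            acc = float((clf.predict(X) == yc).mean())
            out[i] = max(0.0, (acc - mode_acc) / max(1e-12, 1.0 - mode_acc))
        else:
            Xd = np.column_stack([np.ones(len(y)), X])
            beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            resid = y - Xd @ beta
            tss = float(((y - y.mean()) ** 2).sum())
            out[i] = 0.0 if tss == 0 else max(0.0, 1.0 - float((resid**2).sum()) / tss)
    return out


# ---------------------------------------------------------------------------
# bootstrap diagnostics


@dataclass
class EdgeBootstrap:
    nodes: list[str]
    mean: np.ndarray          # bootstrap mean weight per edge (all resamples)
    ci_low: np.ndarray
    ci_high: np.ndarray
    nonzero_mean: np.ndarray  # mean over resamples where the edge is present
    n_resamples: int
    n_failures: int

    def validate(self) -> None:
        assert np.all(self.ci_low <= self.mean + 1e-12)
        assert np.all(self.mean <= self.ci_high + 1e-12)


def bootstrap_edges(
    dataset: TransformedDataset,
    B: int,
    config: RPCNConfig = RPCNConfig(),
    seed: int | np.random.Generator = 0,
) -> EdgeBootstrap:
    """Non-parametric edge-accuracy bootstrap: B row-resamples with
    replacement, full refit each, percentile 2.5/97.5 interval per edge."""
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = dataset.matrix()
    n, p = x.shape
    draws = np.zeros((B, p, p))
    failures = 0
    kept = []
    for b in range(B):
        idx = rng.integers(0, n, n)
        try:
            corr = correlation_auto(x[idx], config.correlation_method)
            net = ebic_glasso(corr, config=config)
        except (SchemaError, RuntimeError):
            failures += 1
            continue
        draws[len(kept)] = net.weights
        kept.append(b)
    if failures > 0.10 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap resamples failed to fit")
    w = draws[: len(kept)]
    mean = w.mean(axis=0)
    lo = np.percentile(w, 2.5, axis=0)
    hi = np.percentile(w, 97.5, axis=0)
    nz_count = np.maximum((w != 0).sum(axis=0), 1)
    nz_mean = w.sum(axis=0) / nz_count
    out = EdgeBootstrap(
        nodes=dataset.table.columns, mean=mean, ci_low=lo, ci_high=hi,
        nonzero_mean=nz_mean, n_resamples=len(kept), n_failures=failures,
    )
    out.validate()
    return out


@dataclass
class StabilityReport:
    drop_grid: tuple
    correlations: dict  # index -> {q: array of Spearman correlations}
    cs: dict            # index -> CS-coefficient
    infeasible: list
    cor_criterion: float = 0.70
    proportion_criterion: float = 0.95

    def flags(self) -> dict:
        return {
            idx: {
                "interpretable": v >= CS_INTERPRETABLE,
                "good": v >= CS_GOOD,
            }
            for idx, v in self.cs.items()
        }

    def cs_at(self, cor: float) -> dict:
        """Recompute CS-coefficients at a different correlation criterion
        from the cached resample correlations."""
        out = {}
        for idx, per_q in self.correlations.items():
            best = 0.0
            for q in self.drop_grid:
                if q not in per_q:
                    continue
                vals = per_q[q]
                ok = np.mean(vals >= cor) >= self.proportion_criterion
                if ok and q > best:
                    best = q
            out[idx] = best
        return out


def _spearman_safe(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    rho = stats.spearmanr(a, b).statistic
    return float(rho) if np.isfinite(rho) else np.nan


def case_drop_stability(
    dataset: TransformedDataset,
    B: int,
    config: RPCNConfig = RPCNConfig(),
    seed: int | np.random.Generator = 0,
    drop_grid: tuple = DROP_GRID,
) -> StabilityReport:
    """Case-dropping centrality stability.

    For each drop proportion q, B subsamples retaining (1-q)*n rows are
    refit; per centrality index, the Spearman correlation between the
    subsample and full-sample values is recorded.  CS(cor=0.70) is the
    largest q at which >= 95% of subsamples correlate >= 0.70; undefined
    correlations (constant vectors) count as failures.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = dataset.matrix()
    n, p = x.shape
    full = centrality(fit_rpcn(dataset, config))
    correlations: dict[str, dict] = {idx: {} for idx in CentralityReport.INDICES}
    infeasible = []
    for q in drop_grid:
        keep = int(round((1 - q) * n))
        if keep <= p:
            infeasible.append(q)
            continue
        per_idx = {idx: np.full(B, np.nan) for idx in CentralityReport.INDICES}
        for b in range(B):
            idx_rows = rng.choice(n, size=keep, replace=False)
            try:
                corr = correlation_auto(x[idx_rows], config.correlation_method)
                net = ebic_glasso(corr, config=config)
                rep = centrality(net)
            except (SchemaError, RuntimeError):
                continue
            for name in CentralityReport.INDICES:
                per_idx[name][b] = _spearman_safe(full.index(name), rep.index(name))
        for name in CentralityReport.INDICES:
            correlations[name][q] = per_idx[name]
    cs = {}
    for name, per_q in correlations.items():
        best = 0.0
        for q, vals in per_q.items():
            vals = np.where(np.isnan(vals), -np.inf, vals)
            if np.mean(vals >= 0.70) >= 0.95 and q > best:
                best = q
        cs[name] = best
    return StabilityReport(
        drop_grid=tuple(q for q in drop_grid), correlations=correlations,
        cs=cs, infeasible=infeasible,
    )
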