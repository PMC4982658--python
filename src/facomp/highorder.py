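"""High-order relation screen over component subsets.

Does jointly considering several components predict a target component's
density better than any smaller subset?  For a chosen target, every
non-empty subset of the remaining components (511 subsets for a
10-component panel) is used as the input of a small multilayer-perceptron
regressor (three hidden layers, each as wide as the input); training runs
as many independent sessions as configured, each on a random 40/30/30
train/validation/test split, and the final performance of a subset is the
mean-squared error of the session-ensemble prediction on the complete
dataset.  Random-forest regression over the same subsets provides an
independent comparison method.

The subsets form a lattice: nodes connected when they differ by exactly
one component.  Each edge is directed toward the node that predicts the
target significantly better (variance-ratio F-test on the per-adhesion
squared errors); nodes are then scored by their position,

    L = L1 / (L1 + L2),

where ``L1``/``L2`` are the shortest edge distances to the closest
single-component node and to the closest node with null out-degree
(a local prediction optimum).  High-L nodes sit far from trivial
single-input predictors and close to prediction optima; a subset with
L > 0.7 in at least 4 of the 6 datasets (at least 2 per labeling order)
is reported as a high-order relation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .tables import DensityTable

logger = logging.getLogger(__name__)

#: Default number of training sessions per subset.  Full-scale screens use
#: 500; the default keeps a complete screen tractable on one CPU.
DEFAULT_SESSIONS = 50
#: Train/validation/test fractions per session.
SPLIT_FRACTIONS = (0.4, 0.3, 0.3)
#: L-score threshold and dataset-support rule for reporting a relation.
L_THRESHOLD = 0.7
MIN_DATASETS = 4
MIN_PER_ORDER = 2
#: Relations whose mean ensemble R2 falls below this are flagged as weak.
R2_FLAG_THRESHOLD = 0.6


def enumerate_input_sets(
    components: Sequence[str], target: str
) -> list[tuple[str, ...]]:
    """All non-empty subsets of the non-target components.

    Deterministic order: by subset size, then lexicographic.  For a
    10-component panel this yields ``2**9 - 1 = 511`` subsets.
    """
    if target not in components:
        raise ValueError(f"target {target!r} not among components")
    rest = sorted(c for c in components if c != target)
    out: list[tuple[str, ...]] = []
    for size in range(1, len(rest) + 1):
        out.extend(combinations(rest, size))
    return out


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------

@dataclass
class PredictorResult:
    """Performance of one (target, input subset) predictor."""

    target: str
    inputs: tuple[str, ...]
    method: str  # "ann" | "rf"
    session_mse: np.ndarray  # test MSE per session (ann) / OOB MSE (rf)
    final_mse: float
    r2: float
    squared_errors: np.ndarray  # per-adhesion, ensemble prediction on all data
    n_failed_sessions: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.inputs):
            raise ValueError("input subset must be non-empty")
        if self.r2 > 1 + 1e-12:
            raise ValueError("R2 cannot exceed 1")


def _design(table: DensityTable, inputs: Sequence[str], target: str):
    """Standardized design matrix and response.

    Box-Cox z-scores are used when the table carries them, otherwise the
    raw columns are z-scored here; perceptron training needs standardized
    inputs either way.
    """
    frame = table.zscores if table.has_zscores else table.raw
    X = frame[list(inputs)].to_numpy(dtype=float)
    y = frame[target].to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    ys = (y - y.mean()) / y.std(ddof=0)
    return Xs, ys


def _split(rng: np.random.Generator, n: int):
    idx = rng.permutation(n)
    n_train = int(round(SPLIT_FRACTIONS[0] * n))
    n_val = int(round(SPLIT_FRACTIONS[1] * n))
    return idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :]


def _fit_session_ann(
    X, y, train, val, hidden: tuple[int, ...], seed: int,
    chunk_iter: int, max_chunks: int,
):
    """One training session with validation-based early stopping.

    The quasi-Newton optimizer runs in chunks; training stops when the
    validation MSE no longer improves, returning the best-validation model.
    """
    model = MLPRegressor(
        hidden_layer_sizes=hidden,
        activation="tanh",
        solver="lbfgs",
        max_iter=chunk_iter,
        tol=1e-5,
        warm_start=True,
        random_state=seed,
    )
    best_val = np.inf
    best_coefs = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_chunks):
            model.fit(X[train], y[train])
            val_mse = float(np.mean((model.predict(X[val]) - y[val]) ** 2))
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_coefs = ([c.copy() for c in model.coefs_],
                              [b.copy() for b in model.intercepts_])
            else:
                break
    if best_coefs is None or not np.isfinite(best_val):
        return None, np.inf
    model.coefs_, model.intercepts_ = best_coefs
    return model, best_val


def fit_ann(
    table: DensityTable,
    inputs: Sequence[str],
    target: str,
    sessions: int = DEFAULT_SESSIONS,
    seed: int = 0,
    chunk_iter: int = 20,
    max_chunks: int = 2,
    aggregate: str = "ensemble",
) -> PredictorResult:
    """Perceptron predictor of ``target`` from an input subset.

    Architecture: three hidden layers, each with as many neurons as input
    components.  Each session draws an independent 40/30/30
    train/validation/test split and stops on validation MSE; the subset's
    final performance is evaluated on the complete dataset, either by the
    mean prediction of all session networks (``aggregate="ensemble"``,
    default) or by the single best-validation network (``"best"``).
    A session that fails to converge is retried once with a new split,
    then dropped with a log message.
    """
    inputs = tuple(inputs)
    if len(inputs) == 0:
        raise ValueError("input subset must be non-empty")
    X, y = _design(table, inputs, target)
    if len(y) < 50:
        raise ValueError("need at least 50 adhesions to train")
    k = len(inputs)
    hidden = (k, k, k)
    rng = np.random.default_rng(seed)
    preds = np.zeros(len(y))
    n_models = 0
    session_mse = []
    best_model, best_val = None, np.inf
    n_failed = 0
    for _ in range(sessions):
        model = None
        for _retry in range(2):
            train, val, test = _split(rng, len(y))
            sess_seed = int(rng.integers(0, 2**31 - 1))
            model, val_mse = _fit_session_ann(
                X, y, train, val, hidden, sess_seed, chunk_iter, max_chunks
            )
            if model is not None:
                break
        if model is None:
            n_failed += 1
            logger.warning("session failed to converge for inputs %s; dropped", inputs)
            continue
        session_mse.append(float(np.mean((model.predict(X[test]) - y[test]) ** 2)))
        preds += model.predict(X)
        n_models += 1
        if val_mse < best_val:
            best_val, best_model = val_mse, model
    if n_models == 0:
        raise RuntimeError(f"all sessions failed for inputs {inputs}")
    if aggregate == "ensemble":
        final_pred = preds / n_models
    elif aggregate == "best":
        final_pred = best_model.predict(X)
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    sq = (final_pred - y) ** 2
    final_mse = float(sq.mean())
    r2 = 1.0 - final_mse / float(np.var(y))
    return PredictorResult(
        target=target, inputs=inputs, method="ann",
        session_mse=np.asarray(session_mse), final_mse=final_mse, r2=r2,
        squared_errors=sq, n_failed_sessions=n_failed,
    )


def fit_rf(
    table: DensityTable,
    inputs: Sequence[str],
    target: str,
    n_trees: int = 500,
    seed: int = 0,
) -> PredictorResult:
    """Random-forest predictor over the same (target, subset) contract.

    All input components are split candidates at every node (bagging is the
    only source of randomization); the out-of-bag MSE is recorded alongside
    the complete-dataset performance.
    """
    inputs = tuple(inputs)
    if len(inputs) == 0:
        raise ValueError("input subset must be non-empty")
    X, y = _design(table, inputs, target)
    if len(y) < 50:
        raise ValueError("need at least 50 adhesions to train")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=None,  # all inputs candidate at each node
            oob_score=True,
            random_state=int(seed) % (2**32),
            n_jobs=1,
        )
        model.fit(X, y)
        oob_mse = float(np.mean((model.oob_prediction_ - y) ** 2))
        pred = model.predict(X)
    sq = (pred - y) ** 2
    return PredictorResult(
        target=target, inputs=inputs, method="rf",
        session_mse=np.array([oob_mse]), final_mse=float(sq.mean()),
        r2=1.0 - float(sq.mean()) / float(np.var(y)), squared_errors=sq,
    )


def compare_predictors(
    ann_results: Mapping[tuple[str, ...], PredictorResult],
    rf_results: Mapping[tuple[str, ...], PredictorResult],
) -> dict:
    """Correlation between the two methods' coefficients of determination.

    Returns the Pearson r between matched R2 vectors and the mean signed
    difference (ann − rf).
    """
    keys = sorted(ann_results)
    if sorted(rf_results) != keys:
        raise ValueError("ann and rf results must cover the same subsets")
    a = np.array([ann_results[k].r2 for k in keys])
    b = np.array([rf_results[k].r2 for k in keys])
    return {
        "r": float(stats.pearsonr(a, b).statistic),
        "mean_difference": float(np.mean(a - b)),
        "n": len(keys),
    }


# ---------------------------------------------------------------------------
# the subset-lattice DAG and the L score
# ---------------------------------------------------------------------------

@dataclass
class RelationDAG:
    """Subset lattice with F-test-directed edges and per-node L scores."""

    target: str
    dataset_id: str
    labeling_order: str
    graph: nx.DiGraph
    l_scores: dict[frozenset, float] = field(default_factory=dict)
    r2: dict[frozenset, float] = field(default_factory=dict)

    @property
    def nodes(self):
        return self.graph.nodes


def build_relation_dag(
    results: Mapping[tuple[str, ...], PredictorResult],
    alpha: float = 0.05,
    dataset_id: str = "R1O1",
    labeling_order: str = "O1",
) -> RelationDAG:
    """Direct the subset lattice by predictive performance.

    Nodes are the input subsets; for every pair differing by one component
    a two-sided variance-ratio F-test compares the per-adhesion squared
    errors of the two ensemble predictions, and an edge is added pointing
    to the significantly better (lower-MSE) node; non-significant pairs
    get no edge.  L scores are attached to every node.
    """
    subsets = [frozenset(k) for k in results]
    expected = enumerate_input_sets(
        sorted({c for k in results for c in k} | {next(iter(results.values())).target}),
        next(iter(results.values())).target,
    )
    if len(subsets) != len(expected):
        raise ValueError(
            f"incomplete screen: {len(subsets)} subsets, expected {len(expected)}"
        )
    by_set = {frozenset(k): v for k, v in results.items()}
    g = nx.DiGraph()
    g.add_nodes_from(subsets)
    target = next(iter(results.values())).target
    for node in subsets:
        for extra in expected[-1]:
            if extra in node:
                continue
            other = node | {extra}
            if other not in by_set:
                continue
            a, b = by_set[node], by_set[other]
            p, better = _f_test(a.squared_errors, b.squared_errors)
            if p < alpha:
                winner, loser = (node, other) if better == 0 else (other, node)
                g.add_edge(loser, winner)
    dag = RelationDAG(
        target=target, dataset_id=dataset_id, labeling_order=labeling_order, graph=g,
        r2={frozenset(k): v.r2 for k, v in results.items()},
    )
    dag.l_scores = {n: l_score(dag, n) for n in g.nodes}
    return dag


def _f_test(sq_a: np.ndarray, sq_b: np.ndarray) -> tuple[float, int]:
    """Two-sided variance-ratio test on squared-error samples.

    Returns ``(p, better)`` with ``better = 0`` if sample a has the lower
    mean squared error.  Squared errors are treated as scaled chi-square
    variates; the ratio of their means is referred to an F distribution
    with (n_a, n_b) degrees of freedom.
    """
    ma, mb = float(np.mean(sq_a)), float(np.mean(sq_b))
    if ma == mb:
        return 1.0, 0
    if ma <= 0 or mb <= 0:  # a perfect predictor: trivially better
        return 0.0, 0 if ma < mb else 1
    f = ma / mb
    p_one = stats.f.sf(f, len(sq_a), len(sq_b)) if f > 1 else stats.f.cdf(f, len(sq_a), len(sq_b))
    return min(1.0, 2 * p_one), 1 if ma > mb else 0


def l_score(dag: RelationDAG, node: frozenset) -> float:
    """Position score ``L = L1/(L1+L2)`` of a node in the directed lattice.

    ``L1``: shortest edge distance to any single-component node; ``L2``: to
    any node with null out-degree.  Distances run over the existing edges
    ignoring direction (direction-respecting distances would be undefined
    for most nodes).  NaN flags nodes for which either distance does not
    exist, or singleton sinks (L1 = L2 = 0).
    """
    g = dag.graph
    if node not in g:
        raise KeyError(f"node {set(node)} not in DAG")
    und = g.to_undirected(as_view=True)
    singletons = {n for n in g.nodes if len(n) == 1}
    sinks = {n for n in g.nodes if g.out_degree(n) == 0}
    l1 = _shortest_to(und, node, singletons)
    l2 = _shortest_to(und, node, sinks)
    if np.isnan(l1) or np.isnan(l2) or (l1 == 0 and l2 == 0):
        return float("nan")
    return l1 / (l1 + l2)


def _shortest_to(graph, source, targets: set) -> float:
    if source in targets:
        return 0.0
    try:
        lengths = nx.single_source_shortest_path_length(graph, source)
    except nx.NetworkXError:
        return float("nan")
    best = min((d for n, d in lengths.items() if n in targets), default=None)
    return float(best) if best is not None else float("nan")


# ---------------------------------------------------------------------------
# cross-dataset selection
# ---------------------------------------------------------------------------

@dataclass
class HighOrderRelation:
    """A subset passing the cross-dataset L-score selection rule."""

    target: str
    inputs: tuple[str, ...]
    n_supporting: int
    supporting_datasets: tuple[str, ...]
    mean_l: float
    mean_size: float
    mean_r2: float
    low_r2_flag: bool


def select_high_order(
    dags: Sequence[RelationDAG],
    threshold: float = L_THRESHOLD,
    min_datasets: int = MIN_DATASETS,
    min_per_order: int = MIN_PER_ORDER,
    r2_flag: float = R2_FLAG_THRESHOLD,
) -> list[HighOrderRelation]:
    """Subsets with L above threshold in enough datasets of both orders.

    A subset is selected when its L exceeds ``threshold`` in at least
    ``min_datasets`` datasets including at least ``min_per_order`` from
    each labeling order.  Selected relations carry their mean subset size
    and mean ensemble R2; those with mean R2 below ``r2_flag`` are flagged
    as weak predictions.
    """
    if len(dags) < min_datasets:
        raise ValueError(f"need at least {min_datasets} datasets, got {len(dags)}")
    targets = {d.target for d in dags}
    if len(targets) != 1:
        raise ValueError(f"DAGs mix targets: {targets}")
    orders = {d.labeling_order for d in dags}
    all_nodes = set().union(*(set(d.graph.nodes) for d in dags))
    out: list[HighOrderRelation] = []
    for node in all_nodes:
        support = [
            d for d in dags
            if node in d.l_scores and not np.isnan(d.l_scores[node]) and d.l_scores[node] > threshold
        ]
        if len(support) < min_datasets:
            continue
        per_order = {o: sum(d.labeling_order == o for d in support) for o in orders}
        if any(c < min_per_order for c in per_order.values()):
            continue
        mean_r2 = float(np.mean([d.r2[node] for d in support if node in d.r2]))
        out.append(
            HighOrderRelation(
                target=next(iter(targets)),
                inputs=tuple(sorted(node)),
                n_supporting=len(support),
                supporting_datasets=tuple(sorted(d.dataset_id for d in support)),
                mean_l=float(np.mean([d.l_scores[node] for d in support])),
                mean_size=float(len(node)),
                mean_r2=mean_r2,
                low_r2_flag=mean_r2 < r2_flag,
            )
        )
    out.sort(key=lambda r: (-r.mean_l, -r.n_supporting, r.inputs))
    return out


def screen_target(
    table: DensityTable,
    target: str,
    sessions: int = DEFAULT_SESSIONS,
    seed: int = 0,
    alpha: float = 0.05,
    components: Sequence[str] | None = None,
) -> tuple[dict[tuple[str, ...], PredictorResult], RelationDAG]:
    """Run the full subset screen for one target on one dataset."""
    comps = tuple(components) if components is not None else table.components
    results: dict[tuple[str, ...], PredictorResult] = {}
    rng = np.random.default_rng(seed)
    for subset in enumerate_input_sets(comps, target):
        results[subset] = fit_ann(
            table, subset, target, sessions=sessions,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    dag = build_relation_dag(
        results, alpha=alpha, dataset_id=table.dataset_id,
        labeling_order=table.labeling_order,
    )
    return results, dag
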