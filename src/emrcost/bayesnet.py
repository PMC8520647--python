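"""Discrete Bayesian-network scoring and naive-Bayes scheme classification.

A fixed directed acyclic graph over the discretized features (and the
treatment-scheme node) is scored by maximum-likelihood conditional
probability tables (CPTs): for each node, P(state | parent states) is the
observed frequency, optionally Laplace-smoothed with pseudocount ``alpha``.
Classification uses the naive factorization

    yhat = argmax_j  P(y_j) * prod_i P(x_i | y_j)

evaluated in log space (16 factors of small probabilities underflow
otherwise), with the posterior over schemes obtained by normalizing across
classes.  Structure learning is out of scope: arbitrary user-supplied DAGs
are supported for CPT fitting and log-likelihood scoring only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConfigError, DomainError, UndefinedCPTError
from .records import SCHEME_COLUMN, FeatureMatrix

__all__ = [
    "DiscreteDAG",
    "CPTSet",
    "DiscretizationMap",
    "discretize_features",
    "naive_bayes_dag",
    "fit_cpts",
    "fit_naive_bayes",
    "log_likelihood",
    "classify",
]


@dataclass(frozen=True)
class DiscreteDAG:
    """A directed acyclic graph over named discrete variables."""

    nodes: tuple
    edges: tuple  # (parent, child) pairs

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        declared = set(self.nodes)
        for p, c in self.edges:
            if p not in declared or c not in declared:
                raise ConfigError(f"edge ({p!r}, {c!r}): undeclared node")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm; raises if no topological order exists.
        children: Dict[str, list] = {n: [] for n in self.nodes}
        indeg = {n: 0 for n in self.nodes}
        for p, c in self.edges:
            children[p].append(c)
            indeg[c] += 1
        queue = [n for n in self.nodes if indeg[n] == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self.nodes):
            raise ConfigError("graph contains a cycle")

    def parents(self, node: str) -> tuple:
        return tuple(p for p, c in self.edges if c == node)

    @classmethod
    def from_edge_file(cls, path) -> "DiscreteDAG":
        """Load a DAG from a text file of tab-separated parent<TAB>child lines."""
        edges = []
        nodes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                p, c = line.split("\t")
                edges.append((p, c))
                for n in (p, c):
                    if n not in nodes:
                        nodes.append(n)
        return cls(nodes=tuple(nodes), edges=tuple(edges))


def naive_bayes_dag(feature_names: Sequence[str],
                    class_node: str = SCHEME_COLUMN) -> DiscreteDAG:
    """The star graph class -> each feature used by the classifier."""
    nodes = (class_node,) + tuple(feature_names)
    edges = tuple((class_node, f) for f in feature_names)
    return DiscreteDAG(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


@dataclass
class DiscretizationMap:
    """Recorded quantile-bin edges for numeric columns, for reuse on new data."""

    bin_edges: Dict[str, np.ndarray]  # interior edges per numeric column

    def transform(self, fm: FeatureMatrix) -> pd.DataFrame:
        if fm.X.isna().any().any():
            raise DomainError("discretize_features requires a fully imputed matrix")
        out = {}
        for spec in fm.columns:
            col = fm.X[spec.name].to_numpy()
            if not np.isfinite(col).all():
                raise DomainError(f"column {spec.name!r}: non-finite cell")
            if spec.name in self.bin_edges:
                out[spec.name] = np.searchsorted(
                    self.bin_edges[spec.name], col, side="right")
            else:
                # degree/binary: finite grid; round to kill float fuzz
                out[spec.name] = np.round(col, 12)
        return pd.DataFrame(out, columns=[c.name for c in fm.columns])


def discretize_features(fm: FeatureMatrix, bins_for_numeric: int = 4):
    """Put every feature on a finite grid.

    Binary and degree columns already take finitely many values and are kept
    as-is; numeric columns are binned into ``bins_for_numeric`` quantile bins
    (bin index recorded, edges kept for inverse lookup / reuse on new data).

    Returns (discrete DataFrame, DiscretizationMap).
    """
    if bins_for_numeric < 2:
        raise ConfigError(f"bins_for_numeric: must be >= 2, got {bins_for_numeric}")
    edges = {}
    for spec in fm.columns:
        if spec.kind == "numeric":
            col = fm.X[spec.name].to_numpy()
            if not np.isfinite(col).all():
                raise DomainError(f"column {spec.name!r}: non-finite cell")
            qs = np.quantile(col, np.linspace(0, 1, bins_for_numeric + 1)[1:-1])
            edges[spec.name] = np.unique(qs)
    dmap = DiscretizationMap(bin_edges=edges)
    return dmap.transform(fm), dmap


# ---------------------------------------------------------------------------
# CPT estimation and scoring
# ---------------------------------------------------------------------------


@dataclass
class NodeCPT:
    node: str
    parents: tuple
    states: tuple                      # child states, sorted
    parent_states: Dict[str, tuple]    # per-parent state spaces, sorted
    table: Dict[tuple, np.ndarray]     # parent-state combo -> prob vector

    def prob(self, state, parent_combo: tuple, alpha: float, n_states: int) -> float:
        probs = self.table[parent_combo]
        try:
            idx = self.states.index(state)
        except ValueError:
            # state never seen at fit time: its smoothed count is alpha
            if alpha <= 0:
                return 0.0
            # renormalization over the enlarged state set is not attempted;
            # the smoothed zero-count mass is the conventional fallback
            return float(alpha / (self._combo_count(parent_combo) + alpha * n_states))
        return float(probs[idx])

    def _combo_count(self, combo: tuple) -> float:
        return self.counts.get(combo, 0.0)

    counts: Dict[tuple, float] = field(default_factory=dict)


@dataclass
class CPTSet:
    """Conditional probability tables for every node of a fixed DAG."""

    dag: DiscreteDAG
    alpha: float
    nodes: Dict[str, NodeCPT]
    class_node: Optional[str] = None

    @property
    def class_states(self) -> tuple:
        return self.nodes[self.class_node].states

    @property
    def class_priors(self) -> np.ndarray:
        return self.nodes[self.class_node].table[()]


def _sorted_states(values) -> tuple:
    return tuple(sorted(pd.unique(values)))


def fit_cpts(data: pd.DataFrame, dag: DiscreteDAG, alpha: float = 0.0,
             class_node: Optional[str] = None) -> CPTSet:
    """Maximum-likelihood (alpha = 0) or Laplace-smoothed CPTs.

    For each node, over every combination of its parents' observed state
    spaces:  P(state | parents) = (count + alpha) / (total + alpha * S).
    With alpha = 0 an unobserved parent combination has no defined
    distribution and raises :class:`UndefinedCPTError`.
    """
    if alpha < 0:
        raise ConfigError(f"alpha: must be >= 0, got {alpha}")
    missing = [n for n in dag.nodes if n not in data.columns]
    if missing:
        raise ConfigError(f"data lacks node column(s) {missing}")
    node_cpts = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        states = _sorted_states(data[node])
        S = len(states)
        pstates = {p: _sorted_states(data[p]) for p in parents}
        table = {}
        counts = {}
        if parents:
            grouped = data.groupby(list(parents), sort=False, observed=True)[node]
            combo_counts = {}
            for key, series in grouped:
                key = key if isinstance(key, tuple) else (key,)
                vc = series.value_counts()
                combo_counts[key] = vc
            for combo in itertools.product(*(pstates[p] for p in parents)):
                vc = combo_counts.get(combo)
                total = 0.0 if vc is None else float(vc.sum())
                if total == 0 and alpha == 0:
                    raise UndefinedCPTError(
                        f"node {node!r}: parent configuration "
                        f"{dict(zip(parents, combo))} never observed and alpha=0")
                raw = np.array(
                    [0.0 if vc is None else float(vc.get(s, 0.0)) for s in states])
                table[combo] = (raw + alpha) / (total + alpha * S)
                counts[combo] = total
        else:
            vc = data[node].value_counts()
            total = float(vc.sum())
            raw = np.array([float(vc.get(s, 0.0)) for s in states])
            table[()] = (raw + alpha) / (total + alpha * S)
            counts[()] = total
        node_cpts[node] = NodeCPT(
            node=node, parents=parents, states=states,
            parent_states=pstates, table=table, counts=counts)
    return CPTSet(dag=dag, alpha=alpha, nodes=node_cpts, class_node=class_node)


def fit_naive_bayes(data: pd.DataFrame, class_col: str = SCHEME_COLUMN,
                    alpha: float = 1.0) -> CPTSet:
    """Fit the naive star DAG (class -> each feature) on a discrete table."""
    features = [c for c in data.columns if c != class_col]
    dag = naive_bayes_dag(features, class_node=class_col)
    return fit_cpts(data, dag, alpha=alpha, class_node=class_col)


def log_likelihood(data: pd.DataFrame, cpts: CPTSet) -> float:
    """Joint log-likelihood sum_records sum_nodes log P(state | parent states).

    A zero-probability observed event yields -inf with a warning rather than
    an exception.
    """
    total = 0.0
    for node in cpts.dag.nodes:
        cpt = cpts.nodes[node]
        S = len(cpt.states)
        for _, row in data.iterrows():
            combo = tuple(row[p] for p in cpt.parents)
            p = cpt.prob(row[node], combo, cpts.alpha, S)
            if p <= 0.0:
                warnings.warn(
                    f"zero probability for node {node!r} state {row[node]!r}; "
                    f"log-likelihood is -inf")
                return float("-inf")
            total += float(np.log(p))
    return total


def _feature_log_table(cpts: CPTSet, feature: str, values: np.ndarray) -> np.ndarray:
    """log P(x | y_j) for a vector of observed values; shape (n, n_classes)."""
    cpt = cpts.nodes[feature]
    classes = cpts.class_states
    S = len(cpt.states)
    out = np.empty((len(values), len(classes)))
    for jc, y in enumerate(classes):
        lookup = {}
        for iv, v in enumerate(pd.unique(values)):
            p = cpt.prob(v, (y,), cpts.alpha, S)
            lookup[v] = np.log(p) if p > 0 else -np.inf
        out[:, jc] = [lookup[v] for v in values]
    return out


def classify(data, cpts: CPTSet):
    """Naive-Bayes classification of one record (Series/dict) or a batch
    (DataFrame) into treatment schemes.

    Returns (labels, posteriors): for a batch, a list of labels and an
    (n, n_classes) posterior array, classes ordered as ``cpts.class_states``;
    for a single record, (label, 1-D posterior).  Log-space throughout;
    posterior ties break toward the lowest class index.
    """
    if cpts.class_node is None:
        raise ConfigError("CPTSet was not fitted with a class node")
    single = not isinstance(data, pd.DataFrame)
    df = pd.DataFrame([data]) if single else data
    classes = cpts.class_states
    features = [n for n in cpts.dag.nodes if n != cpts.class_node]
    log_post = np.tile(np.log(cpts.class_priors), (len(df), 1))
    for f in features:
        if f not in df.columns:
            raise ConfigError(f"record lacks feature {f!r}")
        log_post += _feature_log_table(cpts, f, df[f].to_numpy())
    dead = np.all(np.isinf(log_post) & (log_post < 0), axis=1)
    if dead.any():
        raise DomainError(
            f"record(s) {np.where(dead)[0].tolist()}: zero likelihood under "
            f"every class (unseen states with alpha=0)")
    norm = logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post - norm)
    # argmax with ties broken by class index: argmax returns the first max
    idx = np.argmax(np.isclose(log_post, log_post.max(axis=1, keepdims=True),
                               rtol=0, atol=1e-12), axis=1)
    labels = [classes[i] for i in idx]
    if single:
        return labels[0], post[0]
    return labels, post
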