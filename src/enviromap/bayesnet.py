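"""Core Bayesian-network machinery for categorical cohort data.

This module holds the shared data model (:class:`CategoricalDataset`,
:class:`DagStructure`, :class:`ScoreConfig`) and the deterministic
computations every later stage builds on:

* the BDeu marginal-likelihood family score and the decomposable
  DAG log-posterior used to drive the structure random walk,
* Markov-blanket and directed-path queries on a DAG,
* an exhaustive labelled-DAG enumerator usable as an exact-posterior
  oracle on small variable sets.

All variables are discrete; a cohort is an N x V matrix of 0-based level
indices plus per-variable level labels.  The designated target variable
must be binary (a case/control phenotype).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "CategoricalDataset",
    "DagStructure",
    "ScoreConfig",
    "is_acyclic",
    "family_log_score",
    "dag_log_posterior",
    "markov_blanket",
    "directed_path_exists",
    "enumerate_dags",
    "read_cohort_csv",
]


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class CategoricalDataset:
    """A cohort of subjects described by discrete variables.

    Parameters
    ----------
    variable_names
        One identifier per column.
    cardinalities
        Number of levels per variable (each >= 2).
    level_labels
        Ordered label list per variable; ``level_labels[v][k]`` is the
        label of level index ``k`` of variable ``v``.
    values
        N x V integer matrix of 0-based level indices; no missing cells.
    target_index
        Column index of the binary target phenotype.
    group_labels
        Optional mapping variable name -> group tag (used for grouped
        predictive-power analyses and map colouring).
    """

    variable_names: list[str]
    cardinalities: list[int]
    level_labels: list[list[str]]
    values: np.ndarray
    target_index: int
    group_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, v = self.values.shape
        if v != len(self.variable_names):
            raise ValueError("column count does not match variable_names")
        if len(self.cardinalities) != v or len(self.level_labels) != v:
            raise ValueError("cardinalities/level_labels length mismatch")
        if n < 1:
            raise ValueError("dataset must contain at least one row")
        for i, (c, labels) in enumerate(zip(self.cardinalities, self.level_labels)):
            if c < 2:
                raise ValueError(f"variable {self.variable_names[i]!r} has cardinality {c} < 2")
            if len(labels) != c:
                raise ValueError(f"level labels of {self.variable_names[i]!r} do not match cardinality")
        if not (0 <= self.target_index < v):
            raise ValueError("target_index out of range")
        if self.cardinalities[self.target_index] != 2:
            raise ValueError("target variable must be binary")
        lo = self.values.min(axis=0)
        hi = self.values.max(axis=0)
        if lo.min() < 0 or np.any(hi >= np.asarray(self.cardinalities)):
            raise ValueError("cell level index outside its variable's cardinality")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    @property
    def target_name(self) -> str:
        return self.variable_names[self.target_index]

    def index_of(self, name: str) -> int:
        try:
            return self.variable_names.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}") from None

    def level_index(self, variable: str, label: str) -> int:
        v = self.index_of(variable)
        try:
            return self.level_labels[v].index(label)
        except ValueError:
            raise KeyError(f"unknown level {label!r} of variable {variable!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        """Labelled view of the cohort (one column per variable)."""
        cols = {
            name: pd.Categorical.from_codes(self.values[:, i], categories=self.level_labels[i])
            for i, name in enumerate(self.variable_names)
        }
        return pd.DataFrame(cols)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_cohort_csv(
    path: str | Path,
    target: str,
    *,
    sep: str = ",",
    codebook: Mapping[str, Sequence[str]] | str | Path | None = None,
    group_labels: Mapping[str, str] | None = None,
    drop_missing: bool = False,
) -> CategoricalDataset:
    """Read a cohort table (header row = variable names, cells = level labels).

    Levels are mapped to indices by first-appearance order unless an explicit
    ``codebook`` (mapping variable -> ordered level list, or a path to such a
    JSON file) is supplied.  Missing cells are refused unless
    ``drop_missing=True``, in which case rows with any missing cell are
    removed (listwise deletion).
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.isna().any().any():
        if not drop_missing:
            n_bad = int(df.isna().any(axis=1).sum())
            raise ValueError(
                f"{n_bad} rows contain missing cells; missing data is refused "
                "(pass drop_missing=True for listwise deletion)"
            )
        df = df.dropna(axis=0).reset_index(drop=True)
    if target not in df.columns:
        raise KeyError(f"target {target!r} not among columns")
    if isinstance(codebook, (str, Path)):
        codebook = json.loads(Path(codebook).read_text())
    names = list(df.columns)
    level_labels: list[list[str]] = []
    codes = np.empty((len(df), len(names)), dtype=np.int64)
    for i, name in enumerate(names):
        col = df[name].astype(str)
        if codebook is not None and name in codebook:
            labels = [str(x) for x in codebook[name]]
            unknown = set(col.unique()) - set(labels)
            if unknown:
                raise ValueError(f"values {sorted(unknown)} of {name!r} not in codebook")
        else:
            labels = list(dict.fromkeys(col.tolist()))  # first-appearance order
        level_labels.append(labels)
        lut = {lab: k for k, lab in enumerate(labels)}
        codes[:, i] = col.map(lut).to_numpy()
    return CategoricalDataset(
        variable_names=names,
        cardinalities=[len(l) for l in level_labels],
        level_labels=level_labels,
        values=codes,
        target_index=names.index(target),
        group_labels=dict(group_labels) if group_labels else None,
    )


@dataclass(frozen=True)
class DagStructure:
    """A directed acyclic graph over variable indices.

    ``edges`` is a frozenset of (parent, child) pairs.  Instances are
    hashable so sample sets can count distinct structures cheaply.
    """

    n_vars: int
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(self.edges))
        for (u, v) in self.edges:
            if u == v:
                raise ValueError("self-loop edge")
            if not (0 <= u < self.n_vars and 0 <= v < self.n_vars):
                raise ValueError(f"edge ({u},{v}) references invalid node index")

    def parents(self, node: int) -> set[int]:
        return {u for (u, v) in self.edges if v == node}

    def children(self, node: int) -> set[int]:
        return {v for (u, v) in self.edges if u == node}

    def parent_sets(self) -> list[tuple[int, ...]]:
        """Sorted parent tuple per node (the score's sufficient structure)."""
        ps: list[list[int]] = [[] for _ in range(self.n_vars)]
        for (u, v) in self.edges:
            ps[v].append(u)
        return [tuple(sorted(s)) for s in ps]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_vars, self.n_vars), dtype=bool)
        for (u, v) in self.edges:
            a[u, v] = True
        return a

    def with_edges(self, edges: Iterable[tuple[int, int]]) -> "DagStructure":
        return DagStructure(self.n_vars, frozenset(edges))


def _reachability(adj: np.ndarray) -> np.ndarray:
    """Boolean matrix R with R[i, j] = a directed path i -> ... -> j exists.

    Repeated boolean squaring; irreflexive unless the graph has a cycle
    through the node.
    """
    r = adj.copy()
    while True:
        nxt = r | (r @ r)
        if np.array_equal(nxt, r):
            return r
        r = nxt


def is_acyclic(dag: DagStructure) -> bool:
    """True iff the structure has no directed cycle."""
    if not dag.edges:
        return True
    r = _reachability(dag.adjacency())
    return not bool(np.any(np.diag(r)))


# ---------------------------------------------------------------------------
# BDeu scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreConfig:
    """Structure-score settings.

    equivalent_sample_size
        Total Dirichlet prior mass (ESS); spread uniformly over the child's
        levels and parent configurations (BDeu), which makes Markov-equivalent
        DAGs score identically.
    max_parents
        Hard cap on any node's parent-set size.
    structure_prior
        Only ``"uniform"`` is supported; a uniform prior contributes a
        constant and is dropped from the log-posterior.
    """

    equivalent_sample_size: float = 1.0
    max_parents: int = 5
    structure_prior: str = "uniform"

    def __post_init__(self) -> None:
        if self.equivalent_sample_size <= 0:
            raise ValueError("equivalent_sample_size must be positive")
        if self.max_parents < 0:
            raise ValueError("max_parents must be >= 0")
        if self.structure_prior != "uniform":
            raise ValueError("only the uniform structure prior is supported")


def family_log_score(
    data: CategoricalDataset,
    child: int,
    parents: Sequence[int],
    cfg: ScoreConfig,
) -> float:
    """Log BDeu marginal likelihood of ``child`` given a parent set.

    With r child levels, q parent configurations, counts N_jk and Dirichlet
    hyperparameters a_jk = ESS/(r*q):

        sum_j [ lnG(a_j) - lnG(a_j + N_j) + sum_k ( lnG(a_jk + N_jk) - lnG(a_jk) ) ]

    The value depends only on the (child, parents) contingency counts, so the
    full DAG score decomposes over families.
    """
    parents = tuple(sorted(parents))
    if child in parents:
        raise ValueError("child cannot be its own parent")
    if len(parents) > cfg.max_parents:
        raise ValueError(
            f"parent set of size {len(parents)} exceeds max_parents={cfg.max_parents}"
        )
    r = data.cardinalities[child]
    q = 1
    for p in parents:
        q *= data.cardinalities[p]
    n = data.n_rows
    if n == 0:
        return 0.0
    # contingency counts: rows indexed by (parent config, child level)
    code = data.values[:, child].copy()
    stride = r
    for p in parents:
        code += data.values[:, p] * stride
        stride *= data.cardinalities[p]
    counts = np.bincount(code, minlength=r * q).reshape(q, r)
    a_jk = cfg.equivalent_sample_size / (r * q)
    a_j = cfg.equivalent_sample_size / q
    n_j = counts.sum(axis=1)
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j))
        + np.sum(gammaln(a_jk + counts) - gammaln(a_jk))
    )
    return score


def dag_log_posterior(
    data: CategoricalDataset, dag: DagStructure, cfg: ScoreConfig
) -> float:
    """Unnormalised log posterior of a structure: sum of family scores.

    The uniform structure prior contributes a constant that cancels in every
    posterior ratio and is omitted.  Raises on cyclic input.
    """
    if not is_acyclic(dag):
        raise ValueError("structure contains a directed cycle")
    ps = dag.parent_sets()
    return sum(family_log_score(data, v, ps[v], cfg) for v in range(dag.n_vars))


# ---------------------------------------------------------------------------
# Graph queries
# ---------------------------------------------------------------------------

def markov_blanket(dag: DagStructure, target: int) -> set[int]:
    """Parents, children, and co-parents (spouses) of ``target``."""
    if not (0 <= target < dag.n_vars):
        raise ValueError("target index out of range")
    pa = dag.parents(target)
    ch = dag.children(target)
    spouses: set[int] = set()
    for c in ch:
        spouses |= dag.parents(c)
    mb = pa | ch | spouses
    mb.discard(target)
    return mb


def directed_path_exists(
    dag: DagStructure, src: int, dst: int, min_intermediaries: int = 0
) -> bool:
    """True iff a directed path src => dst has >= ``min_intermediaries``
    internal nodes (so ``min_intermediaries=1`` excludes the direct edge)."""
    if src == dst:
        raise ValueError("src and dst must differ")
    # BFS tracking minimum edge count; a path with k edges has k-1 internal
    # nodes.  DAG, so shortest-path BFS suffices: if the shortest path is
    # short, a longer one may still satisfy the bound — enumerate longest?
    # In a DAG the *longest* path matters for the lower bound; do a DP.
    adj = [sorted(dag.children(u)) for u in range(dag.n_vars)]
    if min_intermediaries <= 0:
        # plain reachability
        seen = {src}
        stack = [src]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v == dst:
                    return True
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False
    # longest directed path from src to dst (edge count), -inf if unreachable
    order = _topological_order(dag)
    longest = {src: 0}
    for u in order:
        if u not in longest:
            continue
        for v in adj[u]:
            if longest.get(v, -1) < longest[u] + 1:
                longest[v] = longest[u] + 1
    return dst in longest and longest[dst] - 1 >= min_intermediaries


def _topological_order(dag: DagStructure) -> list[int]:
    indeg = [0] * dag.n_vars
    for (_, v) in dag.edges:
        indeg[v] += 1
    adj = [sorted(dag.children(u)) for u in range(dag.n_vars)]
    queue = [u for u in range(dag.n_vars) if indeg[u] == 0]
    out: list[int] = []
    while queue:
        u = queue.pop()
        out.append(u)
        for v in adj[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                queue.append(v)
    if len(out) != dag.n_vars:
        raise ValueError("graph contains a directed cycle")
    return out


# ---------------------------------------------------------------------------
# Exhaustive enumeration (exact-posterior oracle)
# ---------------------------------------------------------------------------

_MAX_ENUM_VARS = 5


def enumerate_dags(n_vars: int) -> Iterator[DagStructure]:
    """Yield every labelled DAG on ``n_vars`` nodes exactly once.

    Each unordered node pair is assigned one of {no edge, ->, <-}; candidates
    with directed cycles are discarded.  Counts follow the labelled-DAG
    sequence 1, 3, 25, 543, 29281 for n = 1..5.  Guarded to n <= 5.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if n_vars > _MAX_ENUM_VARS:
        raise ValueError(f"enumeration limited to n_vars <= {_MAX_ENUM_VARS}")
    pairs = list(itertools.combinations(range(n_vars), 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (u, v), s in zip(pairs, states):
            if s == 1:
                edges.append((u, v))
            elif s == 2:
                edges.append((v, u))
        dag = DagStructure(n_vars, frozenset(edges))
        if is_acyclic(dag):
            yield dag
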