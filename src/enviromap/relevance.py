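"""Model-averaged relevance quantities over a structure sample set.

Given MCMC-sampled DAGs, this module estimates the posterior of the
relationship patterns used to read an "envirome" map:

* **edge posteriors** — probability of an edge joining two variables in
  either direction (direction-blind, since edge-direction information is
  pooled over the Markov equivalence class);
* **DIR / TRN** — direct (edge-adjacent) versus transitive (connected only
  through >= 1 intermediary on a directed path) relationship to the target;
* **strong relevance** — Markov-blanket membership, decomposed into a direct
  part (edge adjacency) and an interaction-term part (spouse-only
  membership), with p_relevance = p_direct + p_interaction by construction;
* **ranked Markov-blanket sets** — the most probable strongly relevant
  variable sets;
* **group relevance** — membership of the union of several targets'
  Markov blankets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .bayesnet import DagStructure, directed_path_exists, markov_blanket
from .mcmc import StructureSampleSet

__all__ = [
    "EdgePosteriorMatrix",
    "RelevanceReport",
    "edge_posteriors",
    "classify_pair",
    "relationship_posteriors",
    "strong_relevance",
    "mb_set_posteriors",
    "group_relevance",
    "build_relevance_report",
    "export_map_graphml",
    "export_map_dot",
]


@dataclass
class EdgePosteriorMatrix:
    """Symmetric matrix of direction-blind edge posteriors."""

    matrix: np.ndarray
    display_threshold: float = 0.5

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("entries must lie in [0, 1]")
        self.matrix = m


def edge_posteriors(
    samples: StructureSampleSet, display_threshold: float = 0.5
) -> EdgePosteriorMatrix:
    """Fraction of samples containing an edge i->j or j->i, per pair."""
    if len(samples) == 0:
        raise ValueError("empty sample set")
    v = samples.n_vars
    counts = np.zeros((v, v))
    for g, mult in samples.counted():
        for (a, b) in g.edges:
            counts[a, b] += mult
    sym = counts + counts.T
    return EdgePosteriorMatrix(sym / len(samples), display_threshold)


def classify_pair(dag: DagStructure, x: int, y: int) -> str:
    """Relationship of a variable pair in one structure.

    ``"direct"`` if an edge joins x and y in either direction; otherwise
    ``"transitive"`` if a directed path with at least one intermediary runs
    x => y or y => x; otherwise ``"none"``.  Mutually exclusive by
    construction (adjacency wins).
    """
    if x == y:
        raise ValueError("x and y must differ")
    if (x, y) in dag.edges or (y, x) in dag.edges:
        return "direct"
    if directed_path_exists(dag, x, y, min_intermediaries=1) or directed_path_exists(
        dag, y, x, min_intermediaries=1
    ):
        return "transitive"
    return "none"


def relationship_posteriors(
    samples: StructureSampleSet, target: int
) -> pd.DataFrame:
    """Per-variable DIR/TRN posteriors with respect to ``target``.

    One row per non-target variable with columns ``p_direct`` and
    ``p_transitive``; per sample the pair is classified exclusively, so
    p_direct + p_transitive <= 1.
    """
    v = samples.n_vars
    n = len(samples)
    p_dir = np.zeros(v)
    p_trn = np.zeros(v)
    for g, mult in samples.counted():
        for x in range(v):
            if x == target:
                continue
            tag = classify_pair(g, x, target)
            if tag == "direct":
                p_dir[x] += mult
            elif tag == "transitive":
                p_trn[x] += mult
    rows = [
        {"variable": x, "p_direct": p_dir[x] / n, "p_transitive": p_trn[x] / n}
        for x in range(v)
        if x != target
    ]
    return pd.DataFrame(rows).set_index("variable")


def strong_relevance(samples: StructureSampleSet, target: int) -> pd.DataFrame:
    """Posterior of Markov-blanket membership, split direct vs interaction.

    Per sample a variable in the target's Markov blanket counts as *direct*
    when edge-adjacent to the target and as an *interaction term* when a
    spouse only (co-parent of a common child, no adjacency).  The posterior
    of strong relevance is the sum of the two parts.
    """
    v = samples.n_vars
    n = len(samples)
    p_dir = np.zeros(v)
    p_int = np.zeros(v)
    for g, mult in samples.counted():
        adjacent = g.parents(target) | g.children(target)
        for x in markov_blanket(g, target):
            if x in adjacent:
                p_dir[x] += mult
            else:
                p_int[x] += mult
    rows = []
    for x in range(v):
        if x == target:
            continue
        d, i = p_dir[x] / n, p_int[x] / n
        rows.append(
            {"variable": x, "p_direct": d, "p_interaction": i, "p_relevance": d + i}
        )
    return pd.DataFrame(rows).set_index("variable")


def mb_set_posteriors(
    samples: StructureSampleSet,
    target: int,
    top_k: int = 4,
    names: Sequence[str] | None = None,
) -> list[tuple[tuple, float]]:
    """The ``top_k`` most probable strongly relevant variable sets.

    The target's Markov blanket is extracted from every sample; distinct
    sets are ranked by frequency, ties broken by smaller set size then by
    lexicographic order of the (name or index) tuple.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    freq: dict[frozenset[int], int] = {}
    for g, mult in samples.counted():
        mb = frozenset(markov_blanket(g, target))
        freq[mb] = freq.get(mb, 0) + mult
    n = len(samples)

    def label(s: frozenset[int]) -> tuple:
        if names is None:
            return tuple(sorted(s))
        return tuple(sorted(names[i] for i in s))

    ranked = sorted(
        ((label(s), c / n) for s, c in freq.items()),
        key=lambda item: (-item[1], len(item[0]), item[0]),
    )
    return ranked[:top_k]


def group_relevance(
    samples: StructureSampleSet, targets: Iterable[int]
) -> pd.DataFrame:
    """Relevance with respect to a *group* of targets.

    Per sample a variable is relevant iff it belongs to the union of the
    targets' Markov blankets; the average over samples is a single posterior
    of relevance per variable.  Target variables themselves are excluded
    from the report rows.
    """
    targets = set(targets)
    if not targets:
        raise ValueError("need at least one target")
    v = samples.n_vars
    n = len(samples)
    p_rel = np.zeros(v)
    for g, mult in samples.counted():
        union: set[int] = set()
        for t in targets:
            union |= markov_blanket(g, t)
        for x in union - targets:
            p_rel[x] += mult
    rows = [
        {"variable": x, "p_relevance": p_rel[x] / n}
        for x in range(v)
        if x not in targets
    ]
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class RelevanceReport:
    """Bundle of the per-variable posteriors and ranked MB sets for one
    target, with variable names resolved."""

    target: str
    table: pd.DataFrame  # per-variable p_direct, p_transitive, p_interaction, p_relevance
    mb_sets: list[tuple[tuple, float]] = field(default_factory=list)

    def dir_trn_table(self) -> pd.DataFrame:
        """DIR/TRN posterior layout (per-variable two-column table)."""
        return self.table[["p_direct_trn", "p_transitive"]].rename(
            columns={"p_direct_trn": "DIR", "p_transitive": "TRN"}
        )

    def strong_relevance_table(self, cutoff: float = 0.0) -> pd.DataFrame:
        """Direct relation / interaction term / relevance layout, sorted by
        relevance, optionally filtered by a cutoff."""
        t = self.table[["p_direct", "p_interaction", "p_relevance"]].rename(
            columns={
                "p_direct": "direct_relation",
                "p_interaction": "interaction_term",
                "p_relevance": "relevance",
            }
        )
        t = t[t["relevance"] >= cutoff]
        return t.sort_values("relevance", ascending=False)

    def mb_sets_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"rank": r + 1, "set": ", ".join(map(str, s)), "posterior": p}
                for r, (s, p) in enumerate(self.mb_sets)
            ]
        )


def build_relevance_report(
    samples: StructureSampleSet,
    target: int,
    names: Sequence[str],
    top_k: int = 4,
) -> RelevanceReport:
    """Assemble all per-variable posteriors for one target.

    The DIR/TRN classification and the strong-relevance decomposition use
    the same per-sample adjacency notion, so the two direct columns agree;
    both are kept (``p_direct`` alongside ``p_direct_trn``) for the two
    table layouts.
    """
    dir_trn = relationship_posteriors(samples, target)
    rel = strong_relevance(samples, target)
    table = rel.join(dir_trn.rename(columns={"p_direct": "p_direct_trn"}))
    table.index = [names[i] for i in table.index]
    table.index.name = "variable"
    mb = mb_set_posteriors(samples, target, top_k=top_k, names=names)
    return RelevanceReport(target=names[target], table=table, mb_sets=mb)


# ---------------------------------------------------------------------------
# Map export
# ---------------------------------------------------------------------------

def _map_graph(
    edges: EdgePosteriorMatrix,
    names: Sequence[str],
    groups: dict[str, str] | None = None,
) -> nx.Graph:
    g = nx.Graph()
    for i, name in enumerate(names):
        g.add_node(name, group=(groups or {}).get(name, ""))
    v = edges.matrix.shape[0]
    thr = edges.display_threshold
    for i in range(v):
        for j in range(i + 1, v):
            p = float(edges.matrix[i, j])
            if p >= thr:
                g.add_edge(names[i], names[j], posterior=p, width=p)
    return g


def export_map_graphml(
    edges: EdgePosteriorMatrix,
    names: Sequence[str],
    path: str | Path,
    groups: dict[str, str] | None = None,
) -> None:
    """Write the dependency map as GraphML; edges below the display
    threshold are omitted, edge width attribute equals the posterior."""
    nx.write_graphml(_map_graph(edges, names, groups), str(path))


def export_map_dot(
    edges: EdgePosteriorMatrix,
    names: Sequence[str],
    path: str | Path,
    groups: dict[str, str] | None = None,
) -> None:
    """Write the dependency map in DOT format (plain text)."""
    g = _map_graph(edges, names, groups)
    lines = ["graph envirome {"]
    for node, attrs in g.nodes(data=True):
        grp = attrs.get("group", "")
        lines.append(f'  "{node}" [group="{grp}"];')
    for u, v, attrs in g.edges(data=True):
        p = attrs["posterior"]
        lines.append(f'  "{u}" -- "{v}" [weight={p:.3f}, penwidth={1 + 4 * p:.2f}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
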