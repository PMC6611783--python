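"""Metropolis–Hastings random walk over DAG structures.

The sampler walks the space of directed acyclic graphs with three single-edge
operators — insert, delete, invert — proposing uniformly from the set of
valid moves and correcting acceptance with the ratio of neighbourhood sizes.
The walk is driven by the unnormalised structure log-posterior
(:func:`enviromap.bayesnet.dag_log_posterior`), evaluated incrementally
through a family-score cache: a single-edge move touches at most two
node families, so only those scores are recomputed.

Several independent chains are run from deterministically derived seeds; the
pooled post-burn-in, thinned samples form a :class:`StructureSampleSet` for
model averaging, and :func:`convergence_report` compares per-edge posteriors
across chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bayesnet import (
    CategoricalDataset,
    DagStructure,
    ScoreConfig,
    _reachability,
    family_log_score,
    is_acyclic,
)

__all__ = [
    "McmcConfig",
    "StructureSampleSet",
    "propose",
    "run_chain",
    "convergence_report",
]

# move codes
_INSERT, _DELETE, _INVERT = 0, 1, 2


@dataclass(frozen=True)
class McmcConfig:
    """Random-walk settings.

    ``burn_in_steps`` samples are discarded before collection and every
    ``thinning``-th subsequent state is kept.  ``n_chains`` independent
    chains are run from per-chain seeds derived from ``seed``.
    """

    n_steps: int = 200_000
    burn_in_steps: int = 100_000
    thinning: int = 10
    n_chains: int = 4
    seed: int = 0
    score_cfg: ScoreConfig = field(default_factory=ScoreConfig)
    random_init: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in_steps < self.n_steps):
            raise ValueError("require 0 <= burn_in_steps < n_steps")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class StructureSampleSet:
    """Pooled MCMC output: parallel lists of sampled DAGs, their
    unnormalised log posteriors and originating chain ids."""

    samples: list[DagStructure]
    log_scores: list[float]
    chain_ids: list[int]
    meta: McmcConfig | None = None

    def __post_init__(self) -> None:
        if not (len(self.samples) == len(self.log_scores) == len(self.chain_ids)):
            raise ValueError("samples/log_scores/chain_ids must be parallel")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_vars(self) -> int:
        if not self.samples:
            raise ValueError("empty sample set")
        return self.samples[0].n_vars

    def counted(self) -> list[tuple[DagStructure, int]]:
        """Distinct structures with multiplicities (model-averaging helper)."""
        counts: dict[DagStructure, int] = {}
        for g in self.samples:
            counts[g] = counts.get(g, 0) + 1
        return list(counts.items())

    def save_jsonl(self, path: str | Path) -> None:
        """One sample per line: edge list, log score, chain id."""
        with open(path, "w") as fh:
            for g, s, c in zip(self.samples, self.log_scores, self.chain_ids):
                rec = {
                    "n_vars": g.n_vars,
                    "edges": sorted(map(list, g.edges)),
                    "log_score": s,
                    "chain": c,
                }
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def load_jsonl(cls, path: str | Path) -> "StructureSampleSet":
        samples, scores, chains = [], [], []
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                samples.append(
                    DagStructure(rec["n_vars"], frozenset(map(tuple, rec["edges"])))
                )
                scores.append(float(rec["log_score"]))
                chains.append(int(rec["chain"]))
        return cls(samples, scores, chains)


# ---------------------------------------------------------------------------
# Neighbourhood enumeration
# ---------------------------------------------------------------------------

def _move_masks(adj: np.ndarray, max_parents: int):
    """Valid single-edge moves from the DAG with adjacency ``adj``.

    Returns boolean matrices (insert, delete, invert); ``insert[i, j]`` means
    adding i->j keeps the graph a DAG and within the parent cap, and
    ``invert[i, j]`` means flipping the existing edge i->j does.
    """
    v = adj.shape[0]
    reach = _reachability(adj)
    eye = np.eye(v, dtype=bool)
    n_parents = adj.sum(axis=0)
    # insert i->j: edge absent, no path j=>i (covers the reverse edge), cap ok
    can_insert = ~adj & ~reach.T & ~eye & (n_parents < max_parents)[None, :]
    can_delete = adj
    # invert i->j: valid iff no alternative directed path i=>j of length >= 2
    # (in a DAG such a path cannot revisit i, hence cannot use edge i->j);
    # counted via first-hop decomposition, subtracting the direct edge.
    ai = adj.astype(np.int64)
    paths = ai @ (reach.astype(np.int64) + np.eye(v, dtype=np.int64))
    has_alt = (paths - ai) >= 1
    can_invert = adj & ~has_alt & (n_parents < max_parents)[:, None]
    return can_insert, can_delete, can_invert


def _neighbourhood_size(adj: np.ndarray, max_parents: int) -> int:
    ins, dele, inv = _move_masks(adj, max_parents)
    return int(ins.sum() + dele.sum() + inv.sum())


def _apply_move(adj: np.ndarray, op: int, i: int, j: int) -> None:
    if op == _INSERT:
        adj[i, j] = True
    elif op == _DELETE:
        adj[i, j] = False
    else:  # invert
        adj[i, j] = False
        adj[j, i] = True


def propose(
    dag: DagStructure, rng: np.random.Generator, *, max_parents: int = 5
) -> tuple[DagStructure, float]:
    """Draw one candidate uniformly from the single-edge-move neighbourhood.

    Returns the candidate and the log Hastings correction
    ``log |N(current)| - log |N(candidate)|``.  A structure with no valid
    move (single node) proposes itself with correction 0.
    """
    if not is_acyclic(dag):
        raise ValueError("current structure must be acyclic")
    adj = dag.adjacency()
    ins, dele, inv = _move_masks(adj, max_parents)
    moves = _stack_moves(ins, dele, inv)
    if len(moves) == 0:
        return dag, 0.0
    op, i, j = moves[rng.integers(len(moves))]
    cand_adj = adj.copy()
    _apply_move(cand_adj, op, i, j)
    correction = float(
        np.log(len(moves)) - np.log(_neighbourhood_size(cand_adj, max_parents))
    )
    cand = DagStructure(dag.n_vars, _edge_set(cand_adj))
    return cand, correction


def _edge_set(adj: np.ndarray) -> frozenset[tuple[int, int]]:
    return frozenset((int(a), int(b)) for a, b in np.argwhere(adj))


def _stack_moves(ins: np.ndarray, dele: np.ndarray, inv: np.ndarray) -> np.ndarray:
    parts = []
    for op, mask in ((_INSERT, ins), (_DELETE, dele), (_INVERT, inv)):
        idx = np.argwhere(mask)
        if len(idx):
            parts.append(
                np.column_stack([np.full(len(idx), op, dtype=np.int64), idx])
            )
    if not parts:
        return np.empty((0, 3), dtype=np.int64)
    return np.concatenate(parts, axis=0)


# ---------------------------------------------------------------------------
# The chain
# ---------------------------------------------------------------------------

class _ScoreCache:
    """Memoised family scores keyed by (child, sorted parent tuple)."""

    def __init__(self, data: CategoricalDataset, cfg: ScoreConfig):
        self._data = data
        self._cfg = cfg
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def __call__(self, child: int, parents: tuple[int, ...]) -> float:
        key = (child, parents)
        val = self._cache.get(key)
        if val is None:
            val = family_log_score(self._data, child, parents, self._cfg)
            self._cache[key] = val
        return val


def _parents_tuple(adj: np.ndarray, node: int) -> tuple[int, ...]:
    return tuple(np.flatnonzero(adj[:, node]))


def _random_dag(n_vars: int, rng: np.random.Generator, max_parents: int) -> np.ndarray:
    """Sparse random DAG consistent with a random topological order."""
    order = rng.permutation(n_vars)
    adj = np.zeros((n_vars, n_vars), dtype=bool)
    for pos in range(1, n_vars):
        j = order[pos]
        k = min(int(rng.integers(0, max_parents + 1)), pos)
        if k:
            for i in rng.choice(order[:pos], size=k, replace=False):
                adj[i, j] = True
    return adj


def run_chain(data: CategoricalDataset, cfg: McmcConfig) -> StructureSampleSet:
    """Run ``cfg.n_chains`` independent Metropolis–Hastings chains.

    Acceptance probability for candidate G' from G is

        min(1, exp(score(G') - score(G)) * |N(G)| / |N(G')|)

    with N the valid single-edge-move neighbourhood.  Chains start from the
    empty DAG (or a random DAG when ``cfg.random_init``), discard
    ``burn_in_steps`` states and keep every ``thinning``-th state after.
    Fully reproducible: chain seeds derive from ``cfg.seed``.
    """
    v = data.n_vars
    mp = cfg.score_cfg.max_parents
    cache = _ScoreCache(data, cfg.score_cfg)
    all_samples: list[DagStructure] = []
    all_scores: list[float] = []
    all_chains: list[int] = []
    chain_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    for chain_id in range(cfg.n_chains):
        rng = np.random.default_rng(chain_seeds[chain_id])
        if cfg.random_init:
            adj = _random_dag(v, rng, mp)
        else:
            adj = np.zeros((v, v), dtype=bool)
        fam = [cache(x, _parents_tuple(adj, x)) for x in range(v)]
        total = float(sum(fam))
        n_curr = _neighbourhood_size(adj, mp)
        for step in range(cfg.n_steps):
            if n_curr > 0:
                ins, dele, inv = _move_masks(adj, mp)
                moves = _stack_moves(ins, dele, inv)
                op, i, j = moves[rng.integers(len(moves))]
                cand = adj.copy()
                _apply_move(cand, op, i, j)
                # only the touched families change score
                delta = cache(j, _parents_tuple(cand, j)) - fam[j]
                if op == _INVERT:
                    delta += cache(i, _parents_tuple(cand, i)) - fam[i]
                n_cand = _neighbourhood_size(cand, mp)
                log_alpha = delta + np.log(n_curr) - np.log(n_cand)
                if log_alpha >= 0 or rng.random() < np.exp(log_alpha):
                    adj = cand
                    fam[j] = cache(j, _parents_tuple(adj, j))
                    if op == _INVERT:
                        fam[i] = cache(i, _parents_tuple(adj, i))
                    total += float(delta)
                    n_curr = n_cand
            if step >= cfg.burn_in_steps and (step - cfg.burn_in_steps) % cfg.thinning == 0:
                g = DagStructure(v, _edge_set(adj))
                all_samples.append(g)
                all_scores.append(total)
                all_chains.append(chain_id)
    return StructureSampleSet(all_samples, all_scores, all_chains, meta=cfg)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def convergence_report(
    samples: StructureSampleSet, tolerance: float = 0.05
) -> pd.DataFrame:
    """Cross-chain agreement of pooled (direction-blind) edge posteriors.

    One row per variable pair: the per-chain posterior of an edge joining the
    pair in either direction, the maximum absolute cross-chain difference,
    and a flag when it exceeds ``tolerance``.  Requires >= 2 chains.
    """
    chains = sorted(set(samples.chain_ids))
    if len(chains) < 2:
        raise ValueError("convergence report requires at least two chains")
    v = samples.n_vars
    counts = {c: np.zeros((v, v)) for c in chains}
    totals = {c: 0 for c in chains}
    for g, c in zip(samples.samples, samples.chain_ids):
        totals[c] += 1
        for (a, b) in g.edges:
            lo, hi = (a, b) if a < b else (b, a)
            counts[c][lo, hi] += 1
    rows = []
    for i in range(v):
        for j in range(i + 1, v):
            per_chain = [counts[c][i, j] / totals[c] for c in chains]
            spread = max(per_chain) - min(per_chain)
            rows.append(
                {"var_i": i, "var_j": j,
                 **{f"chain_{c}": p for c, p in zip(chains, per_chain)},
                 "max_diff": spread, "flagged": spread > tolerance}
            )
    return pd.DataFrame(rows)
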