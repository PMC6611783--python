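"""Ground-truth synthetic cohorts from a known categorical Bayesian network.

The default network emulates the architecture of an envirome of a rare
binary phenotype: a small set of *core* variables directly connected to the
target — two 3-level severity scores (current-symptom- and trait-like), one
binary parental-history variable and one binary metabolic variable — plus a
spouse-type interaction pattern (a root variable with no marginal effect on
the target sharing a common child with it), a periphery of variables
reached only through the severity mediators, and a few independent
background distractors.  The target's conditional table is logistic in its
parents with conditional odds ratios in the 2–10 range, and the intercept
is calibrated by bisection so the *exact* marginal case prevalence (computed
by enumeration over the target's ancestors) matches the requested value
(default 5.2%).

Because the generating structure is known, every pipeline stage has an
answer key: :func:`spec_to_truth_tables` labels each variable as direct /
transitive / interaction / none with respect to the target.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bayesnet import (
    CategoricalDataset,
    DagStructure,
    _topological_order,
    directed_path_exists,
    markov_blanket,
)

__all__ = [
    "GroundTruthSpec",
    "default_envirome_spec",
    "exact_target_prevalence",
    "sample_cohort",
    "plant_interaction",
    "spec_to_truth_tables",
]


@dataclass
class GroundTruthSpec:
    """A fully specified categorical Bayesian network BN(G, theta).

    ``cpts[v]`` has shape (q_v, r_v): one row per configuration of v's
    *sorted* parent set (lowest-index parent cycling fastest, matching the
    scoring module's contingency layout), each row a distribution over v's
    levels.
    """

    variable_names: list[str]
    cardinalities: list[int]
    level_labels: list[list[str]]
    dag: DagStructure
    cpts: dict[int, np.ndarray]
    target_index: int
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = len(self.variable_names)
        if self.dag.n_vars != v or len(self.cardinalities) != v:
            raise ValueError("dimension mismatch between names, cardinalities and DAG")
        ps = self.dag.parent_sets()
        for node in range(v):
            q = int(np.prod([self.cardinalities[p] for p in ps[node]])) if ps[node] else 1
            cpt = np.asarray(self.cpts[node], dtype=float)
            if cpt.shape != (q, self.cardinalities[node]):
                raise ValueError(
                    f"CPT of {self.variable_names[node]!r} has shape {cpt.shape}, "
                    f"expected {(q, self.cardinalities[node])}"
                )
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {self.variable_names[node]!r} must sum to 1")
            self.cpts[node] = cpt

    @property
    def n_vars(self) -> int:
        return len(self.variable_names)

    def index_of(self, name: str) -> int:
        return self.variable_names.index(name)

    def save_json(self, path: str | Path) -> None:
        rec = {
            "variable_names": self.variable_names,
            "cardinalities": self.cardinalities,
            "level_labels": self.level_labels,
            "edges": sorted(map(list, self.dag.edges)),
            "cpts": {str(k): v.tolist() for k, v in self.cpts.items()},
            "target_index": self.target_index,
            "group_labels": self.group_labels,
        }
        Path(path).write_text(json.dumps(rec, indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "GroundTruthSpec":
        rec = json.loads(Path(path).read_text())
        return cls(
            variable_names=rec["variable_names"],
            cardinalities=rec["cardinalities"],
            level_labels=rec["level_labels"],
            dag=DagStructure(len(rec["variable_names"]),
                             frozenset(map(tuple, rec["edges"]))),
            cpts={int(k): np.asarray(v) for k, v in rec["cpts"].items()},
            target_index=rec["target_index"],
            group_labels=rec.get("group_labels", {}),
        )


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


# conditional odds ratios of the target's logistic CPT (per parent level,
# relative to the lowest level); chosen in the 2-10 range so that structure
# recovery at n = 20,000 is reliable despite the rare target
_CORE_BETAS = {
    "depressive_symptoms": [0.0, np.log(2.41), np.log(10.66)],
    "neuroticism": [0.0, np.log(3.44), np.log(9.26)],
    "parental_depression": [0.0, np.log(4.0)],
    "body_fat": [0.0, np.log(3.0)],
}
_CORE_MARGINALS = {
    "depressive_symptoms": [0.60, 0.30, 0.10],
    "neuroticism": [0.50, 0.35, 0.15],
    "parental_depression": [0.85, 0.15],
    "body_fat": [0.70, 0.30],
}
_THREE_LEVELS = ["low", "moderate", "high"]


def default_envirome_spec(
    target_prevalence: float = 0.052, n_peripheral: int = 20
) -> GroundTruthSpec:
    """The default ground-truth network.

    Node order: the four core variables (0-3), the binary target (4), the
    spouse-type root (5) and its collider child (6), two upstream ancestors
    feeding the severity cores (7-8, true *transitive* variables), then
    ``n_peripheral`` peripheral variables.  Three of every four peripherals
    are mediated children of a severity core; every fourth is an independent
    background distractor (d-separated from the target).
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target_prevalence must be in (0, 1)")
    if n_peripheral < 0:
        raise ValueError("n_peripheral must be >= 0")

    names = ["depressive_symptoms", "neuroticism", "parental_depression", "body_fat"]
    cards = [3, 3, 2, 2]
    labels: list[list[str]] = [_THREE_LEVELS, _THREE_LEVELS, ["no", "yes"], ["normal", "high"]]
    groups = {
        "depressive_symptoms": "mental_health",
        "neuroticism": "mental_health",
        "parental_depression": "parental_illness",
        "body_fat": "diet_metabolism",
    }
    edges: set[tuple[int, int]] = set()
    cpts: dict[int, np.ndarray] = {}
    # severity cores are conditioned on one upstream ancestor each (added
    # below as indices 7 and 8); the other two cores are roots
    p_stress, p_low_income = 0.30, 0.40
    sympt_cpt = np.asarray([[0.65, 0.28, 0.07], [0.45, 0.35, 0.20]])  # by life stress
    neuro_cpt = np.asarray([[0.55, 0.33, 0.12], [0.40, 0.38, 0.22]])  # by low income
    cpts[0] = sympt_cpt
    cpts[1] = neuro_cpt
    cpts[2] = np.asarray([_CORE_MARGINALS["parental_depression"]])
    cpts[3] = np.asarray([_CORE_MARGINALS["body_fat"]])
    core_marginals = [
        ((1 - p_stress) * sympt_cpt[0] + p_stress * sympt_cpt[1]).tolist(),
        ((1 - p_low_income) * neuro_cpt[0] + p_low_income * neuro_cpt[1]).tolist(),
        _CORE_MARGINALS["parental_depression"],
        _CORE_MARGINALS["body_fat"],
    ]

    target = len(names)  # index 4
    names.append("lifetime_depression")
    cards.append(2)
    labels.append(["no", "yes"])
    groups["lifetime_depression"] = "target"
    for i in range(4):
        edges.add((i, target))
    # logistic CPT over the sorted core parent set (0,1,2,3); parent 0
    # cycles fastest in the row index.  The four cores are mutually
    # independent (disjoint ancestries), so the product of their marginals
    # is their exact joint and the intercept calibration is exact.
    beta_lists = [_CORE_BETAS[n] for n in names[:4]]
    intercept = _calibrate_intercept(beta_lists, core_marginals, target_prevalence)
    rows = []
    for combo in itertools.product(*[range(c) for c in reversed(cards[:4])]):
        combo = tuple(reversed(combo))  # parent 0 fastest
        p1 = _sigmoid(intercept + sum(b[k] for b, k in zip(beta_lists, combo)))
        rows.append([1.0 - p1, p1])
    cpts[target] = np.asarray(rows)

    # spouse-type interaction pattern: risk_taking -> bipolar_disorder <- target
    spouse = len(names)
    names.append("risk_taking")
    cards.append(2)
    labels.append(["no", "yes"])
    groups["risk_taking"] = "mental_health"
    cpts[spouse] = np.asarray([[0.5, 0.5]])
    child = len(names)
    names.append("bipolar_disorder")
    cards.append(2)
    labels.append(["no", "yes"])
    groups["bipolar_disorder"] = "mental_health"
    edges.add((target, child))
    edges.add((spouse, child))
    # rows over (target, spouse) with target (lower index) cycling fastest:
    # (t=0,s=0), (t=1,s=0), (t=0,s=1), (t=1,s=1)
    p_child = [0.05, 0.30, 0.10, 0.85]
    cpts[child] = np.asarray([[1 - p, p] for p in p_child])

    # upstream ancestors: true transitive variables reaching the target
    # only through a severity mediator
    stress = len(names)
    names.append("life_stress")
    cards.append(2)
    labels.append(["no", "yes"])
    groups["life_stress"] = "life_stress"
    edges.add((stress, 0))
    cpts[stress] = np.asarray([[1 - p_stress, p_stress]])
    income = len(names)
    names.append("household_income")
    cards.append(2)
    labels.append(["adequate", "low"])
    groups["household_income"] = "financial"
    edges.add((income, 1))
    cpts[income] = np.asarray([[1 - p_low_income, p_low_income]])

    mediated_binary = [0.20, 0.45, 0.75]  # P(yes | mediator level)
    mediated_three = np.asarray(
        [[0.70, 0.20, 0.10], [0.30, 0.40, 0.30], [0.10, 0.30, 0.60]]
    )
    for i in range(n_peripheral):
        idx = len(names)
        kind = i % 4
        if kind == 0:  # binary child of the symptom severity core
            names.append(f"lifestyle_{i:02d}")
            cards.append(2)
            labels.append(["no", "yes"])
            groups[names[-1]] = "lifestyle"
            edges.add((0, idx))
            cpts[idx] = np.asarray([[1 - p, p] for p in mediated_binary])
        elif kind == 1:  # binary child of the trait core
            names.append(f"social_{i:02d}")
            cards.append(2)
            labels.append(["no", "yes"])
            groups[names[-1]] = "social"
            edges.add((1, idx))
            cpts[idx] = np.asarray([[1 - p, p] for p in mediated_binary])
        elif kind == 2:  # 3-level child of the symptom severity core
            names.append(f"pain_{i:02d}")
            cards.append(3)
            labels.append(_THREE_LEVELS)
            groups[names[-1]] = "pain"
            edges.add((0, idx))
            cpts[idx] = mediated_three.copy()
        else:  # independent background distractor
            names.append(f"background_{i:02d}")
            cards.append(2)
            labels.append(["no", "yes"])
            groups[names[-1]] = "background"
            cpts[idx] = np.asarray([[0.6, 0.4]])

    return GroundTruthSpec(
        variable_names=names,
        cardinalities=cards,
        level_labels=labels,
        dag=DagStructure(len(names), frozenset(edges)),
        cpts=cpts,
        target_index=target,
        group_labels=groups,
    )


def _calibrate_intercept(
    beta_lists: list[list[float]],
    marginals: list[list[float]],
    prevalence: float,
    tol: float = 1e-12,
) -> float:
    """Bisection on the logistic intercept so that the exact marginal
    P(target = 1) = sum over parent configs of P(config) * sigmoid(.)
    equals the requested prevalence."""

    def marginal(b0: float) -> float:
        total = 0.0
        for combo in itertools.product(*[range(len(m)) for m in marginals]):
            w = 1.0
            for m, k in zip(marginals, combo):
                w *= m[k]
            total += w * _sigmoid(b0 + sum(b[k] for b, k in zip(beta_lists, combo)))
        return total

    lo, hi = -30.0, 10.0
    if not (marginal(lo) < prevalence < marginal(hi)):
        raise ValueError("requested prevalence infeasible for the CPT template")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if marginal(mid) < prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def exact_target_prevalence(spec: GroundTruthSpec, max_configs: int = 1_000_000) -> float:
    """Exact marginal P(target = 1) by enumeration over the target's
    ancestor set (whose joint factorises over the ancestors' own CPTs)."""
    t = spec.target_index
    ps = spec.dag.parent_sets()
    ancestors: set[int] = set()
    frontier = set(ps[t])
    while frontier:
        ancestors |= frontier
        frontier = {p for a in frontier for p in ps[a]} - ancestors
    anc = sorted(ancestors)
    n_cfg = int(np.prod([spec.cardinalities[a] for a in anc])) if anc else 1
    if n_cfg > max_configs:
        raise ValueError("ancestor state space too large for exact enumeration")
    pos = {a: i for i, a in enumerate(anc)}
    total = 0.0
    for combo in itertools.product(*[range(spec.cardinalities[a]) for a in anc]):
        w = 1.0
        for a in anc:
            w *= spec.cpts[a][_row_index(spec, ps[a], combo, pos), combo[pos[a]]]
        total += w * spec.cpts[t][_row_index(spec, ps[t], combo, pos), 1]
    return total


def _row_index(spec, parents, combo, pos) -> int:
    code, stride = 0, 1
    for p in parents:  # parent_sets() returns sorted tuples
        code += combo[pos[p]] * stride
        stride *= spec.cardinalities[p]
    return code


def sample_cohort(spec: GroundTruthSpec, n: int, seed: int) -> CategoricalDataset:
    """Ancestral sampling of ``n`` subjects, reproducible by ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.zeros((n, spec.n_vars), dtype=np.int64)
    ps = spec.dag.parent_sets()
    for node in _topological_order(spec.dag):
        code = np.zeros(n, dtype=np.int64)
        stride = 1
        for p in ps[node]:
            code += values[:, p] * stride
            stride *= spec.cardinalities[p]
        cum = np.cumsum(spec.cpts[node], axis=1)
        u = rng.random(n)
        values[:, node] = (cum[code] < u[:, None]).sum(axis=1)
    return CategoricalDataset(
        variable_names=list(spec.variable_names),
        cardinalities=list(spec.cardinalities),
        level_labels=[list(l) for l in spec.level_labels],
        values=values,
        target_index=spec.target_index,
        group_labels=dict(spec.group_labels),
    )


def plant_interaction(
    spec: GroundTruthSpec, names: tuple[str, str]
) -> GroundTruthSpec:
    """Return a new spec with an extra spouse-type pattern X -> C <- target.

    X is a fresh balanced binary root with no marginal effect on the target;
    C depends jointly on X and the target, so X joins the target's true
    Markov blanket only as an interaction term.
    """
    x_name, c_name = names
    for nm in names:
        if nm in spec.variable_names:
            raise ValueError(f"variable name {nm!r} already in use")
    v = spec.n_vars
    x_idx, c_idx = v, v + 1
    new_names = spec.variable_names + [x_name, c_name]
    new_cards = spec.cardinalities + [2, 2]
    new_labels = [list(l) for l in spec.level_labels] + [["no", "yes"], ["no", "yes"]]
    edges = set(spec.dag.edges) | {(x_idx, c_idx), (spec.target_index, c_idx)}
    cpts = {k: c.copy() for k, c in spec.cpts.items()}
    cpts[x_idx] = np.asarray([[0.5, 0.5]])
    # C's sorted parents are (target, X); target cycles fastest
    p_c = [0.05, 0.30, 0.10, 0.85]  # (t,x) = (0,0),(1,0),(0,1),(1,1)
    cpts[c_idx] = np.asarray([[1 - p, p] for p in p_c])
    groups = dict(spec.group_labels)
    groups[x_name] = "planted"
    groups[c_name] = "planted"
    return GroundTruthSpec(
        variable_names=new_names,
        cardinalities=new_cards,
        level_labels=new_labels,
        dag=DagStructure(v + 2, frozenset(edges)),
        cpts=cpts,
        target_index=spec.target_index,
        group_labels=groups,
    )


def spec_to_truth_tables(spec: GroundTruthSpec):
    """Answer key: the true relationship label of every variable with
    respect to the target, read off the generating DAG.

    ``direct`` = edge-adjacent; ``interaction`` = in the Markov blanket
    without adjacency (spouse); ``transitive`` = directed path with >= 1
    intermediary in either orientation; else ``none``.
    """
    import pandas as pd

    t = spec.target_index
    adjacent = spec.dag.parents(t) | spec.dag.children(t)
    mb = markov_blanket(spec.dag, t)
    rows = []
    for x in range(spec.n_vars):
        if x == t:
            continue
        if x in adjacent:
            label = "direct"
        elif x in mb:
            label = "interaction"
        elif directed_path_exists(spec.dag, x, t, 1) or directed_path_exists(
            spec.dag, t, x, 1
        ):
            label = "transitive"
        else:
            label = "none"
        rows.append({"variable": spec.variable_names[x], "true_label": label})
    return pd.DataFrame(rows).set_index("variable")
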