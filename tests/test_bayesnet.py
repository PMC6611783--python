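import math

import networkx as nx
import numpy as np
import pytest

from enviromap.bayesnet import (
    CategoricalDataset,
    DagStructure,
    ScoreConfig,
    dag_log_posterior,
    directed_path_exists,
    enumerate_dags,
    family_log_score,
    is_acyclic,
    markov_blanket,
    read_cohort_csv,
)
from conftest import make_binary_dataset, random_dag_edges


class TestDagBasics:
    @pytest.mark.parametrize(
        "n, edges, acyclic",
        [
            (3, {(0, 1), (1, 2)}, True),
            (2, {(0, 1), (1, 0)}, False),
            (5, set(), True),
            (3, {(0, 1), (1, 2), (2, 0)}, False),
        ],
    )
    def test_is_acyclic(self, n, edges, acyclic):
        assert is_acyclic(DagStructure(n, frozenset(edges))) is acyclic

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            DagStructure(2, frozenset({(0, 0)}))

    @pytest.mark.parametrize(
        "edges, target, expected",
        [
            ({(0, 1), (1, 2)}, 1, {0, 2}),  # chain: parent and child
            ({(0, 2), (1, 2)}, 0, {2, 1}),  # collider: child and spouse
            ({(0, 1), (1, 2)}, 3, set()),  # isolated node
        ],
    )
    def test_markov_blanket_examples(self, edges, target, expected):
        assert markov_blanket(DagStructure(4, frozenset(edges)), target) == expected

    def test_markov_blanket_matches_bruteforce_on_random_dags(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            g = DagStructure(8, random_dag_edges(8, rng))
            y = int(rng.integers(0, 8))
            brute = set()
            for x in range(8):
                if x == y:
                    continue
                if (x, y) in g.edges or (y, x) in g.edges:
                    brute.add(x)
                elif any((y, c) in g.edges and (x, c) in g.edges for c in range(8)):
                    brute.add(x)
            assert markov_blanket(g, y) == brute

    @pytest.mark.parametrize(
        "edges, src, dst, mins, expected",
        [
            ({(0, 1), (1, 2)}, 0, 2, 1, True),
            ({(0, 1), (1, 2)}, 2, 0, 1, False),  # direction matters
            ({(0, 2)}, 0, 2, 1, False),  # direct edge has no intermediary
            ({(0, 2), (0, 1), (1, 2)}, 0, 2, 1, True),  # longer path coexists
            ({(0, 1)}, 0, 1, 0, True),
        ],
    )
    def test_directed_path(self, edges, src, dst, mins, expected):
        g = DagStructure(3, frozenset(edges))
        assert directed_path_exists(g, src, dst, mins) is expected


class TestScore:
    def test_closed_form_no_parents(self):
        """Binary child, counts (2,2), ESS 1: marginal likelihood is 3/128."""
        ds = make_binary_dataset({"y": np.array([0, 0, 1, 1])}, target="y")
        s = family_log_score(ds, 0, (), ScoreConfig(equivalent_sample_size=1.0))
        assert s == pytest.approx(math.log(3 / 128), abs=1e-12)

    def test_row_permutation_invariance(self, collider_dataset):
        perm = np.random.default_rng(1).permutation(collider_dataset.n_rows)
        shuffled = CategoricalDataset(
            collider_dataset.variable_names,
            collider_dataset.cardinalities,
            collider_dataset.level_labels,
            collider_dataset.values[perm],
            collider_dataset.target_index,
        )
        cfg = ScoreConfig()
        for parents in [(), (0,), (0, 1)]:
            assert family_log_score(collider_dataset, 2, parents, cfg) == pytest.approx(
                family_log_score(shuffled, 2, parents, cfg), abs=1e-9
            )

    def test_parent_cap_enforced(self, collider_dataset):
        with pytest.raises(ValueError):
            family_log_score(collider_dataset, 2, (0, 1), ScoreConfig(max_parents=1))

    def test_likelihood_equivalence_two_variables(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.integers(0, 2, 300)
            y = ((x + rng.integers(0, 2, 300)) % 2).astype(np.int64)
            ds = make_binary_dataset({"X": x, "Y": y}, target="Y")
            cfg = ScoreConfig()
            fwd = dag_log_posterior(ds, DagStructure(2, frozenset({(0, 1)})), cfg)
            rev = dag_log_posterior(ds, DagStructure(2, frozenset({(1, 0)})), cfg)
            assert fwd == pytest.approx(rev, abs=1e-9)

    def test_equivalence_class_three_node_chain(self, collider_dataset):
        """The three Markov-equivalent orientations of a chain score equally."""
        cfg = ScoreConfig()
        chains = [
            {(0, 1), (1, 2)},  # A->B->C
            {(1, 0), (1, 2)},  # A<-B->C
            {(2, 1), (1, 0)},  # A<-B<-C
        ]
        scores = [
            dag_log_posterior(collider_dataset, DagStructure(3, frozenset(e)), cfg)
            for e in chains
        ]
        assert max(scores) - min(scores) < 1e-9

    def test_decomposability(self, collider_dataset):
        """Changing one parent set shifts the DAG score by that family's delta."""
        cfg = ScoreConfig()
        g0 = DagStructure(3, frozenset({(0, 2)}))
        g1 = DagStructure(3, frozenset({(0, 2), (1, 2)}))
        delta_dag = dag_log_posterior(collider_dataset, g1, cfg) - dag_log_posterior(
            collider_dataset, g0, cfg
        )
        delta_family = family_log_score(collider_dataset, 2, (0, 1), cfg) - family_log_score(
            collider_dataset, 2, (0,), cfg
        )
        assert delta_dag == pytest.approx(delta_family, abs=1e-9)

    def test_empty_graph_is_sum_of_singletons(self, collider_dataset):
        cfg = ScoreConfig()
        total = dag_log_posterior(collider_dataset, DagStructure(3), cfg)
        parts = sum(family_log_score(collider_dataset, v, (), cfg) for v in range(3))
        assert total == pytest.approx(parts, abs=1e-9)

    def test_collider_beats_empty_on_deterministic_data(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 2, 1000)
        b = rng.integers(0, 2, 1000)
        c = (a & b).astype(np.int64)
        ds = make_binary_dataset({"A": a, "B": b, "C": c}, target="C")
        cfg = ScoreConfig()
        collider = dag_log_posterior(ds, DagStructure(3, frozenset({(0, 2), (1, 2)})), cfg)
        empty = dag_log_posterior(ds, DagStructure(3), cfg)
        assert collider > empty

    def test_cyclic_input_rejected(self, collider_dataset):
        with pytest.raises(ValueError):
            dag_log_posterior(
                collider_dataset, DagStructure(3, frozenset({(0, 1), (1, 0)})), ScoreConfig()
            )


class TestEnumeration:
    @pytest.mark.parametrize("n, count", [(1, 1), (2, 3), (3, 25), (4, 543), (5, 29281)])
    def test_labeled_dag_counts(self, n, count):
        assert sum(1 for _ in enumerate_dags(n)) == count

    def test_counts_against_independent_scan(self):
        """Cross-check n <= 3 against a scan of all directed graphs."""
        import itertools

        for n in (2, 3):
            pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
            total = 0
            for bits in itertools.product((0, 1), repeat=len(pairs)):
                edges = [p for p, b in zip(pairs, bits) if b]
                g = nx.DiGraph(edges)
                g.add_nodes_from(range(n))
                if nx.is_directed_acyclic_graph(g):
                    total += 1
            assert total == sum(1 for _ in enumerate_dags(n))

    def test_uniqueness(self):
        dags = list(enumerate_dags(3))
        assert len({g.edges for g in dags}) == len(dags)

    def test_guard(self):
        with pytest.raises(ValueError):
            list(enumerate_dags(6))


class TestReader:
    def test_roundtrip_and_first_appearance_coding(self, tmp_path):
        p = tmp_path / "cohort.csv"
        p.write_text("exposure,outcome\nhigh,no\nlow,yes\nhigh,no\nlow,no\n")
        ds = read_cohort_csv(p, target="outcome")
        assert ds.level_labels[0] == ["high", "low"]
        assert ds.values[:, 0].tolist() == [0, 1, 0, 1]
        assert ds.target_name == "outcome"

    def test_codebook_orders_levels(self, tmp_path):
        p = tmp_path / "cohort.csv"
        p.write_text("exposure,outcome\nhigh,no\nlow,yes\n")
        ds = read_cohort_csv(p, target="outcome",
                             codebook={"exposure": ["low", "high"]})
        assert ds.level_labels[0] == ["low", "high"]
        assert ds.values[:, 0].tolist() == [1, 0]

    def test_missing_cells_refused_unless_dropped(self, tmp_path):
        p = tmp_path / "cohort.csv"
        p.write_text("exposure,outcome\nhigh,no\n,yes\nlow,yes\nlow,no\n")
        with pytest.raises(ValueError, match="missing"):
            read_cohort_csv(p, target="outcome")
        ds = read_cohort_csv(p, target="outcome", drop_missing=True)
        assert ds.n_rows == 3

    def test_non_binary_target_rejected(self, tmp_path):
        p = tmp_path / "cohort.csv"
        p.write_text("exposure,outcome\na,x\nb,y\nc,z\na,x\n")
        with pytest.raises(ValueError, match="binary"):
            read_cohort_csv(p, target="outcome")
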