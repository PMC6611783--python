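import numpy as np
import pytest

from enviromap.bayesnet import CategoricalDataset
from enviromap.effects import (
    contingency_counts,
    cr_odds_ratio,
    cr_or_table,
    cr_or_table_frame,
    pairwise_config_or,
    pairwise_or,
    value_relative_or,
)
from conftest import make_binary_dataset


def dataset_from_counts(a, b, c, d):
    """Binary exposure/target dataset with exact 2x2 cell counts.

    a/b: cases/controls with exposure level "1"; c/d: without."""
    x = np.array([1] * (a + b) + [0] * (c + d))
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    return make_binary_dataset({"X": x, "Y": y}, target="Y")


class TestCounts:
    def test_conservation_and_brute_force(self):
        rng = np.random.default_rng(0)
        n = 50
        x = rng.integers(0, 3, n)
        z = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        ds = CategoricalDataset(
            ["X", "Z", "Y"], [3, 2, 2],
            [["a", "b", "c"], ["0", "1"], ["0", "1"]],
            np.column_stack([x, z, y]), 2,
        )
        cfg = {"X": "b", "Z": "1"}
        a, b, c, d = contingency_counts(ds, cfg)
        # independent row scan
        aa = bb = cc = dd = 0
        for xi, zi, yi in zip(x, z, y):
            inside = (xi == 1) and (zi == 1)
            if inside and yi == 1:
                aa += 1
            elif inside:
                bb += 1
            elif yi == 1:
                cc += 1
            else:
                dd += 1
        assert (a, b, c, d) == (aa, bb, cc, dd)
        assert a + b + c + d == n

    def test_config_matching_all_rows_empties_complement(self):
        ds = dataset_from_counts(3, 7, 0, 0)
        a, b, c, d = contingency_counts(ds, {"X": "1"})
        assert (c, d) == (0, 0)

    def test_unknown_variable_or_level_rejected(self):
        ds = dataset_from_counts(5, 5, 5, 5)
        with pytest.raises(KeyError):
            contingency_counts(ds, {"nope": "1"})
        with pytest.raises(KeyError):
            contingency_counts(ds, {"X": "banana"})
        with pytest.raises(ValueError):
            contingency_counts(ds, {"Y": "1"})


class TestCrOddsRatio:
    def test_hand_computed_fixture(self):
        res = cr_odds_ratio(dataset_from_counts(30, 70, 20, 80), {"X": "1"})
        assert res.odds_ratio == pytest.approx(2400 / 1400, abs=1e-4)
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert not res.corrected

    def test_exact_independence_gives_one(self):
        # product table: P(X=1)=0.5, P(Y=1)=0.2, fully independent counts
        res = cr_odds_ratio(dataset_from_counts(10, 40, 10, 40), {"X": "1"})
        assert res.odds_ratio == pytest.approx(1.0)

    def test_binary_reciprocity(self):
        ds = dataset_from_counts(30, 70, 20, 80)
        r1 = cr_odds_ratio(ds, {"X": "1"})
        r0 = cr_odds_ratio(ds, {"X": "0"})
        assert r1.odds_ratio == pytest.approx(1 / r0.odds_ratio)

    def test_zero_cell_correction_flagged(self):
        res = cr_odds_ratio(dataset_from_counts(0, 10, 5, 5), {"X": "1"})
        assert res.corrected
        assert res.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_degenerate_strata_rejected(self):
        ds = dataset_from_counts(3, 7, 0, 0)
        with pytest.raises(ValueError, match="degenerate"):
            cr_odds_ratio(ds, {"X": "1"})

    def test_row_duplication_keeps_or_and_narrows_ci(self):
        ds = dataset_from_counts(30, 70, 20, 80)
        doubled = make_binary_dataset(
            {"X": np.tile(ds.values[:, 0], 2), "Y": np.tile(ds.values[:, 1], 2)},
            target="Y",
        )
        r1 = cr_odds_ratio(ds, {"X": "1"})
        r2 = cr_odds_ratio(doubled, {"X": "1"})
        assert r2.odds_ratio == pytest.approx(r1.odds_ratio)
        assert (r2.ci_high - r2.ci_low) < (r1.ci_high - r1.ci_low)


class TestValueRelativeAndPairwise:
    def test_value_relative_is_single_variable_cr(self):
        ds = dataset_from_counts(30, 70, 20, 80)
        assert value_relative_or(ds, "X", "1").odds_ratio == pytest.approx(
            cr_odds_ratio(ds, {"X": "1"}).odds_ratio
        )

    def test_six_level_variable_needs_no_base(self):
        rng = np.random.default_rng(1)
        n = 10_000
        x = rng.integers(0, 6, n)
        y = (rng.random(n) < 0.3).astype(np.int64)
        ds = CategoricalDataset(
            ["X", "Y"], [6, 2],
            [[f"x{i}" for i in range(1, 7)], ["0", "1"]],
            np.column_stack([x, y]), 1,
        )
        results = [value_relative_or(ds, "X", f"x{i}") for i in range(1, 7)]
        assert len(results) == 6
        for r in results:  # independent uniform: all ORs compatible with 1
            assert r.ci_low < 1.0 < r.ci_high

    def test_pairwise_symmetric_table_is_one(self):
        res = pairwise_or(dataset_from_counts(10, 20, 10, 20), "X", "1", "0")
        assert res.odds_ratio == pytest.approx(1.0)

    def test_pairwise_reciprocity(self):
        ds = dataset_from_counts(30, 70, 20, 80)
        fwd = pairwise_or(ds, "X", "1", "0").odds_ratio
        rev = pairwise_or(ds, "X", "0", "1").odds_ratio
        assert fwd == pytest.approx(1 / rev)

    def test_pairwise_matches_cr_on_binary_variable(self):
        ds = dataset_from_counts(30, 70, 20, 80)
        assert pairwise_or(ds, "X", "1", "0").odds_ratio == pytest.approx(
            cr_odds_ratio(ds, {"X": "1"}).odds_ratio
        )

    def test_pairwise_config_contrast_restricts_rows(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.integers(0, 2, n)
        z = rng.integers(0, 2, n)
        y = (rng.random(n) < 0.05 + 0.3 * x + 0.2 * z).astype(np.int64)
        ds = make_binary_dataset({"X": x, "Z": z, "Y": y}, target="Y")
        res = pairwise_config_or(ds, {"X": "1", "Z": "1"}, {"X": "0", "Z": "0"})
        m1 = (x == 1) & (z == 1)
        m0 = (x == 0) & (z == 0)
        a, b = y[m1].sum(), (1 - y[m1]).sum()
        c, d = y[m0].sum(), (1 - y[m0]).sum()
        assert res.counts == (a, b, c, d)
        assert res.odds_ratio == pytest.approx((a * d) / (b * c))
        with pytest.raises(ValueError, match="overlap"):
            pairwise_config_or(ds, {"X": "1"}, {"Z": "1"})


class TestTable:
    def test_two_binaries_give_four_rows_in_row_major_order(self):
        rng = np.random.default_rng(3)
        n = 400
        ds = make_binary_dataset(
            {"X": rng.integers(0, 2, n), "Z": rng.integers(0, 2, n),
             "Y": rng.integers(0, 2, n)}, target="Y",
        )
        rows = cr_or_table(ds, ["X", "Z"])
        assert [r.configuration for r in rows] == [
            {"X": "0", "Z": "0"}, {"X": "0", "Z": "1"},
            {"X": "1", "Z": "0"}, {"X": "1", "Z": "1"},
        ]
        direct = cr_odds_ratio(ds, {"X": "1", "Z": "0"})
        assert rows[2].odds_ratio == pytest.approx(direct.odds_ratio)
        frame = cr_or_table_frame(rows)
        assert list(frame.columns[:4]) == ["X", "Z", "a", "b"]

    def test_configuration_cap(self):
        rng = np.random.default_rng(4)
        ds = make_binary_dataset(
            {"X": rng.integers(0, 2, 50), "Z": rng.integers(0, 2, 50),
             "Y": rng.integers(0, 2, 50)}, target="Y",
        )
        with pytest.raises(ValueError, match="cap"):
            cr_or_table(ds, ["X", "Z"], max_configurations=3)

    def test_planted_synergy_has_largest_cr_or(self):
        """Monotone joint CPT: the doubly-exposed configuration tops the table."""
        rng = np.random.default_rng(5)
        n = 50_000
        x = rng.integers(0, 2, n)
        z = rng.integers(0, 2, n)
        p = 0.02 + 0.04 * x + 0.04 * z + 0.25 * (x & z)
        y = (rng.random(n) < p).astype(np.int64)
        ds = make_binary_dataset({"X": x, "Z": z, "Y": y}, target="Y")
        rows = cr_or_table(ds, ["X", "Z"])
        best = max(rows, key=lambda r: r.odds_ratio)
        assert best.configuration == {"X": "1", "Z": "1"}


class TestTwoByTwoProperties:
    """Structural identities of the 2x2 odds machinery for arbitrary tables."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    cell = st.integers(min_value=1, max_value=500)

    @given(a=cell, b=cell, c=cell, d=cell)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reciprocity_and_ci_ordering(self, a, b, c, d):
        ds = dataset_from_counts(a, b, c, d)
        r1 = cr_odds_ratio(ds, {"X": "1"})
        r0 = cr_odds_ratio(ds, {"X": "0"})
        assert r1.odds_ratio == pytest.approx((a * d) / (b * c))
        assert r1.odds_ratio == pytest.approx(1 / r0.odds_ratio)
        assert r1.ci_low <= r1.odds_ratio <= r1.ci_high
        assert sum(r1.counts) == a + b + c + d
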