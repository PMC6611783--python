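"""Configuration-relative odds ratios for a binary phenotype.

A value configuration fixes the levels of one or more variables.  The
configuration-relative odds ratio (CR-OR) compares the odds of the target
*within* the configuration against the odds over *all other* configurations:

    CR-OR(config) = Odds(Y | config) / Odds(Y | not config) = (a/b) / (c/d)

with the 2x2 counts a = cases matching, b = controls matching, c, d the
complements.  A value-relative OR is the single-variable special case and a
pairwise OR restricts the table to two levels (or two explicit
configurations), which is the ordinary OR between them.

Confidence intervals use the Woolf (log-normal) method; zero cells trigger
the Haldane–Anscombe +0.5 correction on all four cells (flagged in the
result).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bayesnet import CategoricalDataset

__all__ = [
    "ConfigOrResult",
    "contingency_counts",
    "cr_odds_ratio",
    "value_relative_or",
    "pairwise_or",
    "pairwise_config_or",
    "cr_or_table",
    "cr_or_table_frame",
]

_Z95 = norm.ppf(0.975)


@dataclass
class ConfigOrResult:
    """A configuration with its 2x2 counts, odds ratio and 95% CI."""

    configuration: dict[str, str]
    counts: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane–Anscombe +0.5 applied
    kind: str = "cr"  # "cr" or "pairwise"

    def as_row(self) -> dict:
        a, b, c, d = self.counts
        return {
            **self.configuration,
            "a": a, "b": b, "c": c, "d": d,
            "OR": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "corrected": self.corrected,
        }


def _config_mask(data: CategoricalDataset, config: Mapping[str, str]) -> np.ndarray:
    if not config:
        raise ValueError("configuration must fix at least one variable")
    mask = np.ones(data.n_rows, dtype=bool)
    for var, level in config.items():
        v = data.index_of(var)
        if v == data.target_index:
            raise ValueError("target variable cannot appear in a configuration")
        k = data.level_index(var, level)
        mask &= data.values[:, v] == k
    return mask


def contingency_counts(
    data: CategoricalDataset, config: Mapping[str, str]
) -> tuple[int, int, int, int]:
    """2x2 counts (a, b, c, d) of target vs configuration membership.

    a = cases matching every configured value, b = controls matching,
    c/d the non-matching cases/controls; a+b+c+d = N always.
    """
    mask = _config_mask(data, config)
    y = data.values[:, data.target_index] == 1
    a = int(np.sum(mask & y))
    b = int(np.sum(mask & ~y))
    c = int(np.sum(~mask & y))
    d = int(np.sum(~mask & ~y))
    return a, b, c, d


def _or_from_counts(
    a: int, b: int, c: int, d: int,
    config: Mapping[str, str],
    kind: str,
) -> ConfigOrResult:
    if a + b == 0:
        raise ValueError("degenerate stratum: no rows match the configuration")
    if c + d == 0:
        raise ValueError("degenerate stratum: every row matches the configuration")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = math.exp(math.log(or_) - _Z95 * se)
    hi = math.exp(math.log(or_) + _Z95 * se)
    return ConfigOrResult(
        configuration=dict(config),
        counts=(a, b, c, d),
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        corrected=corrected,
        kind=kind,
    )


def cr_odds_ratio(
    data: CategoricalDataset, config: Mapping[str, str]
) -> ConfigOrResult:
    """Configuration-relative odds ratio with Woolf 95% CI."""
    a, b, c, d = contingency_counts(data, config)
    return _or_from_counts(a, b, c, d, config, kind="cr")


def value_relative_or(
    data: CategoricalDataset, variable: str, level: str
) -> ConfigOrResult:
    """Odds of one level of a variable against all its other levels.

    No base level is needed, which matters for multi-level variables where
    neither extreme is a natural reference.
    """
    return cr_odds_ratio(data, {variable: level})


def pairwise_or(
    data: CategoricalDataset, variable: str, level: str, base: str
) -> ConfigOrResult:
    """Ordinary odds ratio of ``level`` versus an explicit ``base`` level,
    restricting the table to rows taking one of the two levels."""
    if level == base:
        raise ValueError("level and base must differ")
    v = data.index_of(variable)
    if v == data.target_index:
        raise ValueError("target variable cannot be the exposure")
    k_level = data.level_index(variable, level)
    k_base = data.level_index(variable, base)
    col = data.values[:, v]
    y = data.values[:, data.target_index] == 1
    a = int(np.sum((col == k_level) & y))
    b = int(np.sum((col == k_level) & ~y))
    c = int(np.sum((col == k_base) & y))
    d = int(np.sum((col == k_base) & ~y))
    return _or_from_counts(
        a, b, c, d, {variable: f"{level} vs {base}"}, kind="pairwise"
    )


def pairwise_config_or(
    data: CategoricalDataset,
    config: Mapping[str, str],
    base_config: Mapping[str, str],
) -> ConfigOrResult:
    """Ordinary odds ratio between two explicit multi-variable
    configurations, restricting rows to subjects matching either one.

    This is the contrast between two extreme configurations (e.g. the
    highest-risk versus the lowest-risk profile); it is *not* the ratio of
    their CR-ORs.
    """
    m1 = _config_mask(data, config)
    m0 = _config_mask(data, base_config)
    if np.any(m1 & m0):
        raise ValueError("the two configurations overlap")
    y = data.values[:, data.target_index] == 1
    a = int(np.sum(m1 & y))
    b = int(np.sum(m1 & ~y))
    c = int(np.sum(m0 & y))
    d = int(np.sum(m0 & ~y))
    label = {f"{k}(vs)": v for k, v in base_config.items()}
    return _or_from_counts(
        a, b, c, d, {**dict(config), **label}, kind="pairwise"
    )


def cr_or_table(
    data: CategoricalDataset,
    variables: Sequence[str],
    max_configurations: int = 4096,
) -> list[ConfigOrResult]:
    """CR-OR for every full value configuration of ``variables``.

    Rows come in row-major order of the given variable order (last variable
    cycling fastest).  Degenerate configurations (no matching rows) are
    skipped.
    """
    idx = [data.index_of(v) for v in variables]
    if data.target_index in idx:
        raise ValueError("target variable cannot appear in the table")
    n_cfg = int(np.prod([data.cardinalities[i] for i in idx]))
    if n_cfg > max_configurations:
        raise ValueError(
            f"{n_cfg} configurations exceed the cap of {max_configurations}"
        )
    level_lists = [data.level_labels[i] for i in idx]
    out: list[ConfigOrResult] = []
    for combo in itertools.product(*level_lists):
        config = dict(zip(variables, combo))
        try:
            out.append(cr_odds_ratio(data, config))
        except ValueError:
            continue  # empty stratum: configuration absent from the cohort
    return out


def cr_or_table_frame(results: Sequence[ConfigOrResult]) -> pd.DataFrame:
    """Tabular layout: configuration columns, counts, CR-OR, CI bounds."""
    return pd.DataFrame([r.as_row() for r in results])
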