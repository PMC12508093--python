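"""Shoal-configuration statistics: origin classes, exact tests, size model.

Each shoal is classified along two axes derived from its member species:

* **origin configuration** — ``native_only``, ``range_extending_only`` or
  ``mixed_origin`` (at least one species of each origin), and
* **shoal type** — ``mono_specific`` (one species) or ``multi_specific``
  (two or more species).

The module tabulates configuration frequencies, compares the propensity of
the two single-origin groups to form multi-specific shoals with an exact
2×2 test and a χ² test, and fits a Gaussian model of log shoal size on the
configuration factor with Tukey-adjusted pairwise contrasts and a compact
letter display.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .errors import DomainError, FittingError, ValidationError
from .io import MONO, MULTI, ShoalRecord, SpeciesCatalog
from .simulate import (
    MIXED_ORIGIN,
    NATIVE_ONLY,
    ORIGIN_CONFIGS,
    RANGE_EXTENDING_ONLY,
    origin_config_of,
)


@dataclass(frozen=True)
class ShoalClassification:
    """Origin configuration, type and size of one shoal."""

    shoal_id: str
    origin_config: str
    shoal_type: str
    shoal_size: int

    def __post_init__(self) -> None:
        if self.origin_config not in ORIGIN_CONFIGS:
            raise ValidationError(f"unknown origin_config {self.origin_config!r}")
        if self.shoal_type not in (MONO, MULTI):
            raise ValidationError(f"unknown shoal_type {self.shoal_type!r}")
        if self.origin_config == MIXED_ORIGIN and self.shoal_type != MULTI:
            raise ValidationError("a mixed-origin shoal is necessarily multi-specific")


def classify_shoal(
    record: ShoalRecord, catalog: SpeciesCatalog
) -> ShoalClassification:
    """Classify one shoal by the origins and number of its member species."""
    record.validate_against(catalog)
    return ShoalClassification(
        shoal_id=record.shoal_id,
        origin_config=origin_config_of(frozenset(record.counts), catalog),
        shoal_type=MULTI if len(record.counts) >= 2 else MONO,
        shoal_size=record.shoal_size,
    )


def classify_all(
    records: Sequence[ShoalRecord], catalog: SpeciesCatalog
) -> list[ShoalClassification]:
    return [classify_shoal(r, catalog) for r in records]


@dataclass(frozen=True)
class ConfigurationFrequencies:
    """Counts and percentages per origin configuration (and × shoal type)."""

    by_origin: pd.DataFrame
    by_origin_type: pd.DataFrame
    n: int


def configuration_frequencies(
    classifications: Sequence[ShoalClassification],
) -> ConfigurationFrequencies:
    """Tabulate how often each origin configuration (× type) occurs.

    Counts sum to the number of shoals, percentages to 100 within rounding;
    all three configuration levels are always present in the table.
    """
    if not classifications:
        raise DomainError("no classifications to tabulate")
    n = len(classifications)
    frame = pd.DataFrame(
        {
            "origin_config": [c.origin_config for c in classifications],
            "shoal_type": [c.shoal_type for c in classifications],
        }
    )
    by_origin = (
        frame.origin_config.value_counts()
        .reindex(ORIGIN_CONFIGS, fill_value=0)
        .rename("count")
        .rename_axis("origin_config")
        .reset_index()
    )
    by_origin["percent"] = by_origin["count"] / n * 100.0
    cross = (
        frame.groupby(["origin_config", "shoal_type"], sort=False)
        .size()
        .rename("count")
        .reset_index()
    )
    full_index = pd.DataFrame(
        [
            (cfg, st)
            for cfg in ORIGIN_CONFIGS
            for st in (MONO, MULTI)
            if not (cfg == MIXED_ORIGIN and st == MONO)
        ],
        columns=["origin_config", "shoal_type"],
    )
    cross = full_index.merge(cross, how="left").fillna({"count": 0})
    cross["count"] = cross["count"].astype(int)
    cross["percent"] = cross["count"] / n * 100.0
    return ConfigurationFrequencies(by_origin=by_origin, by_origin_type=cross, n=n)


# ---------------------------------------------------------------------------
# 2×2 tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2×2 table of counts; rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValidationError("table entries must be non-negative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValidationError("table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def build_origin_type_table(
    classifications: Sequence[ShoalClassification],
    groups: tuple[str, str] = (NATIVE_ONLY, RANGE_EXTENDING_ONLY),
) -> ContingencyTable2x2:
    """2×2 table of multi- vs mono-specific shoals by single-origin group.

    Row 1 = first group, row 2 = second; column 1 counts multi-specific
    shoals, column 2 mono-specific.  Mixed-origin shoals are excluded, since
    they belong to neither single-origin group; the grouping rule is exposed
    here as configuration rather than hard-coded.
    """
    counts = {g: {MULTI: 0, MONO: 0} for g in groups}
    for c in classifications:
        if c.origin_config in counts:
            counts[c.origin_config][c.shoal_type] += 1
    g1, g2 = groups
    return ContingencyTable2x2(
        a=counts[g1][MULTI],
        b=counts[g1][MONO],
        c=counts[g2][MULTI],
        d=counts[g2][MONO],
    )


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float | None  # conditional-MLE estimate
    odds_ratio_sample: float | None  # cross-product ratio ad/bc
    ci95: tuple[float, float] | None
    p_value: float
    degenerate: bool


def _fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p by probability ordering, in exact integer arithmetic.

    Conditional on all margins, the table is determined by its (1,1) cell
    ``k``, with hypergeometric weight ``C(R, k) · C(N−R, C−k)``; the p-value
    sums the weights of all tables no more probable than the observed one.
    Integer weights make the tie comparison exact.
    """
    R, N, C = a + b, a + b + c + d, a + c
    lo, hi = max(0, C - (N - R)), min(R, C)
    weights = {k: comb(R, k) * comb(N - R, C - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    numerator = sum(w for w in weights.values() if w <= w_obs)
    return numerator / comb(N, C)


def fisher_exact_2x2(
    table: ContingencyTable2x2, estimate_or: bool = True
) -> FisherResult:
    """Fisher's exact test with conditional-MLE odds ratio and exact 95% CI.

    The two-sided p uses probability ordering.  If a margin is zero the odds
    ratio is undefined (flagged degenerate) but p = 1 is still returned, the
    margins admitting only one table.  ``estimate_or=False`` skips the odds
    ratio and its interval, which cost far more than the p-value — useful
    when screening many tables.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = (a + b, c + d, a + c, b + d)
    p = _fisher_two_sided_p(a, b, c, d)
    if 0 in margins:
        return FisherResult(None, None, None, p, True)
    if not estimate_or:
        return FisherResult(None, None, None, p, False)
    res = stats.contingency.odds_ratio(table.as_array(), kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    sample_or = (a * d) / (b * c) if b * c > 0 else math.inf
    return FisherResult(
        odds_ratio=float(res.statistic),
        odds_ratio_sample=float(sample_or),
        ci95=(float(ci.low), float(ci.high)),
        p_value=p,
        degenerate=False,
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_2x2(
    table: ContingencyTable2x2, yates: bool = False
) -> ChiSquareResult:
    """Pearson χ² test of independence on a 2×2 table (1 df).

    Expected counts come from the margins; with ``yates=True`` the classic
    0.5 continuity subtraction is applied.
    """
    obs = table.as_array().astype(float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise DomainError("chi-square undefined for a table with a zero margin")
    expected = np.outer(row, col) / n
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    return ChiSquareResult(
        statistic=statistic, df=1, p_value=float(stats.chi2.sf(statistic, 1))
    )


# ---------------------------------------------------------------------------
# Shoal-size model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShoalSizeFit:
    """Gaussian fit of log shoal size on the configuration factor."""

    group_means: dict[str, float]  # on the log scale
    group_n: dict[str, int]
    sigma2: float  # pooled residual variance
    df_resid: int
    contrasts: pd.DataFrame
    letters: dict[str, str]
    aic_reduced: float
    aic_full: float | None


def _gaussian_aic(sse: float, n: int, k_mean_params: int) -> float:
    # MLE profile of the variance; +1 parameter for the variance itself
    return n * (math.log(2.0 * math.pi * sse / n) + 1.0) + 2.0 * (k_mean_params + 1)


def _compact_letters(
    groups: Sequence[str],
    means: dict[str, float],
    not_different: set[frozenset],
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are statistically
    indistinguishable at the chosen level.

    Letters are maximal cliques of the 'not significantly different' graph,
    lettered from the clique containing the largest mean; ties broken
    alphabetically by group label.
    """
    order = sorted(groups, key=lambda g: (-means[g], g))
    cliques: list[set] = []
    for r in range(len(order), 0, -1):
        for subset in itertools.combinations(order, r):
            if any(set(subset) <= c for c in cliques):
                continue
            if all(
                frozenset((x, y)) in not_different
                for x, y in itertools.combinations(subset, 2)
            ):
                cliques.append(set(subset))
    cliques.sort(key=lambda c: (min(order.index(g) for g in c), -len(c)))
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return {g: "".join(sorted(l)) for g, l in letters.items()}


def fit_shoal_size_model(
    classifications: Sequence[ShoalClassification],
    alpha_level: float = 0.05,
    include_shoal_type: bool = False,
    compare_full_model: bool = True,
) -> ShoalSizeFit:
    """OLS of log(shoal size) on origin configuration, with Tukey contrasts.

    The factor model is fitted in closed form (group means, pooled residual
    variance).  All pairwise group contrasts are adjusted by the studentized
    range (Tukey–Kramer for unequal group sizes), and a compact letter
    display groups means not significantly different at ``alpha_level``.
    ``include_shoal_type`` switches the mean structure to the full
    configuration × type cell model; by default the reduced
    configuration-only model is fitted and the full model is only consulted
    for its AIC.
    """
    if not classifications:
        raise FittingError("no data")
    frame = pd.DataFrame(
        {
            "group": [
                (c.origin_config, c.shoal_type) if include_shoal_type else c.origin_config
                for c in classifications
            ],
            "log_size": [math.log(c.shoal_size) for c in classifications],
        }
    )
    grouped = frame.groupby("group")["log_size"]
    group_n = grouped.size().to_dict()
    if len(group_n) < 2:
        raise FittingError("need at least 2 groups to fit the size model")
    for g, n_g in group_n.items():
        if n_g < 2:
            raise FittingError(f"group {g!r} has fewer than 2 observations")
    means = grouped.mean().to_dict()
    n = len(frame)
    k = len(group_n)
    sse = float(((frame.log_size - frame.group.map(means)) ** 2).sum())
    df_resid = n - k
    sigma2 = sse / df_resid

    rows = []
    not_different: set[frozenset] = set()
    for g1, g2 in itertools.combinations(sorted(group_n, key=str), 2):
        diff = means[g1] - means[g2]
        se = math.sqrt(sigma2 * (1.0 / group_n[g1] + 1.0 / group_n[g2]))
        t = diff / se if se > 0 else math.inf
        q = abs(diff) / math.sqrt(sigma2 * 0.5 * (1.0 / group_n[g1] + 1.0 / group_n[g2]))
        p_adj = float(studentized_range.sf(q, k, df_resid))
        p_raw = 2.0 * float(stats.t.sf(abs(t), df_resid))
        rows.append(
            {
                "group_1": str(g1),
                "group_2": str(g2),
                "estimate": diff,
                "se": se,
                "t": t,
                "p_unadjusted": p_raw,
                "p_tukey": p_adj,
            }
        )
        if p_adj >= alpha_level:
            not_different.add(frozenset((g1, g2)))
    letters = _compact_letters(list(group_n), means, not_different)

    aic_reduced = _gaussian_aic(sse, n, k)
    aic_full = None
    if compare_full_model and not include_shoal_type:
        full = frame.assign(
            cell=[(c.origin_config, c.shoal_type) for c in classifications]
        )
        cell_means = full.groupby("cell")["log_size"].transform("mean")
        sse_full = float(((full.log_size - cell_means) ** 2).sum())
        aic_full = _gaussian_aic(sse_full, n, full["cell"].nunique())

    return ShoalSizeFit(
        group_means={str(g): m for g, m in means.items()},
        group_n={str(g): int(v) for g, v in group_n.items()},
        sigma2=sigma2,
        df_resid=df_resid,
        contrasts=pd.DataFrame(rows),
        letters={str(g): l for g, l in letters.items()},
        aic_reduced=aic_reduced,
        aic_full=aic_full,
    )
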