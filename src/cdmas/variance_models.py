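"""ANOVA variance partitioning and multiple comparisons for grain-Cd data.

Implements the statistical layer of the screening analysis directly from
the linear-model definitions:

* two-way fixed-effects ANOVA (genotype class x field, replicate plots as
  the error stratum), with the effect-share column
  ``ss_effect / (ss_effect + ss_error)`` — numerically a partial
  eta-squared — reported alongside each effect;
* one-way ANOVA with Tukey HSD and Student-Newman-Keuls all-pairs
  procedures, both driven by the studentized-range distribution
  (:data:`scipy.stats.studentized_range`), with Tukey-Kramer standard
  errors for unequal group sizes;
* compact letter displays (insert-and-absorb) summarizing a pairwise
  significance matrix: groups sharing a letter are not significantly
  different.

Sums of squares are computed by nested-model residual comparison on
explicit design matrices, so balanced designs decompose exactly
(``SS_A + SS_B + SS_AB + SS_E = SS_total``) and unbalanced designs get
sequential (hierarchical) SS by default, with a Type-III (sum-to-zero
contrasts) option.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaRow",
    "OneWayResult",
    "PairwiseComparisons",
    "ComparisonLetters",
    "two_way_anova",
    "effect_share",
    "one_way_anova",
    "tukey_hsd",
    "snk_test",
    "compact_letter_display",
    "format_p",
    "write_anova_table",
    "write_letters_table",
]


@dataclass(frozen=True)
class AnovaRow:
    """One source-of-variation row (the Error row has no F/p/share)."""

    source: str
    ss: float
    df: int
    ms: float
    f_stat: float | None = None
    p_value: float | None = None
    effect_share: float | None = None

    def __post_init__(self) -> None:
        if self.ss < 0:
            raise ValueError(f"{self.source}: negative sum of squares")
        if self.df < 1:
            raise ValueError(f"{self.source}: df must be >= 1")
        if self.effect_share is not None and not 0 <= self.effect_share <= 1:
            raise ValueError(f"{self.source}: effect share outside [0, 1]")


@dataclass(frozen=True)
class OneWayResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    group_means: dict[str, float]
    group_ns: dict[str, int]


@dataclass(frozen=True)
class PairwiseComparisons:
    """Symmetric pairwise significance decisions over a set of groups."""

    groups: tuple[str, ...]
    significant: Mapping[tuple[str, str], bool]
    alpha: float

    def is_significant(self, a: str, b: str) -> bool:
        if a == b:
            return False
        return self.significant[(a, b) if (a, b) in self.significant else (b, a)]

    def matrix(self) -> pd.DataFrame:
        data = [[self.is_significant(a, b) for b in self.groups] for a in self.groups]
        return pd.DataFrame(data, index=list(self.groups), columns=list(self.groups))


@dataclass(frozen=True)
class ComparisonLetters:
    """One group's mean +/- SE and its compact-letter code."""

    group_id: str
    mean: float
    se: float
    letters: str


# --- design-matrix helpers -------------------------------------------------


def _one_hot(labels: Sequence, levels: Sequence) -> np.ndarray:
    index = {lev: j for j, lev in enumerate(levels)}
    x = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        x[i, index[lab]] = 1.0
    return x


def _effects_coding(labels: Sequence, levels: Sequence) -> np.ndarray:
    """Sum-to-zero contrast columns (k-1 columns for k levels)."""
    index = {lev: j for j, lev in enumerate(levels)}
    k = len(levels)
    x = np.zeros((len(labels), k - 1))
    for i, lab in enumerate(labels):
        j = index[lab]
        if j < k - 1:
            x[i, j] = 1.0
        else:
            x[i, :] = -1.0
    return x


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of the least-squares projection of y on x."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def two_way_anova(values: Sequence[float], factor_a: Sequence, factor_b: Sequence,
                  a_name: str = "Markers", b_name: str = "Field",
                  ss_type: str = "sequential") -> list[AnovaRow]:
    """Two-way fixed-effects ANOVA with interaction.

    ``ss_type`` is ``"sequential"`` (hierarchical; A, then B|A, then AB|A,B
    — exact partition on balanced data) or ``"type3"`` (each effect adjusted
    for all others under sum-to-zero contrasts). Every cell of the A x B
    cross must be occupied and the error stratum non-empty.
    """
    y = np.asarray(values, dtype=float)
    fa = list(factor_a)
    fb = list(factor_b)
    if not (len(y) == len(fa) == len(fb)):
        raise ValueError("values and factor labelings differ in length")
    levels_a = sorted(set(fa))
    levels_b = sorted(set(fb))
    if len(levels_a) < 2:
        raise ValueError(f"factor '{a_name}' needs >= 2 levels")
    if len(levels_b) < 2:
        raise ValueError(f"factor '{b_name}' needs >= 2 levels")
    cells = {(a, b) for a, b in zip(fa, fb)}
    for cell in itertools.product(levels_a, levels_b):
        if cell not in cells:
            raise ValueError(f"empty cell {a_name}={cell[0]!r}, {b_name}={cell[1]!r}")
    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b
    df_e = len(y) - len(levels_a) * len(levels_b)
    if df_e < 1:
        raise ValueError("no residual degrees of freedom; replicate the cells")

    ones = np.ones((len(y), 1))
    xa = _one_hot(fa, levels_a)
    xb = _one_hot(fb, levels_b)
    xab = _one_hot(list(zip(fa, fb)), sorted(cells))
    ss_total = _rss(ones, y)
    ss_e = _rss(xab, y)  # cell-means model == full interaction model

    if ss_type == "sequential":
        rss_a = _rss(np.hstack([ones, xa]), y)
        rss_ab = _rss(np.hstack([ones, xa, xb]), y)
        ss_a = max(ss_total - rss_a, 0.0)
        ss_b = max(rss_a - rss_ab, 0.0)
        ss_int = max(rss_ab - ss_e, 0.0)
    elif ss_type == "type3":
        ca = _effects_coding(fa, levels_a)
        cb = _effects_coding(fb, levels_b)
        cab = np.hstack([ca[:, [i]] * cb[:, [j]]
                         for i in range(ca.shape[1]) for j in range(cb.shape[1])])
        full = np.hstack([ones, ca, cb, cab])
        rss_full = _rss(full, y)
        ss_a = max(_rss(np.hstack([ones, cb, cab]), y) - rss_full, 0.0)
        ss_b = max(_rss(np.hstack([ones, ca, cab]), y) - rss_full, 0.0)
        ss_int = max(_rss(np.hstack([ones, ca, cb]), y) - rss_full, 0.0)
    else:
        raise ValueError(f"unknown ss_type {ss_type!r}")

    ms_e = ss_e / df_e

    def row(source: str, ss: float, df: int) -> AnovaRow:
        ms = ss / df
        f = ms / ms_e
        return AnovaRow(source, ss, df, ms, f, float(stats.f.sf(f, df, df_e)),
                        effect_share(ss, ss_e))

    return [
        row(a_name, ss_a, df_a),
        row(b_name, ss_b, df_b),
        row(f"{a_name} x {b_name}", ss_int, df_ab),
        AnovaRow("Error", ss_e, df_e, ms_e),
    ]


def effect_share(ss_effect: float, ss_error: float) -> float:
    """Effect share ``ss_effect / (ss_effect + ss_error)`` (partial
    eta-squared): the fraction of effect-plus-error variation attributable
    to the effect."""
    if ss_effect < 0:
        raise ValueError("ss_effect must be >= 0")
    if ss_error <= 0:
        raise ValueError("ss_error must be > 0")
    return ss_effect / (ss_effect + ss_error)


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> OneWayResult:
    """Standard between/within decomposition across >= 2 groups of >= 2."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    ss_between = sum(arr.size * (arr.mean() - grand) ** 2 for arr in arrays.values())
    ss_within = sum(float(((arr - arr.mean()) ** 2).sum()) for arr in arrays.values())
    df_between = len(arrays) - 1
    df_within = all_values.size - len(arrays)
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = 0.0 if ss_between == 0 else float("inf")
    else:
        f = (ss_between / df_between) / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return OneWayResult(
        f_stat=float(f), p_value=p, df_between=df_between, df_within=df_within,
        ms_within=float(ms_within),
        group_means={g: float(arr.mean()) for g, arr in arrays.items()},
        group_ns={g: int(arr.size) for g, arr in arrays.items()},
    )


# --- all-pairs procedures --------------------------------------------------


@lru_cache(maxsize=4096)
def _q_crit(alpha: float, k: int, df: int) -> float:
    """Upper studentized-range quantile; cached (the ppf is expensive)."""
    return float(stats.studentized_range.ppf(1 - alpha, k, df))


def _q_statistic(mean_i: float, mean_j: float, n_i: int, n_j: int,
                 ms_within: float) -> float:
    """Studentized-range statistic with the Tukey-Kramer SE for unequal n."""
    se = np.sqrt(ms_within / 2.0 * (1.0 / n_i + 1.0 / n_j))
    if se == 0:
        return 0.0 if mean_i == mean_j else float("inf")
    return abs(mean_i - mean_j) / se


def tukey_hsd(groups: Mapping[str, Sequence[float]],
              alpha: float = 0.05) -> PairwiseComparisons:
    """Tukey's honestly-significant-difference all-pairs test.

    Every pair is judged against the studentized-range upper quantile at
    (k groups, error df); a single critical value for all pairs.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    res = one_way_anova(groups)
    names = tuple(sorted(groups))
    k = len(names)
    q_crit = _q_crit(alpha, k, res.df_within)
    decisions: dict[tuple[str, str], bool] = {}
    for a, b in itertools.combinations(names, 2):
        q = _q_statistic(res.group_means[a], res.group_means[b],
                         res.group_ns[a], res.group_ns[b], res.ms_within)
        decisions[(a, b)] = bool(q > q_crit)
    return PairwiseComparisons(names, decisions, alpha)


def snk_test(groups: Mapping[str, Sequence[float]],
             alpha: float = 0.05) -> PairwiseComparisons:
    """Student-Newman-Keuls stepwise all-pairs test.

    Means are range-ordered; a pair spanning ``r`` ordered means is judged
    at the studentized-range quantile for ``r`` (not k), subject to the
    step-down protection rule: pairs inside a range already declared
    non-significant are non-significant without testing. With equal group
    sizes the critical values never exceed Tukey's, so SNK rejects at least
    every Tukey-rejected pair.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    res = one_way_anova(groups)
    names = tuple(sorted(groups))
    ordered = sorted(names, key=lambda g: res.group_means[g])
    pos = {g: i for i, g in enumerate(ordered)}
    k = len(ordered)
    nonsig_ranges: list[tuple[int, int]] = []
    decisions: dict[tuple[str, str], bool] = {}
    for span in range(k, 1, -1):
        q_crit = _q_crit(alpha, span, res.df_within)
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            a, b = ordered[lo], ordered[hi]
            key = tuple(sorted((a, b)))
            if any(lo >= rlo and hi <= rhi for rlo, rhi in nonsig_ranges):
                decisions[key] = False
                continue
            q = _q_statistic(res.group_means[a], res.group_means[b],
                             res.group_ns[a], res.group_ns[b], res.ms_within)
            sig = bool(q > q_crit)
            decisions[key] = sig
            if not sig:
                nonsig_ranges.append((lo, hi))
    canonical = {(a, b): decisions[tuple(sorted((a, b)))]
                 for a, b in itertools.combinations(names, 2)}
    return PairwiseComparisons(names, canonical, alpha)


# --- compact letter display ------------------------------------------------


def _letter_symbols(n: int) -> list[str]:
    letters = list(string.ascii_lowercase)
    while len(letters) < n:
        letters += [a + b for a in string.ascii_lowercase
                    for b in string.ascii_lowercase]
    return letters[:n]


def compact_letter_display(pairwise: PairwiseComparisons,
                           group_means: Mapping[str, float],
                           group_ses: Mapping[str, float] | None = None,
                           ) -> list[ComparisonLetters]:
    """Insert-and-absorb compact lettering of an all-pairs decision matrix.

    Letters are assigned so that two groups share a letter iff they belong
    to a common column of mutually non-significant groups; columns are
    lettered in descending order of their best group mean, so 'a' marks the
    highest-mean homogeneous set. The matrix must be symmetric and complete
    over ``group_means``.
    """
    groups = sorted(group_means, key=lambda g: -group_means[g])
    if set(groups) != set(pairwise.groups):
        raise ValueError("pairwise matrix and group_means cover different groups")
    for (a, b), val in pairwise.significant.items():
        if (b, a) in pairwise.significant and pairwise.significant[(b, a)] != val:
            raise ValueError(f"non-symmetric decisions for pair ({a}, {b})")

    columns: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if not pairwise.is_significant(a, b):
            continue
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = [c for c in new_columns if c and
                   not any(c < other for other in new_columns)]
        # dedupe identical columns
        unique: list[set[str]] = []
        for c in columns:
            if c not in unique:
                unique.append(c)
        columns = unique

    columns.sort(key=lambda col: (-max(group_means[g] for g in col), sorted(col)))
    symbols = _letter_symbols(len(columns))
    per_group: dict[str, list[str]] = {g: [] for g in groups}
    for sym, col in zip(symbols, columns):
        for g in col:
            per_group[g].append(sym)
    return [
        ComparisonLetters(g, float(group_means[g]),
                          0.0 if group_ses is None else float(group_ses[g]),
                          "".join(sorted(per_group[g])))
        for g in groups
    ]


# --- display / output ------------------------------------------------------


def format_p(p: float, floor: float = 0.001) -> str:
    """p to 3 decimals with a '<0.001' floor, table style."""
    return f"<{floor}" if p < floor else f"{p:.3f}"


def write_anova_table(rows: Sequence[AnovaRow], path: str | Path,
                      panel_label: str = "") -> None:
    out = []
    for r in rows:
        out.append({
            "panel": panel_label,
            "source": r.source,
            "ss": f"{r.ss:.6g}",
            "df": r.df,
            "ms": f"{r.ms:.6g}",
            "f": "" if r.f_stat is None else f"{r.f_stat:.6g}",
            "p": "" if r.p_value is None else format_p(r.p_value),
            "effect_share_pct": "" if r.effect_share is None
                                 else f"{100 * r.effect_share:.1f}",
        })
    pd.DataFrame(out).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_letters_table(letters_by_field: Mapping[str, Sequence[ComparisonLetters]],
                        path: str | Path) -> None:
    rows = []
    for field_id in sorted(letters_by_field):
        for rec in letters_by_field[field_id]:
            rows.append({
                "field": field_id,
                "class_name": rec.group_id,
                "mean_grain_cd": f"{rec.mean:.6g}",
                "se": f"{rec.se:.6g}",
                "letters": rec.letters,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
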