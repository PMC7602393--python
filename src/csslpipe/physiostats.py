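"""Physiology statistics: one-way ANOVA, Duncan's multiple range test with
compact letter display, and percent-change arithmetic.

Duncan's multiple range test (DMRT) is a step-down multiple-comparison
procedure on ordered group means.  For a span of p adjacent ordered means the
critical range is

    R_p = q(1 - (1-alpha)^(p-1); p, df) * sqrt(MSE / n_h)

where q(.; p, df) is a studentized-range quantile at Duncan's special
protection level and n_h the (harmonic mean) group size.  Two means differ
iff their gap exceeds R_p for their span and no enclosing span has already
been declared non-significant (the containment rule).  Results are rendered
as compact letters: groups sharing a letter are not significantly different,
and the highest mean carries "a".

The module also supports DMRT directly from summary statistics (mean, SE, n
per group), reconstructing the pooled error variance as
s_i^2 = n_i * SE_i^2, MSE = sum (n_i - 1) s_i^2 / sum (n_i - 1), which is how
published tables reporting mean +/- SE can be re-tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# ANOVA


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    mse: float
    df_within: int
    df_between: int
    ss_between: float
    ss_within: float


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA decomposition.

    Exposes MSE and the within-groups degrees of freedom, which Duncan's
    test needs.  Identical groups give F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = all_values.size - len(arrays)
    mse = ss_within / df_within
    if ss_within == 0 and ss_between == 0:
        f, p = 0.0, 1.0
    elif ss_within == 0:
        f, p = math.inf, 0.0
    else:
        f = (ss_between / df_between) / mse
        p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), float(p), float(mse), df_within, df_between,
                       float(ss_between), float(ss_within))


# ---------------------------------------------------------------------------
# Duncan's multiple range test


@lru_cache(maxsize=4096)
def duncan_q(alpha: float, span: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level
    1 - (1-alpha)^(span-1), cached (the ppf is expensive)."""
    if df < 1:
        raise ValueError("df_within must be >= 1")
    protection = (1.0 - alpha) ** (span - 1)
    return float(stats.studentized_range.ppf(protection, span, df))


def duncan_critical_range(alpha: float, span: int, df: int, n_h: float, mse: float) -> float:
    """R_p for a span of p ordered means at Duncan's protection level."""
    return duncan_q(alpha, span, df) * math.sqrt(mse / n_h)


@dataclass
class DmrtGrouping:
    """Compact-letter result of Duncan's test.

    ``table`` rows are ordered by mean descending; ``letters[label]`` is the
    letter string for a group; groups sharing any letter are not
    significantly different at ``alpha``.
    """

    table: pd.DataFrame
    alpha: float
    mse: float
    df_within: int
    n_harmonic: float

    @property
    def letters(self) -> dict[str, str]:
        return dict(zip(self.table["group"], self.table["letters"]))

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _duncan_nonsig(means: np.ndarray, mse: float, df: int, n_h: float,
                   alpha: float) -> np.ndarray:
    """Boolean matrix ns[i, j] (i <= j over means sorted descending): the
    pair is non-significant under the step-down containment rule."""
    k = means.size
    ns = np.zeros((k, k), dtype=bool)
    for i in range(k):
        ns[i, i] = True
    # largest spans first; an enclosing non-significant span absorbs subspans
    for span in range(k, 1, -1):
        r_p = duncan_critical_range(alpha, span, df, n_h, mse)
        for i in range(0, k - span + 1):
            j = i + span - 1
            enclosed = (i > 0 and ns[i - 1, j]) or (j < k - 1 and ns[i, j + 1])
            if enclosed or (means[i] - means[j]) <= r_p:
                ns[i, j] = True
    return ns


def _letters_from_nonsig(ns: np.ndarray) -> list[str]:
    """Compact letters from the non-significance matrix.

    Under the containment rule non-significant sets are intervals of the
    descending mean order, so letters correspond to maximal non-significant
    intervals, lettered 'a' from the top mean down.
    """
    k = ns.shape[0]
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and ns[i, j + 1]:
            j += 1
        intervals.append((i, j))
    maximal = [
        (i, j) for (i, j) in intervals
        if not any((i2 <= i and j <= j2) and (i2, j2) != (i, j) for (i2, j2) in intervals)
    ]
    maximal.sort()
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for letter, (i, j) in zip(alphabet, maximal):
        for g in range(i, j + 1):
            letters[g] += letter
    return letters


def _dmrt_core(labels: list[str], means: np.ndarray, ns_counts: np.ndarray,
               mse: float, df_within: int, alpha: float) -> DmrtGrouping:
    order = sorted(range(len(labels)), key=lambda i: (-means[i], labels[i]))
    means_sorted = means[order]
    labels_sorted = [labels[i] for i in order]
    counts_sorted = ns_counts[order]
    n_h = len(counts_sorted) / np.sum(1.0 / counts_sorted)
    ns = _duncan_nonsig(means_sorted, mse, df_within, n_h, alpha)
    letters = _letters_from_nonsig(ns)
    table = pd.DataFrame(
        {"group": labels_sorted, "mean": means_sorted,
         "n": counts_sorted.astype(int), "letters": letters}
    )
    return DmrtGrouping(table, alpha, mse, df_within, float(n_h))


def dmrt(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> DmrtGrouping:
    """Duncan's multiple range test on replicate-level groups.

    Runs the one-way ANOVA for the pooled error, then the step-down range
    procedure.  Unbalanced designs use the harmonic mean of the group sizes.
    """
    anova = anova_oneway(groups)
    if anova.df_within < 1:
        raise ValueError("df_within must be >= 1")
    labels = list(labels) if labels else [f"group_{i + 1}" for i in range(len(groups))]
    means = np.array([np.mean(g) for g in groups], dtype=float)
    counts = np.array([len(g) for g in groups], dtype=float)
    return _dmrt_core(labels, means, counts, anova.mse, anova.df_within, alpha)


def dmrt_from_summary(
    means: Sequence[float],
    ses: Sequence[float],
    ns: Sequence[int],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> DmrtGrouping:
    """Duncan's test from per-group (mean, SE, n) summaries.

    The pooled error is reconstructed from the SEs: s_i^2 = n_i * SE_i^2,
    MSE = sum (n_i-1) s_i^2 / sum (n_i-1), df = sum (n_i-1).  Identical in
    contract to :func:`dmrt` given exact summaries.
    """
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    counts = np.asarray(ns, dtype=float)
    if np.any(counts < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(ses < 0):
        raise ValueError("SEs must be >= 0")
    variances = counts * ses**2
    df_within = int(np.sum(counts - 1))
    mse = float(np.sum((counts - 1) * variances) / np.sum(counts - 1))
    labels = list(labels) if labels else [f"group_{i + 1}" for i in range(means.size)]
    return _dmrt_core(labels, means, counts, mse, df_within, alpha)


def replicates_from_summary(mean: float, se: float, n: int) -> np.ndarray:
    """Synthetic replicates with exactly the given mean and standard error.

    A centered deviation pattern is scaled so the sample SD equals
    se * sqrt(n); used to re-test published mean +/- SE tables at replicate
    level.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    base = np.arange(n, dtype=float) - (n - 1) / 2.0
    sd_target = se * math.sqrt(n)
    sd_base = base.std(ddof=1)
    return mean + base * (sd_target / sd_base if sd_base > 0 else 0.0)


# ---------------------------------------------------------------------------
# percent arithmetic


@dataclass(frozen=True)
class PercentResult:
    raw: float
    rounded: int


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def percent_change(reference: float, new: float) -> PercentResult:
    """Percent reduction of ``new`` relative to ``reference``:
    100 * (reference - new) / |reference|.  Positive = decline."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    raw = 100.0 * (reference - new) / abs(reference)
    return PercentResult(raw, _round_half_away(raw))


def percent_difference(value_a: float, value_b: float) -> PercentResult:
    """How much lower (positive) or higher (negative) ``value_b`` is than
    ``value_a``, as a percentage of |value_a|."""
    if value_a == 0:
        raise ValueError("denominator value must be nonzero")
    raw = 100.0 * (value_a - value_b) / abs(value_a)
    return PercentResult(raw, _round_half_away(raw))


# ---------------------------------------------------------------------------
# summary tables


def load_physiology_table(path: str | Path | None = None) -> pd.DataFrame:
    """Tidy summary table (line, condition, day, trait, mean, se, n).

    Without a path the packaged rice physiology summary (three lines, two
    growth conditions, four sampling days, nine traits, n = 4) is returned.
    """
    if path is None:
        source = resources.files("csslpipe.data").joinpath("rice_physiology_summary.tsv")
        with resources.as_file(source) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def table_value(table: pd.DataFrame, line: str, condition: str, day: int, trait: str) -> float:
    cell = table[
        (table["line"] == line) & (table["condition"] == condition)
        & (table["day"] == day) & (table["trait"] == trait)
    ]
    if len(cell) != 1:
        raise KeyError(f"no unique cell for {line}/{condition}/day {day}/{trait}")
    return float(cell["mean"].iloc[0])


def table_extrema(
    table: pd.DataFrame, trait: str, condition: str, day: int, which: str = "min"
) -> tuple[list[str], float]:
    """The line(s) attaining the min/max mean for one trait cell.

    Ties return all attaining lines.  Missing lines raise with their names.
    """
    cells = table[
        (table["condition"] == condition) & (table["day"] == day) & (table["trait"] == trait)
    ]
    all_lines = sorted(table["line"].unique())
    present = set(cells["line"])
    missing = [l for l in all_lines if l not in present]
    if missing:
        raise ValueError(f"missing cells for lines: {missing}")
    value = cells["mean"].min() if which == "min" else cells["mean"].max()
    lines = sorted(cells.loc[cells["mean"] == value, "line"])
    return lines, float(value)


def dmrt_letters_for_cell(
    table: pd.DataFrame, trait: str, condition: str, day: int, alpha: float = 0.05
) -> DmrtGrouping:
    """Run the summary-level Duncan test for one (trait, condition, day)
    cell of a tidy summary table."""
    cells = table[
        (table["condition"] == condition) & (table["day"] == day) & (table["trait"] == trait)
    ]
    return dmrt_from_summary(
        cells["mean"].to_numpy(), cells["se"].to_numpy(),
        cells["n"].to_numpy(int), alpha=alpha, labels=cells["line"].tolist()
    )
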