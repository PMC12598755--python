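"""Group comparisons of corrected brain-age deltas and demographics.

Two-sample t-tests (pooled-variance Student's t by default, Welch behind a
flag) compare corrected deltas between the obese and matched-control groups
over the whole lifespan and within age strata (18-40, 40-60, 60+); Pearson
chi-square compares categorical demographics.  A summary-statistics entry
point reruns the same t formula from published mean (+/-SD) and N, so printed
comparison tables can be recomputed without raw data.

The statistics are computed from their closed forms; scipy supplies only the
t and chi-square distribution functions, which keeps scipy.stats.ttest_ind /
chi2_contingency available as independent cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "AgeStratum",
    "DEFAULT_STRATA",
    "summarize",
    "compare_deltas",
    "compare_from_summaries",
    "stratify",
    "chi_square_table",
    "delta_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean (+/-SD) and N for one group, as printed in cohort tables."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be non-negative")


@dataclass(frozen=True)
class GroupComparison:
    summary_a: GroupSummary
    summary_b: GroupSummary
    mean_difference: float  # mean_b - mean_a
    t_statistic: float
    df: float
    p_value: float
    two_tailed: bool = True


@dataclass(frozen=True)
class AgeStratum:
    label: str
    lower: float
    upper: float  # half-open: [lower, upper)

    def contains(self, age: float) -> bool:
        return self.lower <= age < self.upper


#: Half-open default strata: the labels "18-40 / 40-60 / over 60" overlap at
#: the boundaries, so 40.0 falls in mid-age and 60.0 in older.
DEFAULT_STRATA: tuple[AgeStratum, ...] = (
    AgeStratum("younger", 18.0, 40.0),
    AgeStratum("mid-age", 40.0, 60.0),
    AgeStratum("older", 60.0, math.inf),
)


def summarize(label: str, values: np.ndarray) -> GroupSummary:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations per group")
    return GroupSummary(label=label, n=int(x.size), mean=float(x.mean()),
                        sd=float(x.std(ddof=1)))


def compare_from_summaries(
    s1: GroupSummary, s2: GroupSummary, welch: bool = False
) -> GroupComparison:
    """Two-sample two-tailed t-test driven by summary statistics.

    Pooled-variance (Student's) t by default; Welch's unequal-variance t
    behind the flag.  A zero-variance comparison returns a documented
    sentinel: t = +/-inf with p = 0 when the means differ, t = 0 with p = 1
    when they do not.
    """
    diff = s2.mean - s1.mean
    if welch:
        v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
        se = math.sqrt(v1 + v2)
        if se == 0.0:
            return _degenerate(s1, s2, diff)
        df = (v1 + v2) ** 2 / (
            v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1)
        )
    else:
        df = s1.n + s2.n - 2
        sp2 = ((s1.n - 1) * s1.sd**2 + (s2.n - 1) * s2.sd**2) / df
        se = math.sqrt(sp2 * (1.0 / s1.n + 1.0 / s2.n))
        if se == 0.0:
            return _degenerate(s1, s2, diff)
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(
        summary_a=s1, summary_b=s2, mean_difference=diff,
        t_statistic=float(t), df=float(df), p_value=float(min(p, 1.0)),
    )


def _degenerate(s1: GroupSummary, s2: GroupSummary, diff: float) -> GroupComparison:
    t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    p = 1.0 if diff == 0 else 0.0
    return GroupComparison(
        summary_a=s1, summary_b=s2, mean_difference=diff,
        t_statistic=t, df=float(s1.n + s2.n - 2), p_value=p,
    )


def compare_deltas(
    deltas_a: np.ndarray,
    deltas_b: np.ndarray,
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> GroupComparison:
    """Two-tailed t-test on raw delta vectors.

    Delegates to :func:`compare_from_summaries` via :func:`summarize`, so the
    raw-data and summary-statistics paths agree exactly by construction.
    """
    return compare_from_summaries(
        summarize(labels[0], deltas_a), summarize(labels[1], deltas_b), welch=welch
    )


def stratify(
    ages: np.ndarray,
    deltas: np.ndarray,
    strata: tuple[AgeStratum, ...] = DEFAULT_STRATA,
) -> dict[str, np.ndarray]:
    """Split deltas into age strata; every age must fall in exactly one."""
    ages = np.asarray(ages, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    if ages.size != deltas.size:
        raise ValueError("ages and deltas lengths differ")
    out: dict[str, np.ndarray] = {}
    assigned = np.zeros(ages.size, dtype=bool)
    for stratum in strata:
        mask = (ages >= stratum.lower) & (ages < stratum.upper)
        if (assigned & mask).any():
            raise ValueError(f"strata overlap at stratum {stratum.label!r}")
        assigned |= mask
        out[stratum.label] = deltas[mask]
    if not assigned.all():
        bad = ages[~assigned][0]
        raise ValueError(f"age {bad} not covered by any stratum")
    return out


def chi_square_table(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table (no continuity correction).

    Returns (statistic, df, p).  Expected counts come from the product of
    the margins; df = (rows - 1) * (cols - 1).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all row and column sums must be positive")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def delta_report(
    ages_a: np.ndarray,
    deltas_a: np.ndarray,
    ages_b: np.ndarray,
    deltas_b: np.ndarray,
    labels: tuple[str, str] = ("NWc", "O"),
    strata: tuple[AgeStratum, ...] = DEFAULT_STRATA,
    modality: str = "gm",
    welch: bool = False,
) -> pd.DataFrame:
    """Comparison table across the lifespan and per age stratum.

    One row per scope (lifespan plus each stratum with n >= 2 in both
    groups): group means (+/-SD) and n, t, p, and the mean difference
    (group b minus group a).
    """
    rows = []
    scopes: list[tuple[str, np.ndarray, np.ndarray]] = [
        ("lifespan", np.asarray(deltas_a, float), np.asarray(deltas_b, float))
    ]
    strat_a = stratify(ages_a, deltas_a, strata)
    strat_b = stratify(ages_b, deltas_b, strata)
    for stratum in strata:
        scopes.append((stratum.label, strat_a[stratum.label], strat_b[stratum.label]))
    for scope, xa, xb in scopes:
        if xa.size < 2 or xb.size < 2:
            continue
        cmp = compare_deltas(xa, xb, labels=labels, welch=welch)
        rows.append(
            {
                "modality": modality,
                "scope": scope,
                f"n_{labels[0]}": cmp.summary_a.n,
                f"mean_{labels[0]}": cmp.summary_a.mean,
                f"sd_{labels[0]}": cmp.summary_a.sd,
                f"n_{labels[1]}": cmp.summary_b.n,
                f"mean_{labels[1]}": cmp.summary_b.mean,
                f"sd_{labels[1]}": cmp.summary_b.sd,
                "t": cmp.t_statistic,
                "p": cmp.p_value,
                "mean_difference": cmp.mean_difference,
            }
        )
    return pd.DataFrame(rows)
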