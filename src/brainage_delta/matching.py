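"""Iterative case-control matching.

Builds the held-out obese (case) and normal-weight control groups by greedy
1:1 nearest-age matching without replacement: for each case the admissible
control with the smallest absolute age difference is taken, subject to a
maximum age difference (default 5 years), same sex, and education level
differing by at most one ordinal unit.  A case with no admissible control is
excluded rather than matched loosely.

Cases are processed in descending age order (ties broken by id): the oldest
cases face the scarcest candidate pools, so serving them first minimises
avoidable exclusions.  Ties between equally close candidates go to the
smaller education difference, then the lexicographically smaller id, making
the result invariant to the input ordering of the candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["MatchConstraints", "MatchResult", "match_controls"]


@dataclass(frozen=True)
class MatchConstraints:
    max_age_diff: float = 5.0
    require_same_sex: bool = True
    max_education_diff: int = 1

    def __post_init__(self) -> None:
        if self.max_age_diff <= 0:
            raise ValueError("max_age_diff must be positive")
        if self.max_education_diff < 0:
            raise ValueError("max_education_diff must be non-negative")


@dataclass
class MatchResult:
    """Pairs plus the bookkeeping of who could not be matched."""

    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    excluded_cases: list[str] = field(default_factory=list)
    unused_controls: list[str] = field(default_factory=list)

    @property
    def case_ids(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [p[1] for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["case_id", "control_id", "age_diff"]
        )


def _check_table(table: pd.DataFrame, name: str) -> None:
    required = {"id", "age", "sex", "education"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    if table["id"].duplicated().any():
        dup = table.loc[table["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate id {dup!r} in {name} table")


def match_controls(
    cases: pd.DataFrame,
    candidates: pd.DataFrame,
    constraints: MatchConstraints | None = None,
) -> MatchResult:
    """Greedy 1:1 nearest-age matching of cases to controls.

    Parameters
    ----------
    cases, candidates
        Participant tables with at least ``id``, ``age``, ``sex`` and
        ``education`` columns; their id sets must be disjoint.
    constraints
        Admissibility rules; defaults to the 5-year / same-sex / one
        education-unit caliper.

    Returns
    -------
    MatchResult with one pair per matchable case (each control used at most
    once), the excluded cases, and the controls left unused.  An empty
    candidate pool yields all cases excluded, not an exception.
    """
    constraints = constraints or MatchConstraints()
    _check_table(cases, "cases")
    _check_table(candidates, "candidates")
    overlap = set(cases["id"]) & set(candidates["id"])
    if overlap:
        raise ValueError(f"cases and candidates share ids: {sorted(overlap)[:5]}")

    case_order = cases.sort_values(
        ["age", "id"], ascending=[False, True]
    ).reset_index(drop=True)
    pool = candidates.set_index("id")
    available = set(pool.index)

    result = MatchResult()
    for row in case_order.itertuples(index=False):
        best: tuple[float, int, str] | None = None  # (age_diff, edu_diff, id)
        for cid in available:
            cand = pool.loc[cid]
            age_diff = abs(float(row.age) - float(cand["age"]))
            if age_diff > constraints.max_age_diff:
                continue
            if constraints.require_same_sex and cand["sex"] != row.sex:
                continue
            edu_diff = abs(int(row.education) - int(cand["education"]))
            if edu_diff > constraints.max_education_diff:
                continue
            key = (age_diff, edu_diff, cid)
            if best is None or key < best:
                best = key
        if best is None:
            result.excluded_cases.append(row.id)
        else:
            age_diff, _, cid = best
            available.discard(cid)
            result.pairs.append((row.id, cid, age_diff))
    result.unused_controls = sorted(available)
    return result
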