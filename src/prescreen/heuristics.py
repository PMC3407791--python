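"""Heuristic-evaluation analysis: severity classification and HCDIM profiles.

Expert usability inspection against Nielsen's ten principles yields, per
expert and heuristic, a rating on a 5-point scale from 0 (no usability
problem) to 4 (usability catastrophe). Ratings are averaged per heuristic
and the average classified:

* ``major``    — average >= 2.75 ("at least 2.75", inclusive boundary)
* ``minor``    — 1.5 <= average < 2.75
* ``cosmetic`` — average < 1.5 (strict boundary)

The thresholds partition [0, 4]: every average maps to exactly one label.

Independently, each item of the heuristic checklist instrument is assigned
a category of the Human Centered Distributed Information model (HCDIM):
*representational* (how information is displayed and flows),
*task* (the system's fit to the user's task sequence), or
*functional* (top-level domain structure). Per heuristic, the three
category percentages sum to 100 whenever any items exist, and together
with severity they predict where usability problems will surface.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from .errors import InputError

__all__ = [
    "NIELSEN_HEURISTICS",
    "Severity",
    "HcdimCategory",
    "HeuristicSummary",
    "average_rating",
    "classify_severity",
    "hcdim_proportions",
    "summarize",
    "read_ratings",
    "read_assignments",
    "summary_frame",
]

MAJOR_THRESHOLD = 2.75  # inclusive
COSMETIC_THRESHOLD = 1.5  # strict upper bound for cosmetic

NIELSEN_HEURISTICS = {
    1: "Visibility of System Status",
    2: "Match Between System and Real World",
    3: "User Control and Freedom",
    4: "Consistency and Standards",
    5: "Help Users Recognize, Diagnose, and Recover From Errors",
    6: "Error Prevention",
    7: "Recognition Rather Than Recall",
    8: "Flexibility and Ease of Use",
    9: "Aesthetic and Minimalist Design",
    10: "Help and Documentation",
}


class Severity(str, Enum):
    COSMETIC = "cosmetic"
    MINOR = "minor"
    MAJOR = "major"


class HcdimCategory(str, Enum):
    REPRESENTATIONAL = "representational"
    TASK = "task"
    FUNCTIONAL = "functional"


@dataclass(frozen=True, slots=True)
class HcdimProportions:
    pct_representational: float
    pct_task: float
    pct_functional: float
    n_items: int

    @property
    def empty(self) -> bool:
        return self.n_items == 0


@dataclass(frozen=True, slots=True)
class HeuristicSummary:
    heuristic_id: int
    name: str
    average_rating: float
    severity: Severity
    hcdim: HcdimProportions


def average_rating(ratings: Sequence[int]) -> float:
    """Arithmetic mean of expert ratings; not rounded internally."""
    if len(ratings) == 0:
        raise InputError("no ratings to average")
    for r in ratings:
        if not isinstance(r, int) or isinstance(r, bool) or not 0 <= r <= 4:
            raise InputError(f"rating {r!r} outside the 0-4 scale")
    return sum(ratings) / len(ratings)


def classify_severity(average: float) -> Severity:
    """Map an average rating in [0, 4] to a severity label."""
    if not 0 <= average <= 4:
        raise InputError(f"average rating {average!r} outside [0, 4]")
    if average >= MAJOR_THRESHOLD:
        return Severity.MAJOR
    if average < COSMETIC_THRESHOLD:
        return Severity.COSMETIC
    return Severity.MINOR


def hcdim_proportions(categories: Iterable[str | HcdimCategory]) -> HcdimProportions:
    """Percentage of checklist items per HCDIM category (sums to 100, or
    all-zero with ``empty`` set when no items exist)."""
    counts = {c: 0 for c in HcdimCategory}
    n = 0
    for raw in categories:
        try:
            cat = HcdimCategory(str(raw).strip().lower())
        except ValueError:
            raise InputError(f"unknown HCDIM category {raw!r}") from None
        counts[cat] += 1
        n += 1
    if n == 0:
        return HcdimProportions(0.0, 0.0, 0.0, 0)
    return HcdimProportions(
        pct_representational=100.0 * counts[HcdimCategory.REPRESENTATIONAL] / n,
        pct_task=100.0 * counts[HcdimCategory.TASK] / n,
        pct_functional=100.0 * counts[HcdimCategory.FUNCTIONAL] / n,
        n_items=n,
    )


def summarize(
    ratings: pd.DataFrame, assignments: pd.DataFrame | None = None
) -> list[HeuristicSummary]:
    """One summary per heuristic present in the ratings table.

    ``ratings`` needs columns ``heuristic_id``, ``expert_id``, ``rating``;
    ``assignments`` (optional) needs ``heuristic_id``, ``item_id``,
    ``category``. Row order is irrelevant — the mean is symmetric.
    """
    for col in ("heuristic_id", "expert_id", "rating"):
        if col not in ratings.columns:
            raise InputError(f"ratings table: missing column {col!r}")
    summaries: list[HeuristicSummary] = []
    for hid, group in ratings.groupby("heuristic_id"):
        hid = int(hid)
        if not 1 <= hid <= 10:
            raise InputError(f"heuristic_id {hid} outside 1-10")
        avg = average_rating([int(r) for r in group["rating"]])
        if assignments is not None and len(assignments):
            sub = assignments[assignments["heuristic_id"].astype(int) == hid]
            hcdim = hcdim_proportions(sub["category"])
        else:
            hcdim = HcdimProportions(0.0, 0.0, 0.0, 0)
        summaries.append(
            HeuristicSummary(
                heuristic_id=hid,
                name=NIELSEN_HEURISTICS[hid],
                average_rating=avg,
                severity=classify_severity(avg),
                hcdim=hcdim,
            )
        )
    summaries.sort(key=lambda s: s.heuristic_id)
    return summaries


def read_ratings(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("heuristic_id", "expert_id", "rating"):
        if col not in frame.columns:
            raise InputError(f"{Path(path).name}: missing column {col!r}")
    return frame


def read_assignments(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in ("heuristic_id", "item_id", "category"):
        if col not in frame.columns:
            raise InputError(f"{Path(path).name}: missing column {col!r}")
    return frame


def summary_frame(summaries: list[HeuristicSummary]) -> pd.DataFrame:
    """Tabular rendering: averages shown to 2 decimals, percentages to 1."""
    return pd.DataFrame(
        [
            {
                "heuristic_id": s.heuristic_id,
                "heuristic": s.name,
                "pct_representational": round(s.hcdim.pct_representational, 1),
                "pct_task": round(s.hcdim.pct_task, 1),
                "pct_functional": round(s.hcdim.pct_functional, 1),
                "average_rating": round(s.average_rating, 2),
                "severity": s.severity.value,
            }
            for s in summaries
        ]
    )
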