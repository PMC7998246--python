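"""Weighted-ranking score for heterogeneously stained IHC sections.

Semi-quantitative immunohistochemistry assigns each region of a stained
section an ordinal intensity grade (0, 1+, 2+, 3+).  For markers with
strong intra-tumoral heterogeneity a single ordinal call throws away most
of the information, so instead each full-face section is profiled as the
percentage of tissue area at each grade and the profile is collapsed into
a single *cumulative intensity score*

    score = 0.25 * %1+  +  0.5 * %2+  +  1.0 * %3+

ranging over 0-100.  Unlike the classical H-score (weights 1/2/3, range
0-300), the weights here halve with each step down in grade, so the score
reads directly as a percentage-like quantity: 100 means the whole section
stained 3+.  Sections are then banded into hypo-intense (<33),
intermediate (33-66) and hyper-intense (>66) expression categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "IntensityProfile",
    "ScoreWeights",
    "CategoryThresholds",
    "ScoreResult",
    "HYPO",
    "INTERMEDIATE",
    "HYPER",
    "CATEGORIES",
    "weighted_score",
    "classify",
    "score_cases",
]

#: Category labels, ordered from weakest to strongest staining.
HYPO = "hypo-intense"
INTERMEDIATE = "intermediate"
HYPER = "hyper-intense"
CATEGORIES = (HYPO, INTERMEDIATE, HYPER)

#: Absolute tolerance used for threshold and bound comparisons so that a
#: score arithmetically equal to a boundary is never misclassified by
#: floating-point noise.
_EPS = 1e-9

#: Percentage profiles are hand-entered by pathologists; sums slightly over
#: 100 occur in practice (e.g. thirds entered as 33/33/33... rounded up).
#: Sums in (100, 100 + _SUM_SLACK] are accepted with a warning.
_SUM_SLACK = 1.0


class ProfileError(ValueError):
    """Raised when an intensity profile violates its invariants."""


@dataclass(frozen=True)
class IntensityProfile:
    """Percentages of tissue area at each staining grade.

    ``p1``, ``p2``, ``p3`` are the percentages scored 1+, 2+ and 3+.
    ``p0`` (unstained) defaults to the remainder to 100 and is clamped to
    0 when the graded percentages over-run 100 by rounding slack.
    """

    p1: float
    p2: float
    p3: float
    p0: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3"):
            v = getattr(self, name)
            if not (-_EPS <= v <= 100 + _EPS):
                raise ProfileError(
                    f"{name}={v!r} is outside [0, 100]"
                )
        total = self.p1 + self.p2 + self.p3
        if total > 100 + _SUM_SLACK + _EPS:
            raise ProfileError(
                f"graded percentages sum to {total}, exceeding 100 by more "
                f"than the permitted slack of {_SUM_SLACK}"
            )
        if self.p0 is None:
            if total > 100 + _EPS:
                warnings.warn(
                    f"graded percentages sum to {total} > 100; "
                    "treating unstained fraction as 0",
                    stacklevel=3,
                )
                object.__setattr__(self, "p0", 0.0)
            else:
                object.__setattr__(self, "p0", 100.0 - total)
        elif not (-_EPS <= self.p0 <= 100 + _EPS):
            raise ProfileError(f"p0={self.p0!r} is outside [0, 100]")

    def as_fractions(self) -> tuple[float, float, float, float]:
        """Return (f0, f1, f2, f3) normalised to sum to 1."""
        total = self.p0 + self.p1 + self.p2 + self.p3
        return (self.p0 / total, self.p1 / total, self.p2 / total, self.p3 / total)


@dataclass(frozen=True)
class ScoreWeights:
    """Per-percent weight at each graded intensity.

    Defaults halve with each grade step down from 3+: a percent of 3+
    tissue contributes a full point, 2+ half a point, 1+ a quarter point.
    """

    w1: float = 0.25
    w2: float = 0.5
    w3: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.w1 <= self.w2 <= self.w3):
            raise ValueError(
                f"weights must satisfy 0 <= w1 <= w2 <= w3, got "
                f"({self.w1}, {self.w2}, {self.w3})"
            )


@dataclass(frozen=True)
class CategoryThresholds:
    """Score boundaries between the three expression bands.

    Scores strictly below ``low_cut`` are hypo-intense, strictly above
    ``high_cut`` hyper-intense, and everything between (boundaries
    included) intermediate.
    """

    low_cut: float = 33.0
    high_cut: float = 66.0

    def __post_init__(self) -> None:
        if not (0 < self.low_cut < self.high_cut < 100):
            raise ValueError(
                f"need 0 < low_cut < high_cut < 100, got "
                f"({self.low_cut}, {self.high_cut})"
            )


@dataclass(frozen=True)
class ScoreResult:
    """Cumulative score, its per-grade components and the assigned band."""

    score: float
    category: str
    components: tuple[float, float, float]


DEFAULT_WEIGHTS = ScoreWeights()
DEFAULT_THRESHOLDS = CategoryThresholds()


def weighted_score(
    profile: IntensityProfile, weights: ScoreWeights = DEFAULT_WEIGHTS
) -> float:
    """Cumulative intensity score ``w1*p1 + w2*p2 + w3*p3``.

    With the default weights the score lies in [0, 100] and equals 100
    exactly when the whole section stained 3+.
    """
    return weights.w1 * profile.p1 + weights.w2 * profile.p2 + weights.w3 * profile.p3


def classify(
    score: float, thresholds: CategoryThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Band a cumulative score as hypo-intense / intermediate / hyper-intense.

    Boundary scores (exactly ``low_cut`` or ``high_cut``) are intermediate;
    comparisons carry a 1e-9 absolute tolerance so arithmetic that lands on
    a boundary is classified stably.
    """
    if not (-_EPS <= score <= 100 + _EPS):
        raise ValueError(f"score {score!r} is outside [0, 100]")
    if score < thresholds.low_cut - _EPS:
        return HYPO
    if score > thresholds.high_cut + _EPS:
        return HYPER
    return INTERMEDIATE


def score_profile(
    profile: IntensityProfile,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
    thresholds: CategoryThresholds = DEFAULT_THRESHOLDS,
) -> ScoreResult:
    """Score one profile and classify it in a single step."""
    components = (
        weights.w1 * profile.p1,
        weights.w2 * profile.p2,
        weights.w3 * profile.p3,
    )
    score = sum(components)
    return ScoreResult(score=score, category=classify(score, thresholds), components=components)


def _round_half_up(x: float) -> int:
    # Python's round() is banker's rounding; category percentages are
    # reported with conventional half-up rounding (e.g. 43.5 -> 44).
    import math

    return int(math.floor(x + 0.5))


def score_cases(
    cases: Iterable,  # Iterable[CaseRecord]; kept loose to avoid an import cycle
    weights: ScoreWeights = DEFAULT_WEIGHTS,
    thresholds: CategoryThresholds = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, int]]:
    """Score a cohort of cases with full-face percentage profiles.

    Returns ``(table, counts, percentages)`` where *table* has one row per
    case in input order with component, score and category columns;
    *counts* is the category histogram and *percentages* the histogram as
    integer percents (rounded half-up).

    Raises :class:`ProfileError` mentioning the offending case id if any
    case fails profile validation.
    """
    rows = []
    for case in cases:
        profile = case.profile
        if profile is None:
            raise ProfileError(f"case {case.case_id!r} has no intensity profile")
        try:
            res = score_profile(profile, weights, thresholds)
        except (ProfileError, ValueError) as exc:
            raise ProfileError(f"case {case.case_id!r}: {exc}") from exc
        row = {
            "case_id": case.case_id,
            "pct_1plus": profile.p1,
            "pct_2plus": profile.p2,
            "pct_3plus": profile.p3,
            "component_1": res.components[0],
            "component_2": res.components[1],
            "component_3": res.components[2],
            "cumulative_score": res.score,
            "category": res.category,
        }
        row.update(getattr(case, "covariates", {}) or {})
        rows.append(row)
    table = pd.DataFrame(rows)
    counts = {cat: int((table["category"] == cat).sum()) for cat in CATEGORIES}
    n = len(table)
    percentages = {
        cat: _round_half_up(100.0 * c / n) if n else 0 for cat, c in counts.items()
    }
    return table, counts, percentages
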