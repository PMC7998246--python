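"""Duplicate-core aggregation and concordance accounting for TMA scores.

A tissue microarray (TMA) carries one or two small cylindrical cores per
patient, each given a single ordinal staining score (0, 1+, 2+, 3+).  When
a marker is heterogeneously expressed, the two cores of one patient often
disagree; the fraction of discordant duplicates is a direct, if coarse,
read-out of intra-tumoral heterogeneity.  For downstream analysis a
patient's cores are collapsed by adopting the higher score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "CoreScore",
    "CaseCoreSet",
    "HIGH",
    "LOW_MODERATE",
    "aggregate_case",
    "dichotomize",
    "concordance_summary",
]

HIGH = "high"
LOW_MODERATE = "low_moderate"

VALID_SCORES = frozenset({0, 1, 2, 3})


@dataclass(frozen=True)
class CoreScore:
    """One ordinal intensity call (0..3) on one core of one case."""

    case_id: str
    core_id: str
    score: int

    def __post_init__(self) -> None:
        _check_score(self.score)


@dataclass(frozen=True)
class CaseCoreSet:
    """All core scores belonging to one case (usually 1 or 2 cores)."""

    case_id: str
    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.scores) == 0:
            raise ValueError(f"case {self.case_id!r} has no core scores")
        for s in self.scores:
            _check_score(s)


def _check_score(score: int) -> None:
    if score not in VALID_SCORES:
        raise ValueError(f"core score must be an integer in 0..3, got {score!r}")


def aggregate_case(scores: CaseCoreSet | Sequence[int]) -> int:
    """Collapse a case's core scores to one ordinal score: the maximum.

    Discordant duplicates are resolved in favour of the higher score, the
    convention for ordinal IHC calls on duplicate cores.  Order-invariant
    and idempotent under duplication of identical scores.
    """
    values = scores.scores if isinstance(scores, CaseCoreSet) else tuple(scores)
    if len(values) == 0:
        raise ValueError("cannot aggregate an empty score set")
    for s in values:
        _check_score(s)
    return max(values)


def dichotomize(score: int) -> str:
    """Split an ordinal score into high (3+) vs low/moderate (0, 1+, 2+).

    Score 0 is grouped with low/moderate so that "high" means exactly 3+
    and every scored case lands in one of the two bins.
    """
    _check_score(score)
    return HIGH if score == 3 else LOW_MODERATE


def _is_concordant(scores: Sequence[int], adjacent: bool) -> bool:
    if adjacent:
        return max(scores) - min(scores) <= 1
    return len(set(scores)) == 1


def concordance_summary(
    cases: Iterable[CaseCoreSet],
    restrict_to_high: bool = False,
    adjacent: bool = False,
) -> dict:
    """Count concordant vs discordant multi-core cases.

    A case is eligible if it has at least two cores (singletons are
    counted separately, not dropped silently) and, when
    ``restrict_to_high`` is set, its maximum core score is 3+.  A case is
    concordant iff all its core scores are equal; with ``adjacent=True``
    scores within one grade of each other also count as concordant.

    Percentages are reported rounded to the nearest integer percent.
    """
    n_single = 0
    n_conc = 0
    n_disc = 0
    for case in cases:
        if len(case.scores) < 2:
            n_single += 1
            continue
        if restrict_to_high and aggregate_case(case) != 3:
            continue
        if _is_concordant(case.scores, adjacent):
            n_conc += 1
        else:
            n_disc += 1
    n_eligible = n_conc + n_disc
    if n_eligible:
        pct_conc = round(100.0 * n_conc / n_eligible)
        pct_disc = round(100.0 * n_disc / n_eligible)
    else:
        pct_conc = pct_disc = 0
    return {
        "n_eligible": n_eligible,
        "n_concordant": n_conc,
        "n_discordant": n_disc,
        "n_single_core": n_single,
        "pct_concordant": pct_conc,
        "pct_discordant": pct_disc,
    }
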