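"""Aggregation of improvement scores to framework groups and tiers.

Scores are averaged per (jurisdiction, tier, group) cell — and per
(jurisdiction, tier) for tier-level summaries — denominated by the number of
viable indicator scores in the cell.  Tier means therefore average over
indicators directly, not over group means.  The SEM uses the sample (n−1)
standard deviation, and the 95% interval mean ± 1.96·SEM is descriptive
display metadata only, not a significance test.

Records from merged jurisdictions (e.g. "Vic+Tas") or national-only rows are
scored upstream but cannot be allocated to a single state/territory panel;
they are excluded here.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .framework import (
    UNDEFINED,
    FrameworkSpec,
    GroupSummary,
    ScoreRecord,
    load_framework,
)

__all__ = [
    "aggregate",
    "ci_bounds",
    "summaries_to_frame",
    "summaries_from_frame",
    "ScoreAggregator",
]

logger = logging.getLogger(__name__)

#: Normal-approximation multiplier for the displayed 95% interval.
CI_MULTIPLIER = 1.96


def ci_bounds(mean: float, sem: float) -> tuple[float, float]:
    """Displayed 95% interval (mean − 1.96·SEM, mean + 1.96·SEM)."""
    half = CI_MULTIPLIER * float(sem)
    return float(mean) - half, float(mean) + half


def _summarise(
    jurisdiction: str,
    tier_number: int,
    group_name: Optional[str],
    scores: Sequence[int],
) -> GroupSummary:
    n = len(scores)
    mean = float(np.mean(scores))
    if n > 1:
        sem = float(np.std(scores, ddof=1) / math.sqrt(n))
        low, high = ci_bounds(mean, sem)
    else:
        sem = low = high = UNDEFINED
    return GroupSummary(
        jurisdiction=jurisdiction,
        tier_number=tier_number,
        group_name=group_name,
        n_indicators=n,
        mean_score=mean,
        sem=sem,
        ci_low=low,
        ci_high=high,
    )


def aggregate(
    scores: Sequence[ScoreRecord],
    spec: FrameworkSpec,
    level: str = "group",
) -> list[GroupSummary]:
    """Summarise score records per (jurisdiction, tier[, group]) cell.

    Every record's measure code must resolve into *spec*; non-allocatable
    records (merged jurisdictions, national-only rows) are excluded and
    logged.  Cells with no viable indicator are simply omitted — the output
    never contains NaN summaries.
    """
    if level not in ("group", "tier"):
        raise ValueError(f"level must be 'group' or 'tier', got {level!r}")
    cells: dict[tuple, list[int]] = {}
    n_skipped = 0
    for record in scores:
        if not record.allocatable:
            n_skipped += 1
            continue
        tier, group = spec.locate(record.measure_code)  # KeyError if unknown
        key = (
            (record.jurisdiction, tier.number, group.name)
            if level == "group"
            else (record.jurisdiction, tier.number, None)
        )
        cells.setdefault(key, []).append(record.improvement_score)
    if n_skipped:
        logger.info(
            "%d non-allocatable score(s) excluded from %s averages",
            n_skipped, level,
        )
    if not cells:
        logger.warning("no allocatable scores: empty %s summary", level)

    # deterministic output order: framework declaration order, then jurisdiction
    group_order = {
        (t.number, g.name): i
        for i, (t, g) in enumerate(
            (t, g) for t in spec.tiers for g in t.groups
        )
    }
    ordered = sorted(
        cells.items(),
        key=lambda kv: (
            kv[0][0],
            kv[0][1],
            group_order.get((kv[0][1], kv[0][2]), -1),
        ),
    )
    # sorting each cell makes the summaries exactly permutation invariant
    return [
        _summarise(juris, tier_number, group_name, sorted(cell_scores))
        for (juris, tier_number, group_name), cell_scores in ordered
    ]


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Tabulate summaries; UNDEFINED SEM/CI (n = 1 cells) become NaN."""
    rows = [
        {
            "jurisdiction": s.jurisdiction,
            "tier": s.tier_number,
            "group": s.group_name if s.group_name is not None else "",
            "n": s.n_indicators,
            "mean": s.mean_score,
            "sem": np.nan if s.sem is UNDEFINED else s.sem,
            "ci_low": np.nan if s.ci_low is UNDEFINED else s.ci_low,
            "ci_high": np.nan if s.ci_high is UNDEFINED else s.ci_high,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=["jurisdiction", "tier", "group", "n", "mean", "sem",
                 "ci_low", "ci_high"],
    )


def summaries_from_frame(frame: pd.DataFrame) -> list[GroupSummary]:
    """Inverse of :func:`summaries_to_frame` (NaN SEM/CI become UNDEFINED)."""
    summaries = []
    for row in frame.itertuples(index=False):
        sem = getattr(row, "sem")
        undefined = pd.isna(sem)
        group = getattr(row, "group", "")
        summaries.append(
            GroupSummary(
                jurisdiction=str(row.jurisdiction),
                tier_number=int(row.tier),
                group_name=None if pd.isna(group) or group == "" else str(group),
                n_indicators=int(row.n),
                mean_score=float(row.mean),
                sem=UNDEFINED if undefined else float(sem),
                ci_low=UNDEFINED if undefined else float(row.ci_low),
                ci_high=UNDEFINED if undefined else float(row.ci_high),
            )
        )
    return summaries


class ScoreAggregator(TransformerMixin, BaseEstimator):
    """Aggregate a score table to group or tier summaries, sklearn style.

    Input ``X`` is the score DataFrame produced by
    :class:`~hpfscore.scoring.ImprovementScorer` (columns ``jurisdiction``,
    ``measure_code``, ``score``, ``flags``).  ``transform`` returns the
    summary DataFrame of :func:`summaries_to_frame`.

    Parameters
    ----------
    level : {"group", "tier"}, default "group"
    framework : FrameworkSpec, optional
        Hierarchy to aggregate against; the bundled default when omitted.
    """

    def __init__(self, level: str = "group", framework: Optional[FrameworkSpec] = None):
        self.level = level
        self.framework = framework

    def fit(self, X: pd.DataFrame, y=None) -> "ScoreAggregator":
        if self.level not in ("group", "tier"):
            raise ValueError(f"level must be 'group' or 'tier', got {self.level!r}")
        self.framework_ = self.framework or load_framework()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "framework_")
        required = {"jurisdiction", "measure_code", "score"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"X is missing column(s) {sorted(missing)}")
        records = _frame_to_minimal_records(X)
        return summaries_to_frame(aggregate(records, self.framework_, self.level))


def _frame_to_minimal_records(X: pd.DataFrame) -> list[ScoreRecord]:
    """Rebuild just enough of each ScoreRecord for aggregation."""
    records = []
    for row in X.itertuples(index=False):
        flags = str(getattr(row, "flags", "") or "")
        score = int(row.score)
        precluded = "confidence_precluded" in flags
        records.append(
            ScoreRecord(
                indicator_id=str(row.indicator_id),
                jurisdiction=str(row.jurisdiction),
                measure_code=str(row.measure_code),
                value_t1=0.0,
                value_t2=0.0,
                delta=UNDEFINED,
                pct_change=UNDEFINED,
                lad=UNDEFINED,
                unit_change=0 if score == 0 else (1 if score > 0 else -1),
                c1=0,
                c2=0,
                improvement_score=score,
                confidence_precluded=precluded,
                allocatable="non_allocatable" not in flags,
            )
        )
    return records
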