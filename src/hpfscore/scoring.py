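"""Two-timepoint improvement scoring.

For each indicator *i* and jurisdiction, with published values T1 and T2:

* Δ = T2 − T1 and the unit change indicator U = sign(Δ) ∈ {−1, 0, +1};
* %Δ = 100·(T2 − T1)/T1, UNDEFINED on a zero baseline;
* C1 = 1 when |%Δ| ≥ τ (relative-change confidence, default τ = 2%);
* C2 = 1 when |Δ| ≥ q·LAD where LAD is the largest |Δ| observed by any
  jurisdiction for that indicator (comparative confidence, default q = 0.10);
* improvement score = direction × U × (1 + C1 + C2) ∈ {−3 … +3}, where
  *direction* is the indicator's direction of effect.

The sign of the score says whether things moved towards or away from
improvement; the magnitude (1–3) says how much confidence the two binary
indicators lend to that direction.  Suppressed ("n.p.") values preclude both
confidence indicators: the direction of change is still inferred (a value
too small to publish is taken to be below any published value), so the score
is bounded to ±1.

:class:`ImprovementScorer` wraps the same arithmetic as a scikit-learn
transformer over long-format DataFrames, so it composes with pipelines and
``get_params``/``set_params`` based tooling.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .framework import (
    SUPPRESSED,
    UNDEFINED,
    IndicatorDefinition,
    Observation,
    ScoreRecord,
    Thresholds,
    _Marker,
    is_merged_jurisdiction,
)
from .ingestion import NATIONAL_LABELS

__all__ = [
    "delta",
    "unit_change",
    "percent_change",
    "c1",
    "lad",
    "c2",
    "resolve_suppressed",
    "improvement_score",
    "score_indicator",
    "scores_to_frame",
    "ImprovementScorer",
]

logger = logging.getLogger(__name__)

Number = Union[int, float]
MaybeMarker = Union[float, _Marker]


def delta(t1: Number, t2: Number) -> float:
    """Between-report change Δ = T2 − T1 on the published (rounded) values."""
    if t1 is SUPPRESSED or t2 is SUPPRESSED:
        raise TypeError("suppressed value: use resolve_suppressed instead")
    return float(t2) - float(t1)


def unit_change(d: Number) -> int:
    """Direction of change U = sign(Δ): −1 decreased, 0 unchanged, +1 increased."""
    d = float(d)
    if d != d:
        raise ValueError("unit_change requires a finite delta")
    return -1 if d < 0 else (1 if d > 0 else 0)


def percent_change(t1: Number, t2: Number) -> MaybeMarker:
    """Relative change %Δ = 100·(T2 − T1)/T1; UNDEFINED on a zero baseline.

    A zero baseline never yields an infinity or a silent zero — downstream
    code must treat UNDEFINED explicitly.
    """
    t1 = float(t1)
    if t1 == 0.0:
        return UNDEFINED
    return 100.0 * (float(t2) - t1) / t1


def c1(pct: MaybeMarker, tau: float) -> Union[int, _Marker]:
    """Relative-change confidence: 1 when |%Δ| meets or exceeds τ.

    UNDEFINED percentage changes propagate (the indicator then relies on C2
    alone, capping the score magnitude at 2).
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    if pct is UNDEFINED:
        return UNDEFINED
    return 1 if abs(float(pct)) >= tau else 0


def lad(deltas: Sequence[Number]) -> MaybeMarker:
    """Largest absolute difference max|Δ| across a indicator's jurisdictions.

    Suppression-derived entries must already be excluded.  An empty list
    yields UNDEFINED (every dependent C2 becomes UNDEFINED).
    """
    numeric = [abs(float(d)) for d in deltas]
    if not numeric:
        return UNDEFINED
    return max(numeric)


def c2(d: Number, lad_value: MaybeMarker, q: float) -> Union[int, _Marker]:
    """Comparative confidence: 1 when |Δ| meets or exceeds q·LAD.

    Guards the degenerate cases: a zero LAD (nothing moved anywhere) or a
    zero Δ never earns the indicator, and an UNDEFINED LAD propagates.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if lad_value is UNDEFINED:
        return UNDEFINED
    lad_value = float(lad_value)
    if lad_value < 0:
        raise ValueError("LAD must be non-negative")
    d = float(d)
    if lad_value == 0.0 or d == 0.0:
        return 0
    return 1 if abs(d) >= q * lad_value else 0


def resolve_suppressed(t1: object, t2: object) -> tuple[int, bool]:
    """Infer the direction of change when a timepoint is suppressed.

    "n.p." marks a number too small to publish, hence quantitatively below
    any published value: (n.p., number) is an increase, (number, n.p.) a
    decrease, and (n.p., n.p.) no change.  Confidence indicators are
    precluded in all three cases; returns ``(U, confidence_precluded=True)``.
    """
    s1, s2 = t1 is SUPPRESSED, t2 is SUPPRESSED
    if not (s1 or s2):
        raise TypeError("resolve_suppressed requires at least one suppressed side")
    if s1 and s2:
        return 0, True
    return (1, True) if s1 else (-1, True)


def improvement_score(
    direction: int,
    u: int,
    c1v: Union[int, _Marker],
    c2v: Union[int, _Marker],
    confidence_precluded: bool,
) -> int:
    """Composite score = direction × U × (1 + C1 + C2) ∈ [−3, 3].

    UNDEFINED or precluded confidence indicators contribute 0, so the score
    magnitude is 1 + (number of confidence indicators earned), and the sign
    is positive exactly when the change ran in the direction of improvement.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    if u not in (-1, 0, 1):
        raise ValueError("u must be in {-1, 0, +1}")
    c1e = 0 if (confidence_precluded or c1v is UNDEFINED) else int(c1v)
    c2e = 0 if (confidence_precluded or c2v is UNDEFINED) else int(c2v)
    return direction * u * (1 + c1e + c2e)


def score_indicator(
    observations: Sequence[Observation],
    defn: IndicatorDefinition,
    thresholds: Thresholds = Thresholds(),
    zero_baseline_awards_c1: bool = False,
    lad_value: Optional[MaybeMarker] = None,
) -> list[ScoreRecord]:
    """Score one indicator across its jurisdictions.

    The LAD is computed once per indicator over the numerically complete
    jurisdictions (or supplied via *lad_value*, e.g. by a fitted
    :class:`ImprovementScorer`).  With ``zero_baseline_awards_c1=True`` a
    zero baseline with positive change earns C1 (the "infinite relative
    change" reading) instead of leaving it UNDEFINED.
    """
    if not observations:
        return []
    ids = {o.indicator_id for o in observations}
    if ids != {defn.indicator_id}:
        raise ValueError(
            f"observations for {sorted(ids)} passed with definition for "
            f"{defn.indicator_id!r}"
        )
    for o in observations:
        if o.value_t1 is None or o.value_t2 is None:
            raise ValueError(
                f"{o.indicator_id}/{o.jurisdiction}: incomplete observation; "
                "apply eligibility_filter first"
            )

    if lad_value is None:
        lad_value = lad(
            [
                delta(o.value_t1, o.value_t2)
                for o in observations
                if o.value_t1 is not SUPPRESSED and o.value_t2 is not SUPPRESSED
            ]
        )

    records: list[ScoreRecord] = []
    for o in observations:
        suppressed = o.value_t1 is SUPPRESSED or o.value_t2 is SUPPRESSED
        if suppressed:
            u, precluded = resolve_suppressed(o.value_t1, o.value_t2)
            d = pct = c1v = c2v = UNDEFINED
            logger.info(
                "%s/%s: suppressed timepoint, confidence precluded, U=%+d",
                o.indicator_id, o.jurisdiction, u,
            )
        else:
            d = delta(o.value_t1, o.value_t2)
            u = unit_change(d)
            precluded = False
            pct = percent_change(o.value_t1, o.value_t2)
            c1v = c1(pct, thresholds.tau)
            if c1v is UNDEFINED:
                if zero_baseline_awards_c1 and d > 0:
                    c1v = 1
                else:
                    logger.info(
                        "%s/%s: zero baseline, %%change undefined",
                        o.indicator_id, o.jurisdiction,
                    )
            c2v = c2(d, lad_value, thresholds.q)
        score = improvement_score(defn.direction_of_effect, u, c1v, c2v, precluded)
        allocatable = not (
            is_merged_jurisdiction(o.jurisdiction)
            or o.jurisdiction in NATIONAL_LABELS
        )
        if not allocatable:
            logger.info(
                "%s/%s: scored but not allocatable to a state/territory panel",
                o.indicator_id, o.jurisdiction,
            )
        records.append(
            ScoreRecord(
                indicator_id=o.indicator_id,
                jurisdiction=o.jurisdiction,
                measure_code=defn.measure_code,
                value_t1=o.value_t1,
                value_t2=o.value_t2,
                delta=d,
                pct_change=pct,
                lad=lad_value,
                unit_change=u,
                c1=c1v,
                c2=c2v,
                improvement_score=score,
                confidence_precluded=precluded,
                allocatable=allocatable,
            )
        )
    return records


def scores_to_frame(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Tabulate score records; markers become NaN (numeric) or flag strings."""
    rows = []
    for r in records:
        flags = []
        if r.confidence_precluded:
            flags.append("confidence_precluded")
        if not r.allocatable:
            flags.append("non_allocatable")
        if r.c1 is UNDEFINED and not r.confidence_precluded:
            flags.append("zero_baseline")
        rows.append(
            {
                "indicator_id": r.indicator_id,
                "jurisdiction": r.jurisdiction,
                "measure_code": r.measure_code,
                "t1": np.nan if r.value_t1 is SUPPRESSED else r.value_t1,
                "t2": np.nan if r.value_t2 is SUPPRESSED else r.value_t2,
                "delta": np.nan if r.delta is UNDEFINED else r.delta,
                "pct_change": np.nan if r.pct_change is UNDEFINED else r.pct_change,
                "lad": np.nan if r.lad is UNDEFINED else r.lad,
                "unit_change": r.unit_change,
                "c1": np.nan if r.c1 is UNDEFINED else r.c1,
                "c2": np.nan if r.c2 is UNDEFINED else r.c2,
                "score": r.improvement_score,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "indicator_id", "jurisdiction", "measure_code", "t1", "t2",
            "delta", "pct_change", "lad", "unit_change", "c1", "c2",
            "score", "flags",
        ],
    )


class ImprovementScorer(TransformerMixin, BaseEstimator):
    """Score long-format two-timepoint observations, scikit-learn style.

    The input ``X`` is a DataFrame with one row per (indicator,
    jurisdiction) and columns ``indicator_id``, ``jurisdiction``, ``t1``,
    ``t2``; NaN in a value column encodes a suppressed ("n.p.") cell.  The
    direction of effect comes from the ``registry`` parameter (an
    ``indicator_id`` → :class:`IndicatorDefinition` mapping, or a plain
    ``indicator_id`` → ±1 mapping) or from a ``direction`` column in ``X``.

    ``fit`` learns the per-indicator largest absolute difference (the C2
    comparator scale); ``transform`` scores rows against those fitted LADs,
    so held-out jurisdictions are judged on the same scale as the fitting
    data.  ``fit_transform(X)`` reproduces the plain per-indicator scoring.

    Parameters
    ----------
    tau : float, default 2.0
        Relative-change threshold for C1, in percent.
    q : float, default 0.10
        Fraction of the LAD defining the C2 threshold.
    registry : mapping, optional
        Per-indicator definitions or bare directions of effect.
    zero_baseline_awards_c1 : bool, default False
        Treat a zero baseline with positive change as infinitely large
        relative change (C1 earned) instead of UNDEFINED.

    Attributes
    ----------
    lad_ : pandas.Series
        Largest absolute difference per indicator_id seen during ``fit``.
    indicator_ids_ : ndarray
        Indicators seen during ``fit``.
    n_features_in_ : int
    """

    def __init__(
        self,
        tau: float = 2.0,
        q: float = 0.10,
        registry: Optional[Mapping] = None,
        zero_baseline_awards_c1: bool = False,
    ):
        self.tau = tau
        self.q = q
        self.registry = registry
        self.zero_baseline_awards_c1 = zero_baseline_awards_c1

    # -- helpers ----------------------------------------------------------

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of long-format "
                            "two-timepoint observations")
        required = {"indicator_id", "jurisdiction", "t1", "t2"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"X is missing column(s) {sorted(missing)}")
        if self.registry is None and "direction" not in X.columns:
            raise ValueError(
                "no registry given and X has no 'direction' column; the "
                "direction of effect is required for every indicator"
            )
        return X

    def _definition(self, X: pd.DataFrame, indicator_id: str) -> IndicatorDefinition:
        entry = None if self.registry is None else self.registry.get(indicator_id)
        if isinstance(entry, IndicatorDefinition):
            return entry
        if entry is None:
            directions = (
                X.loc[X["indicator_id"] == indicator_id, "direction"].unique()
            )
            if len(directions) != 1:
                raise ValueError(
                    f"{indicator_id}: ambiguous or missing direction of effect"
                )
            entry = directions[0]
        return IndicatorDefinition(
            indicator_id=indicator_id,
            measure_code="",
            direction_of_effect=int(entry),
        )

    @staticmethod
    def _observations(X: pd.DataFrame, indicator_id: str) -> list[Observation]:
        sub = X[X["indicator_id"] == indicator_id]
        obs = []
        for row in sub.itertuples(index=False):
            t1 = SUPPRESSED if pd.isna(row.t1) else float(row.t1)
            t2 = SUPPRESSED if pd.isna(row.t2) else float(row.t2)
            obs.append(
                Observation(
                    indicator_id=indicator_id,
                    jurisdiction=str(row.jurisdiction),
                    value_t1=t1,
                    value_t2=t2,
                )
            )
        return obs

    # -- estimator API ----------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "ImprovementScorer":
        """Learn the per-indicator LAD from ``X``."""
        X = self._validate(X)
        Thresholds(tau=self.tau, q=self.q)  # validate parameters early
        lads: dict[str, MaybeMarker] = {}
        for indicator_id in X["indicator_id"].unique():
            obs = self._observations(X, indicator_id)
            lads[indicator_id] = lad(
                [
                    delta(o.value_t1, o.value_t2)
                    for o in obs
                    if o.value_t1 is not SUPPRESSED and o.value_t2 is not SUPPRESSED
                ]
            )
        self.lad_ = pd.Series(
            {k: (np.nan if v is UNDEFINED else v) for k, v in lads.items()},
            dtype=float,
        )
        self.indicator_ids_ = np.asarray(list(lads), dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Score each row of ``X`` against the fitted per-indicator LADs."""
        check_is_fitted(self, "lad_")
        X = self._validate(X)
        thresholds = Thresholds(tau=self.tau, q=self.q)
        records: list[ScoreRecord] = []
        for indicator_id in X["indicator_id"].unique():
            if indicator_id not in self.lad_.index:
                raise ValueError(f"indicator {indicator_id!r} was not seen in fit")
            lv = self.lad_[indicator_id]
            records.extend(
                score_indicator(
                    self._observations(X, indicator_id),
                    self._definition(X, indicator_id),
                    thresholds=thresholds,
                    zero_baseline_awards_c1=self.zero_baseline_awards_c1,
                    lad_value=UNDEFINED if np.isnan(lv) else float(lv),
                )
            )
        return scores_to_frame(records)

    def score_records(self, X: pd.DataFrame) -> list[ScoreRecord]:
        """Like :meth:`fit_transform` but returning :class:`ScoreRecord` objects."""
        self.fit(X)
        thresholds = Thresholds(tau=self.tau, q=self.q)
        records: list[ScoreRecord] = []
        for indicator_id in X["indicator_id"].unique():
            lv = self.lad_[indicator_id]
            records.extend(
                score_indicator(
                    self._observations(X, indicator_id),
                    self._definition(X, indicator_id),
                    thresholds=thresholds,
                    zero_baseline_awards_c1=self.zero_baseline_awards_c1,
                    lad_value=UNDEFINED if np.isnan(lv) else float(lv),
                )
            )
        return records
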