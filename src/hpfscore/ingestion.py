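"""Reading long-format two-timepoint indicator tables.

Input dialect: UTF-8 CSV with header columns ``indicator_id, jurisdiction,
timepoint, category, value`` (``category`` optional).  ``timepoint`` is
``T1`` (earlier report) or ``T2`` (later report); ``value`` is a non-negative
decimal literal or the suppression token (default ``"n.p."``).  Anything else
is a hard parse error listing the offending rows — never a silent coercion.

The pipeline here is: :func:`parse_table` → per-indicator category reduction
(:func:`select_category`, :func:`ordinal_weighted_value`) inside
:func:`build_observations` → :func:`eligibility_filter`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .framework import (
    DEFAULT_JURISDICTIONS,
    SUPPRESSED,
    IndicatorDefinition,
    Observation,
    is_merged_jurisdiction,
)

__all__ = [
    "RawRecord",
    "IngestionError",
    "NATIONAL_LABELS",
    "parse_table",
    "write_table",
    "select_category",
    "ordinal_weighted_value",
    "build_observations",
    "eligibility_filter",
    "observations_to_frame",
]

logger = logging.getLogger(__name__)

#: Labels accepted as whole-of-country rows (scored, but never allocated to a
#: state/territory panel).
NATIONAL_LABELS = frozenset({"National", "Australia"})

REQUIRED_COLUMNS = ("indicator_id", "jurisdiction", "timepoint", "value")


class IngestionError(ValueError):
    """Raised for malformed input tables or category-selection failures."""


@dataclass(frozen=True)
class RawRecord:
    """One parsed table cell: a (indicator, jurisdiction, timepoint) value."""

    indicator_id: str
    jurisdiction: str
    timepoint: str  # "T1" or "T2"
    category: Optional[str]
    value: Union[float, object]  # float or SUPPRESSED


def parse_table(
    path: Union[str, Path], suppression_token: str = "n.p."
) -> list[RawRecord]:
    """Parse a long-format indicator CSV into :class:`RawRecord` rows.

    Every ``value`` cell is classified as numeric or SUPPRESSED; unknown
    tokens (``"—"``, ``"<5"``, ...) raise :class:`IngestionError` naming the
    offending row numbers (2-based, counting the header as row 1).
    """
    frame = pd.read_csv(
        Path(path), dtype=str, keep_default_na=False, skipinitialspace=True
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise IngestionError(f"{path}: missing required column(s) {missing}")

    records: list[RawRecord] = []
    problems: list[str] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        timepoint = getattr(row, "timepoint").strip()
        if timepoint not in ("T1", "T2"):
            problems.append(f"row {idx}: timepoint {timepoint!r} not in {{T1, T2}}")
            continue
        token = getattr(row, "value").strip()
        if token == suppression_token:
            value: Union[float, object] = SUPPRESSED
        else:
            try:
                value = float(token)
            except ValueError:
                problems.append(f"row {idx}: unparseable value {token!r}")
                continue
            if not value >= 0 or value != value or value == float("inf"):
                problems.append(f"row {idx}: value {token!r} is not a finite "
                                "non-negative number")
                continue
        category = getattr(row, "category", "").strip() if "category" in frame.columns else ""
        records.append(
            RawRecord(
                indicator_id=getattr(row, "indicator_id").strip(),
                jurisdiction=getattr(row, "jurisdiction").strip(),
                timepoint=timepoint,
                category=category or None,
                value=value,
            )
        )
    if problems:
        raise IngestionError(
            f"{path}: {len(problems)} malformed cell(s):\n  " + "\n  ".join(problems)
        )
    return records


def write_table(
    records: Iterable[RawRecord],
    path: Union[str, Path],
    suppression_token: str = "n.p.",
) -> None:
    """Serialise records back to the input CSV dialect (parse round-trips)."""
    rows = [
        {
            "indicator_id": r.indicator_id,
            "jurisdiction": r.jurisdiction,
            "timepoint": r.timepoint,
            "category": r.category or "",
            "value": suppression_token if r.value is SUPPRESSED else repr(float(r.value)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["indicator_id", "jurisdiction", "timepoint",
                                "category", "value"]).to_csv(path, index=False)


def select_category(
    records: Sequence[RawRecord], defn: IndicatorDefinition
) -> list[RawRecord]:
    """Keep only the scoreable category rows of a categorical indicator.

    Binary indicators keep the subjectively favourable category (e.g. for
    prostate screening published as tested / not tested, only "tested" is
    scored); nested indicators keep the broader category (e.g. "any
    mammogram" rather than its subset "regular mammograms").  Values are
    never altered, only row membership.
    """
    if defn.measurement_kind == "binary_categorical":
        wanted = defn.favourable_category
    elif defn.measurement_kind == "nested_categorical":
        wanted = defn.broader_category
    else:
        raise IngestionError(
            f"{defn.indicator_id}: select_category applies only to binary/nested "
            f"categorical indicators, not {defn.measurement_kind!r}"
        )
    kept = [r for r in records if r.category == wanted]
    if records and not kept:
        raise IngestionError(
            f"{defn.indicator_id}: category {wanted!r} absent from data "
            f"(saw {sorted({r.category for r in records})})"
        )
    return kept


def ordinal_weighted_value(
    category_rates: Mapping[str, float],
    weights: Mapping[str, float],
    normalise: bool = True,
) -> float:
    """Collapse ordinal category rates to a single positively geared value.

    With ``normalise=True`` (the default) returns the rate-mass-weighted mean
    Σ rate·weight / Σ rate, bounded by [min weight, max weight]; with
    ``normalise=False`` returns the raw weighted sum Σ rate·weight.
    """
    if not category_rates:
        raise IngestionError("empty category rate map")
    unknown = set(category_rates) - set(weights)
    if unknown:
        raise IngestionError(f"categories without weights: {sorted(unknown)}")
    for cat, rate in category_rates.items():
        if rate < 0:
            raise IngestionError(f"negative rate for category {cat!r}: {rate}")
    total = float(sum(category_rates.values()))
    weighted = float(
        sum(rate * weights[cat] for cat, rate in category_rates.items())
    )
    if not normalise:
        return weighted
    if total <= 0:
        raise IngestionError("normalised weighting needs at least one positive rate")
    return weighted / total


def _check_jurisdiction(label: str, jurisdictions: Sequence[str]) -> None:
    if label in jurisdictions or label in NATIONAL_LABELS:
        return
    if is_merged_jurisdiction(label):
        parts = label.split("+")
        if all(p in jurisdictions for p in parts):
            return
        raise IngestionError(
            f"merged jurisdiction {label!r} has unknown component(s)"
        )
    raise IngestionError(
        f"unknown jurisdiction {label!r}; expected one of {list(jurisdictions)}, "
        "a merged label such as 'Vic+Tas', or a national label"
    )


def build_observations(
    records: Sequence[RawRecord],
    registry: Mapping[str, IndicatorDefinition],
    jurisdictions: Sequence[str] = DEFAULT_JURISDICTIONS,
    normalise_ordinal: bool = True,
) -> list[Observation]:
    """Reduce raw rows to one two-timepoint :class:`Observation` per
    (indicator, jurisdiction), applying the category rules of each
    indicator's registered measurement kind.

    A timepoint with no rows at all yields ``None`` on that side (the
    eligibility filter will drop it); an ordinal indicator with any
    suppressed category rate yields SUPPRESSED for that timepoint.
    Categories with missing rates inside an ordinal indicator are an error —
    no imputation is attempted.
    """
    by_indicator: dict[str, list[RawRecord]] = {}
    for r in records:
        _check_jurisdiction(r.jurisdiction, jurisdictions)
        by_indicator.setdefault(r.indicator_id, []).append(r)

    observations: list[Observation] = []
    for indicator_id, rows in by_indicator.items():
        if indicator_id not in registry:
            raise IngestionError(f"indicator {indicator_id!r} not in registry")
        defn = registry[indicator_id]
        if defn.measurement_kind in ("binary_categorical", "nested_categorical"):
            rows = select_category(rows, defn)

        cells: dict[tuple[str, str], list[RawRecord]] = {}
        for r in rows:
            cells.setdefault((r.jurisdiction, r.timepoint), []).append(r)

        values: dict[tuple[str, str], object] = {}
        for (juris, tp), cell_rows in cells.items():
            if defn.measurement_kind == "ordinal_categorical":
                values[(juris, tp)] = _ordinal_cell(
                    cell_rows, defn, normalise_ordinal
                )
            else:
                if len(cell_rows) > 1:
                    raise IngestionError(
                        f"{indicator_id}/{juris}/{tp}: {len(cell_rows)} rows where "
                        "one was expected"
                    )
                values[(juris, tp)] = cell_rows[0].value

        for juris in sorted({j for j, _ in values}):
            observations.append(
                Observation(
                    indicator_id=indicator_id,
                    jurisdiction=juris,
                    value_t1=values.get((juris, "T1")),
                    value_t2=values.get((juris, "T2")),
                )
            )
    return observations


def _ordinal_cell(
    cell_rows: Sequence[RawRecord],
    defn: IndicatorDefinition,
    normalise: bool,
) -> object:
    assert defn.category_weights is not None
    rates: dict[str, float] = {}
    for r in cell_rows:
        if r.category is None:
            raise IngestionError(
                f"{defn.indicator_id}: ordinal indicator row without a category"
            )
        if r.category in rates:
            raise IngestionError(
                f"{defn.indicator_id}: duplicate category {r.category!r}"
            )
        rates[r.category] = r.value  # may be SUPPRESSED, checked below
    expected = set(defn.category_weights)
    if set(rates) != expected:
        raise IngestionError(
            f"{defn.indicator_id}: ordinal categories {sorted(rates)} do not "
            f"match registered weights {sorted(expected)} (no imputation)"
        )
    if any(v is SUPPRESSED for v in rates.values()):
        # one unpublished category makes the weighted value uncomputable
        return SUPPRESSED
    return ordinal_weighted_value(rates, defn.category_weights, normalise=normalise)


def observations_to_frame(observations: Sequence[Observation]) -> pd.DataFrame:
    """Tabulate complete observations for the scorer: NaN encodes "n.p.".

    Intended for use after :func:`eligibility_filter`, when every remaining
    observation has both sides present (numeric or suppressed).
    """
    rows = []
    for o in observations:
        if o.value_t1 is None or o.value_t2 is None:
            raise IngestionError(
                f"{o.indicator_id}/{o.jurisdiction}: incomplete observation; "
                "apply eligibility_filter first"
            )
        rows.append(
            {
                "indicator_id": o.indicator_id,
                "jurisdiction": o.jurisdiction,
                "t1": np.nan if o.value_t1 is SUPPRESSED else o.value_t1,
                "t2": np.nan if o.value_t2 is SUPPRESSED else o.value_t2,
            }
        )
    return pd.DataFrame(rows, columns=["indicator_id", "jurisdiction", "t1", "t2"])


def eligibility_filter(observations: Sequence[Observation]) -> list[Observation]:
    """Keep indicators available in both reports; drop incomplete pairs.

    An indicator is eligible when at least one jurisdiction has a row in
    BOTH timepoints; a suppressed ("n.p.") value counts as present since its
    change direction is inferable, whereas a fully absent row does not.
    Within eligible indicators, (indicator, jurisdiction) pairs missing one
    side are also dropped.  An empty result is permitted and logged.
    """
    by_indicator: dict[str, list[Observation]] = {}
    for obs in observations:
        by_indicator.setdefault(obs.indicator_id, []).append(obs)

    kept: list[Observation] = []
    for indicator_id, obs_list in by_indicator.items():
        complete = [
            o
            for o in obs_list
            if o.value_t1 is not None and o.value_t2 is not None
        ]
        if not complete:
            logger.info(
                "indicator %s dropped: not available in both reports", indicator_id
            )
            continue
        n_dropped = len(obs_list) - len(complete)
        if n_dropped:
            logger.info(
                "indicator %s: %d jurisdiction(s) missing one timepoint dropped",
                indicator_id,
                n_dropped,
            )
        kept.extend(complete)
    if not kept:
        logger.warning("eligibility filter retained no observations")
    return kept
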