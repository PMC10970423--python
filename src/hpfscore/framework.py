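"""Domain model for hierarchical indicator frameworks.

The Health Performance Framework (HPF) organises 68 *measures* into 13
*groups* within 3 *tiers* (health status and outcomes; determinants of
health; health system performance).  Published data tables provide one or
more *indicators* per measure; each indicator carries a direction of effect
(whether a numeric increase counts as improvement) and a measurement kind
that controls how raw category rows are reduced to a single value.

This module houses the shared types: :class:`FrameworkSpec` (the hierarchy),
:class:`IndicatorDefinition` (the registry entry), :class:`Observation`
(a two-timepoint value pair), :class:`Thresholds` (the confidence-indicator
thresholds), :class:`ScoreRecord` and :class:`GroupSummary`, plus loaders
for the YAML configuration formats and the bundled default framework.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

__all__ = [
    "SUPPRESSED",
    "UNDEFINED",
    "DEFAULT_JURISDICTIONS",
    "MEASUREMENT_KINDS",
    "Measure",
    "Group",
    "Tier",
    "FrameworkSpec",
    "IndicatorDefinition",
    "Observation",
    "Thresholds",
    "ScoreRecord",
    "GroupSummary",
    "FrameworkError",
    "load_framework",
    "save_framework",
    "load_registry",
    "save_registry",
    "validate_indicator",
    "is_merged_jurisdiction",
    "is_suppressed",
    "is_undefined",
]


class _Marker:
    """Singleton marker; survives copy and compares by identity."""

    __slots__ = ("_name",)
    _instances: dict[str, "_Marker"] = {}

    def __new__(cls, name: str) -> "_Marker":
        if name not in cls._instances:
            inst = super().__new__(cls)
            inst._name = name
            cls._instances[name] = inst
        return cls._instances[name]

    def __repr__(self) -> str:
        return self._name

    def __reduce__(self):
        return (_Marker, (self._name,))

    def __bool__(self) -> bool:
        return False


#: Marker for values published as "n.p." (not published / suppressed).
SUPPRESSED = _Marker("SUPPRESSED")
#: Marker for quantities that cannot be computed (e.g. %change on a zero base).
UNDEFINED = _Marker("UNDEFINED")

#: Australian states and territories, in conventional order.
DEFAULT_JURISDICTIONS = ("NSW", "Vic", "Qld", "WA", "SA", "Tas", "ACT", "NT")

MEASUREMENT_KINDS = frozenset(
    {"plain_rate", "ordinal_categorical", "binary_categorical", "nested_categorical"}
)


def is_suppressed(value: object) -> bool:
    return value is SUPPRESSED


def is_undefined(value: object) -> bool:
    return value is UNDEFINED


def is_merged_jurisdiction(jurisdiction: str) -> bool:
    """True for merged labels such as ``"Vic+Tas"`` or ``"NSW+ACT"``.

    Some source collections aggregate smaller jurisdictions into neighbours;
    those records are scored normally but cannot be allocated to a single
    state/territory panel.
    """
    return "+" in jurisdiction


class FrameworkError(ValueError):
    """Raised when a framework or registry configuration is invalid."""


# ---------------------------------------------------------------------------
# Hierarchy types


@dataclass(frozen=True)
class Measure:
    """A framework measure, e.g. code ``"1.17"``, label ``"Perceived health status"``."""

    code: str
    label: str = ""


@dataclass(frozen=True)
class Group:
    name: str
    measures: tuple[Measure, ...]


@dataclass(frozen=True)
class Tier:
    number: int
    name: str
    groups: tuple[Group, ...]

    @property
    def measures(self) -> tuple[Measure, ...]:
        return tuple(m for g in self.groups for m in g.measures)


@dataclass(frozen=True)
class FrameworkSpec:
    """Validated tier → group → measure hierarchy.

    Invariants enforced on construction: tier numbers are exactly {1, 2, 3},
    group names are unique within a tier, and measure codes are unique across
    the whole framework (a measure relevant to several tiers must be
    allocated to exactly one).
    """

    tiers: tuple[Tier, ...]

    def __post_init__(self) -> None:
        numbers = [t.number for t in self.tiers]
        for n in numbers:
            if n not in (1, 2, 3):
                raise FrameworkError(f"unknown tier number {n!r}; expected 1, 2 or 3")
        if sorted(numbers) != [1, 2, 3]:
            raise FrameworkError(
                f"tier numbers must be exactly {{1, 2, 3}}, got {sorted(numbers)}"
            )
        seen: dict[str, str] = {}
        for tier in self.tiers:
            for group in tier.groups:
                for measure in group.measures:
                    if measure.code in seen:
                        raise FrameworkError(
                            f"duplicate measure code {measure.code!r}: appears in "
                            f"group {seen[measure.code]!r} and group {group.name!r}"
                        )
                    seen[measure.code] = group.name

    # -- lookups ----------------------------------------------------------

    def tier(self, number: int) -> Tier:
        for t in self.tiers:
            if t.number == number:
                return t
        raise KeyError(number)

    @property
    def groups(self) -> tuple[Group, ...]:
        return tuple(g for t in self.tiers for g in t.groups)

    @property
    def measure_codes(self) -> tuple[str, ...]:
        return tuple(m.code for t in self.tiers for m in t.measures)

    def locate(self, measure_code: str) -> tuple[Tier, Group]:
        """Return the (tier, group) holding *measure_code*."""
        for tier in self.tiers:
            for group in tier.groups:
                if any(m.code == measure_code for m in group.measures):
                    return tier, group
        raise KeyError(measure_code)

    def __contains__(self, measure_code: str) -> bool:
        return measure_code in self.measure_codes

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tiers": [
                {
                    "number": t.number,
                    "name": t.name,
                    "groups": [
                        {
                            "name": g.name,
                            "measures": [
                                f"{m.code} {m.label}".strip() for m in g.measures
                            ],
                        }
                        for g in t.groups
                    ],
                }
                for t in self.tiers
            ]
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FrameworkSpec":
        try:
            raw_tiers = payload["tiers"]
        except (KeyError, TypeError):
            raise FrameworkError("framework config must contain a 'tiers' list")
        tiers = []
        for raw_tier in raw_tiers:
            groups = []
            for raw_group in raw_tier.get("groups", []):
                measures = tuple(
                    _parse_measure(entry) for entry in raw_group.get("measures", [])
                )
                groups.append(Group(name=str(raw_group["name"]), measures=measures))
            tiers.append(
                Tier(
                    number=int(raw_tier["number"]),
                    name=str(raw_tier.get("name", "")),
                    groups=tuple(groups),
                )
            )
        return cls(tiers=tuple(tiers))


def _parse_measure(entry: Union[str, Mapping]) -> Measure:
    if isinstance(entry, Mapping):
        return Measure(code=str(entry["code"]), label=str(entry.get("label", "")))
    code, _, label = str(entry).partition(" ")
    return Measure(code=code, label=label.strip())


def load_framework(path: Optional[Union[str, Path]] = None) -> FrameworkSpec:
    """Load a framework hierarchy from YAML.

    With ``path=None`` the bundled default structure (3 tiers, 15 groups,
    68 measures) is returned.
    """
    if path is None:
        text = (
            resources.files("hpfscore.data")
            .joinpath("framework_default.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return FrameworkSpec.from_dict(yaml.safe_load(text))


def save_framework(spec: FrameworkSpec, path: Union[str, Path]) -> None:
    Path(path).write_text(
        yaml.safe_dump(spec.to_dict(), sort_keys=False, allow_unicode=True),
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Indicator registry


@dataclass(frozen=True)
class IndicatorDefinition:
    """Registry entry tying a published indicator to the framework.

    Parameters
    ----------
    direction_of_effect
        +1 when a numeric increase counts as improvement (screening uptake,
        breastfeeding, physical activity, ...), −1 when a decrease does
        (hospitalisation, mortality, smoking, waiting times, ...).
    measurement_kind
        ``plain_rate`` — the value is used as published; ``ordinal_categorical``
        — category rates are collapsed to a weighted mean using
        ``category_weights``; ``binary_categorical`` — only the
        ``favourable_category`` rows are scored; ``nested_categorical`` — only
        the ``broader_category`` rows are scored.
    """

    indicator_id: str
    measure_code: str
    direction_of_effect: int
    measurement_kind: str = "plain_rate"
    label: str = ""
    category_weights: Optional[Mapping[str, float]] = None
    favourable_category: Optional[str] = None
    broader_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction_of_effect not in (1, -1):
            raise FrameworkError(
                f"{self.indicator_id}: direction_of_effect must be +1 or -1, "
                f"got {self.direction_of_effect!r}"
            )
        if self.measurement_kind not in MEASUREMENT_KINDS:
            raise FrameworkError(
                f"{self.indicator_id}: unknown measurement_kind "
                f"{self.measurement_kind!r}"
            )
        if self.measurement_kind == "ordinal_categorical":
            w = self.category_weights
            if not w:
                raise FrameworkError(
                    f"{self.indicator_id}: ordinal_categorical requires "
                    "category_weights"
                )
            if len(w) < 2 or len(set(w.values())) != len(w):
                raise FrameworkError(
                    f"{self.indicator_id}: category_weights needs >=2 categories "
                    "with strictly distinct weights"
                )
            if any(v <= 0 for v in w.values()):
                raise FrameworkError(
                    f"{self.indicator_id}: category weights must be positive"
                )
        if self.measurement_kind == "binary_categorical" and not self.favourable_category:
            raise FrameworkError(
                f"{self.indicator_id}: binary_categorical requires "
                "favourable_category"
            )
        if self.measurement_kind == "nested_categorical" and not self.broader_category:
            raise FrameworkError(
                f"{self.indicator_id}: nested_categorical requires broader_category"
            )


def validate_indicator(
    defn: IndicatorDefinition, spec: FrameworkSpec
) -> IndicatorDefinition:
    """Check that *defn* resolves into *spec*; return it unchanged or raise."""
    if defn.measure_code not in spec:
        raise FrameworkError(
            f"{defn.indicator_id}: measure code {defn.measure_code!r} is not in "
            "the framework"
        )
    return defn


def load_registry(path: Union[str, Path]) -> dict[str, IndicatorDefinition]:
    """Load an indicator registry YAML into an id → definition mapping."""
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return registry_from_dict(payload)


def registry_from_dict(payload: Mapping) -> dict[str, IndicatorDefinition]:
    try:
        entries = payload["indicators"]
    except (KeyError, TypeError):
        raise FrameworkError("registry config must contain an 'indicators' list")
    registry: dict[str, IndicatorDefinition] = {}
    for entry in entries:
        defn = IndicatorDefinition(
            indicator_id=str(entry["indicator_id"]),
            measure_code=str(entry["measure_code"]),
            direction_of_effect=int(entry["direction_of_effect"]),
            measurement_kind=str(entry.get("measurement_kind", "plain_rate")),
            label=str(entry.get("label", "")),
            category_weights=entry.get("category_weights"),
            favourable_category=entry.get("favourable_category"),
            broader_category=entry.get("broader_category"),
        )
        if defn.indicator_id in registry:
            raise FrameworkError(f"duplicate indicator_id {defn.indicator_id!r}")
        registry[defn.indicator_id] = defn
    return registry


def save_registry(
    registry: Mapping[str, IndicatorDefinition], path: Union[str, Path]
) -> None:
    entries = []
    for defn in registry.values():
        entry = {
            "indicator_id": defn.indicator_id,
            "measure_code": defn.measure_code,
            "label": defn.label,
            "direction_of_effect": defn.direction_of_effect,
            "measurement_kind": defn.measurement_kind,
        }
        if defn.category_weights is not None:
            entry["category_weights"] = dict(defn.category_weights)
        if defn.favourable_category is not None:
            entry["favourable_category"] = defn.favourable_category
        if defn.broader_category is not None:
            entry["broader_category"] = defn.broader_category
        entries.append(entry)
    Path(path).write_text(
        yaml.safe_dump({"indicators": entries}, sort_keys=False, allow_unicode=True),
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Observations, thresholds, results

Value = Union[float, _Marker]  # a published number, or SUPPRESSED


@dataclass(frozen=True)
class Observation:
    """Two-timepoint value pair for one (indicator, jurisdiction).

    Each side is a finite non-negative number, the SUPPRESSED marker (the
    report printed "n.p."), or None when the report carried no row at all.
    SUPPRESSED counts as *present* for eligibility purposes — its direction
    of change is inferable — whereas None does not.
    """

    indicator_id: str
    jurisdiction: str
    value_t1: Optional[Value]
    value_t2: Optional[Value]

    def __post_init__(self) -> None:
        for name in ("value_t1", "value_t2"):
            v = getattr(self, name)
            if v is SUPPRESSED or v is None:
                continue
            v = float(v)
            if not (v >= 0) or v != v or v == float("inf"):
                raise ValueError(
                    f"{self.indicator_id}/{self.jurisdiction}: {name} must be a "
                    f"finite non-negative number or SUPPRESSED, got {v!r}"
                )
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class Thresholds:
    """Confidence-indicator thresholds.

    ``tau`` is the relative-change threshold in percent (C1 is earned when
    |%Δ| ≥ τ); ``q`` is the fraction of the largest absolute difference
    (C2 is earned when |Δ| ≥ q·LAD).  Defaults (2%, 0.10) deliberately favour
    sensitivity to change.
    """

    tau: float = 2.0
    q: float = 0.10

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau!r}")
        if not 0 < self.q <= 1:
            raise ValueError(f"q must be in (0, 1], got {self.q!r}")


@dataclass(frozen=True)
class ScoreRecord:
    """All per-(indicator, jurisdiction) scoring quantities.

    ``improvement_score = direction × U × (1 + C1 + C2)`` with UNDEFINED
    confidence indicators contributing 0, hence the score is an integer in
    [−3, 3]; its sign encodes direction relative to the direction of effect
    and its magnitude encodes confidence.
    """

    indicator_id: str
    jurisdiction: str
    measure_code: str
    value_t1: Value
    value_t2: Value
    delta: Union[float, _Marker]
    pct_change: Union[float, _Marker]
    lad: Union[float, _Marker]
    unit_change: int
    c1: Union[int, _Marker]
    c2: Union[int, _Marker]
    improvement_score: int
    confidence_precluded: bool
    allocatable: bool = True

    def __post_init__(self) -> None:
        if self.unit_change not in (-1, 0, 1):
            raise ValueError(f"unit_change must be in {{-1,0,1}}: {self.unit_change}")
        if self.improvement_score not in range(-3, 4):
            raise ValueError(
                f"improvement_score out of [-3, 3]: {self.improvement_score}"
            )
        if self.unit_change == 0 and self.improvement_score != 0:
            raise ValueError("unit_change == 0 requires improvement_score == 0")
        if self.confidence_precluded and abs(self.improvement_score) > 1:
            raise ValueError("confidence precluded requires |score| <= 1")
        if (
            self.c1 is UNDEFINED
            and not self.confidence_precluded
            and abs(self.improvement_score) > 2
        ):
            raise ValueError("undefined C1 (zero baseline) requires |score| <= 2")


@dataclass(frozen=True)
class GroupSummary:
    """Aggregated improvement for one (jurisdiction, tier[, group]) cell.

    ``sem`` is the standard error of the mean score (sample sd, n−1
    denominator); the 95% CI is mean ± 1.96·SEM and is descriptive only,
    never a significance test.  With a single viable indicator the SEM and
    CI are UNDEFINED.
    """

    jurisdiction: str
    tier_number: int
    group_name: Optional[str]
    n_indicators: int
    mean_score: float
    sem: Union[float, _Marker]
    ci_low: Union[float, _Marker]
    ci_high: Union[float, _Marker]

    def __post_init__(self) -> None:
        if self.n_indicators < 1:
            raise ValueError("n_indicators must be >= 1")
        if not -3.0 <= self.mean_score <= 3.0:
            raise ValueError(f"mean_score out of [-3, 3]: {self.mean_score}")
        if self.sem is not UNDEFINED:
            if self.sem < 0:
                raise ValueError("sem must be non-negative")
            if not (self.ci_low <= self.mean_score <= self.ci_high):
                raise ValueError("CI must bracket the mean")
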