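"""Synthetic framework-shaped fixtures with known ground truth.

Emulates the statistical shape of published two-timepoint indicator tables:
~289 indicators allocated across the bundled 3-tier / 13-group hierarchy,
eight jurisdictions, values rounded to one decimal place, sporadic "n.p."
suppression, occasional merged-jurisdiction reporting (Vic+Tas, NSW+ACT),
zero baselines to exercise the division-by-zero path, and a mix of plain
rates, ordinal category tables and binary category pairs.

Each indicator is assigned a latent truth — whether it genuinely improved
between the reports and by how much — recorded per jurisdiction *before*
rounding and suppression, so recovery of the change direction by the scoring
pipeline can be measured exactly.  No attempt is made to match any real
collection's empirical marginal distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .framework import (
    DEFAULT_JURISDICTIONS,
    FrameworkSpec,
    IndicatorDefinition,
    load_framework,
    save_framework,
    save_registry,
)

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "sign_recovery_rate"]

logger = logging.getLogger(__name__)

#: Merged labels used when a synthetic indicator reports aggregated
#: small jurisdictions (as some national collections do).
MERGED_PANEL = ("NSW+ACT", "Vic+Tas", "Qld", "WA", "SA", "NT")

ORDINAL_WEIGHTS = {"poor": 1.0, "fair": 2.0, "good": 3.0, "very_good": 4.0,
                   "excellent": 5.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic generator.

    ``effect_size_scale`` is the latent |Δ| of a truly changing indicator as
    a fraction of its baseline; ``noise_scale`` is the standard deviation of
    the per-jurisdiction perturbation on the same scale.  ``rounding=None``
    disables the 1-dp publication rounding (useful for noiseless recovery
    checks).
    """

    seed: int = 0
    n_indicators: int = 289
    jurisdictions: Sequence[str] = DEFAULT_JURISDICTIONS
    true_improvement_prob: float = 0.6
    effect_size_scale: float = 0.08
    noise_scale: float = 0.02
    suppression_prob: float = 0.03
    merged_jurisdiction_prob: float = 0.05
    ordinal_frac: float = 0.10
    binary_frac: float = 0.05
    zero_baseline_frac: float = 0.02
    baseline_range: tuple[float, float] = (5.0, 95.0)
    rounding: Optional[int] = 1

    def __post_init__(self) -> None:
        for name in (
            "true_improvement_prob", "suppression_prob",
            "merged_jurisdiction_prob", "ordinal_frac", "binary_frac",
            "zero_baseline_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.n_indicators < 1:
            raise ValueError("n_indicators must be >= 1")
        if self.effect_size_scale < 0 or self.noise_scale < 0:
            raise ValueError("scales must be non-negative")
        lo, hi = self.baseline_range
        if not 0 <= lo < hi:
            raise ValueError("baseline_range must satisfy 0 <= lo < hi")


@dataclass
class SyntheticDataset:
    """A generated fixture set: hierarchy, registry, long table, truth."""

    framework: FrameworkSpec
    registry: dict[str, IndicatorDefinition]
    observations: pd.DataFrame  # ingestion CSV dialect, values as strings
    ground_truth: pd.DataFrame

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "framework": out_dir / "framework.yaml",
            "registry": out_dir / "registry.yaml",
            "observations": out_dir / "observations.csv",
            "ground_truth": out_dir / "ground_truth.csv",
        }
        save_framework(self.framework, paths["framework"])
        save_registry(self.registry, paths["registry"])
        self.observations.to_csv(paths["observations"], index=False)
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        return paths


def _fmt(value: float, rounding: Optional[int]) -> str:
    if rounding is None:
        return repr(float(value))
    return f"{value:.{rounding}f}"


def generate(config: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Generate a fully self-consistent synthetic fixture set.

    Deterministic for a fixed config (including the seed).  The observations
    table always passes ingestion validation; the ground-truth table records
    each indicator's direction of effect and each jurisdiction's latent Δ on
    the scored scale, before rounding and suppression were applied.
    """
    rng = np.random.default_rng(config.seed)
    framework = load_framework()
    codes = framework.measure_codes

    registry: dict[str, IndicatorDefinition] = {}
    obs_rows: list[dict] = []
    truth_rows: list[dict] = []

    for k in range(config.n_indicators):
        indicator_id = f"syn_{k:04d}"
        measure_code = codes[k % len(codes)]
        direction = int(rng.choice([1, -1]))
        improving = bool(rng.random() < config.true_improvement_prob)
        # latent change runs with the direction of effect iff truly improving
        change_sign = direction if improving else -direction

        r = rng.random()
        if r < config.ordinal_frac:
            kind = "ordinal_categorical"
            direction = 1  # ordinal values are positively geared by weighting
            change_sign = 1 if improving else -1
        elif r < config.ordinal_frac + config.binary_frac:
            kind = "binary_categorical"
        else:
            kind = "plain_rate"

        if rng.random() < config.merged_jurisdiction_prob:
            panel = MERGED_PANEL
        else:
            panel = tuple(config.jurisdictions)

        defn = IndicatorDefinition(
            indicator_id=indicator_id,
            measure_code=measure_code,
            direction_of_effect=direction,
            measurement_kind=kind,
            label=f"Synthetic indicator {k}",
            category_weights=ORDINAL_WEIGHTS if kind == "ordinal_categorical" else None,
            favourable_category="favourable" if kind == "binary_categorical" else None,
        )
        registry[indicator_id] = defn

        if kind == "ordinal_categorical":
            _ordinal_indicator(
                rng, config, defn, panel, change_sign, obs_rows, truth_rows
            )
        else:
            _rate_indicator(
                rng, config, defn, panel, change_sign, kind, obs_rows, truth_rows
            )

    observations = pd.DataFrame(
        obs_rows,
        columns=["indicator_id", "jurisdiction", "timepoint", "category", "value"],
    )
    ground_truth = pd.DataFrame(
        truth_rows,
        columns=[
            "indicator_id", "jurisdiction", "direction_of_effect",
            "true_delta", "true_sign", "improving",
        ],
    )
    return SyntheticDataset(framework, registry, observations, ground_truth)


def _suppress(rng: np.random.Generator, config: GeneratorConfig) -> bool:
    return rng.random() < config.suppression_prob


def _rate_indicator(rng, config, defn, panel, change_sign, kind,
                    obs_rows, truth_rows) -> None:
    lo, hi = config.baseline_range
    base = rng.uniform(lo, hi)
    for juris in panel:
        if rng.random() < config.zero_baseline_frac:
            t1 = 0.0
            latent = base * config.effect_size_scale
            noise = rng.normal(0.0, config.noise_scale * max(base, 1.0)) \
                if config.noise_scale else 0.0
            t2 = max(0.0, latent + noise)
        else:
            t1 = base * (1.0 + rng.uniform(-0.15, 0.15))
            latent = change_sign * config.effect_size_scale * base
            noise = rng.normal(0.0, config.noise_scale * base) \
                if config.noise_scale else 0.0
            t2 = max(0.0, t1 + latent + noise)
        # truth records the latent (noise-free) change on the scored scale
        true_delta = latent
        truth_rows.append(
            {
                "indicator_id": defn.indicator_id,
                "jurisdiction": juris,
                "direction_of_effect": defn.direction_of_effect,
                "true_delta": true_delta,
                "true_sign": int(np.sign(true_delta)),
                "improving": change_sign == defn.direction_of_effect,
            }
        )
        for tp, value in (("T1", t1), ("T2", t2)):
            token = "n.p." if _suppress(rng, config) else _fmt(value, config.rounding)
            if kind == "binary_categorical":
                other = max(0.0, 100.0 - value)
                obs_rows.append(_row(defn, juris, tp, "favourable", token))
                obs_rows.append(
                    _row(defn, juris, tp, "unfavourable",
                         _fmt(other, config.rounding))
                )
            else:
                obs_rows.append(_row(defn, juris, tp, None, token))


def _ordinal_indicator(rng, config, defn, panel, change_sign,
                       obs_rows, truth_rows) -> None:
    weights = np.array(list(ORDINAL_WEIGHTS.values()))
    cats = list(ORDINAL_WEIGHTS)
    base_rates = rng.dirichlet(np.full(len(cats), 5.0)) * 100.0
    for juris in panel:
        t1_rates = base_rates.copy()
        if config.noise_scale:
            t1_rates = (1 - config.noise_scale) * t1_rates + \
                config.noise_scale * rng.dirichlet(np.ones(len(cats))) * 100.0
        # move probability mass between the extreme categories: towards the
        # top for a genuine improvement, towards the bottom otherwise
        shift = config.effect_size_scale * 50.0
        t2_clean = t1_rates.copy()
        if change_sign > 0:
            moved = min(shift, t2_clean[0])
            t2_clean[0] -= moved
            t2_clean[-1] += moved
        elif change_sign < 0:
            moved = min(shift, t2_clean[-1])
            t2_clean[-1] -= moved
            t2_clean[0] += moved
        t2_rates = t2_clean
        if config.noise_scale:
            t2_rates = (1 - config.noise_scale) * t2_clean + \
                config.noise_scale * rng.dirichlet(np.ones(len(cats))) * 100.0

        def wmean(rates: np.ndarray) -> float:
            return float((rates * weights).sum() / rates.sum())

        # latent change: the mass shift alone, before jurisdiction noise
        true_delta = wmean(t2_clean) - wmean(t1_rates)
        truth_rows.append(
            {
                "indicator_id": defn.indicator_id,
                "jurisdiction": juris,
                "direction_of_effect": defn.direction_of_effect,
                "true_delta": true_delta,
                "true_sign": int(np.sign(true_delta)),
                "improving": change_sign > 0,
            }
        )
        for tp, rates in (("T1", t1_rates), ("T2", t2_rates)):
            suppressed = _suppress(rng, config)
            for cat, rate in zip(cats, rates):
                token = "n.p." if suppressed else _fmt(rate, config.rounding)
                obs_rows.append(_row(defn, juris, tp, cat, token))


def _row(defn, juris, tp, category, token) -> dict:
    return {
        "indicator_id": defn.indicator_id,
        "jurisdiction": juris,
        "timepoint": tp,
        "category": category or "",
        "value": token,
    }


def sign_recovery_rate(
    scores: pd.DataFrame, ground_truth: pd.DataFrame
) -> float:
    """Fraction of scoreable cells whose score sign matches the latent truth.

    Joins the score table (``indicator_id, jurisdiction, score, flags``) with
    the ground-truth table on (indicator, jurisdiction); cells with a zero
    latent Δ or with suppression-precluded confidence are excluded from the
    denominator (their sign is not identifiable from the published values).
    """
    merged = scores.merge(
        ground_truth, on=["indicator_id", "jurisdiction"], how="inner",
        validate="one_to_one",
    )
    flags = merged["flags"].fillna("").astype(str)
    mask = (merged["true_sign"] != 0) & ~flags.str.contains("confidence_precluded")
    merged = merged[mask]
    if merged.empty:
        return float("nan")
    expected = np.sign(merged["direction_of_effect"] * merged["true_sign"])
    got = np.sign(merged["score"])
    return float((expected == got).mean())
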