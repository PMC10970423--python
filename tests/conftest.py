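from importlib import resources

import pandas as pd
import pytest

from hpfscore import IndicatorDefinition, Observation, load_registry

# Self-assessed health status, weighted mean of five ordinal response
# categories (excellent=5 ... poor=1), across the eight jurisdictions in
# the two consecutive reports.
SELF_ASSESSED_HEALTH = {
    "ACT": (63.7, 60.7),
    "NSW": (63.4, 65.7),
    "NT": (67.1, 69.1),
    "Qld": (63.7, 65.8),
    "SA": (63.3, 60.7),
    "Tas": (61.4, 63.3),
    "Vic": (62.7, 66.6),
    "WA": (63.9, 65.1),
}

EXPECTED_SCORES = {
    "ACT": -3, "NSW": 3, "NT": 3, "Qld": 3,
    "SA": -3, "Tas": 3, "Vic": 3, "WA": 2,
}


def bundled(name: str) -> str:
    return str(resources.files("hpfscore.data").joinpath(name))


@pytest.fixture
def health_defn() -> IndicatorDefinition:
    return IndicatorDefinition(
        indicator_id="self_assessed_health",
        measure_code="1.17",
        direction_of_effect=1,
        label="Self-assessed health weighted rating",
    )


@pytest.fixture
def health_observations(health_defn) -> list[Observation]:
    return [
        Observation(health_defn.indicator_id, juris, t1, t2)
        for juris, (t1, t2) in SELF_ASSESSED_HEALTH.items()
    ]


@pytest.fixture
def health_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"indicator_id": "self_assessed_health", "jurisdiction": j,
             "t1": t1, "t2": t2, "direction": 1}
            for j, (t1, t2) in SELF_ASSESSED_HEALTH.items()
        ]
    )


@pytest.fixture
def health_registry() -> dict:
    return load_registry(bundled("self_assessed_health_registry.yaml"))
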