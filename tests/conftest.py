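import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ciscreen import (
    IndicatorDefinition,
    IndicatorValueMatrix,
    ReferenceDistribution,
    default_component_specs,
    pilot_config,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def specs():
    return default_component_specs()


@pytest.fixture(scope="session")
def cfg():
    """The 16-indicator pilot-shaped configuration (5/4/2/2/3 per component)."""
    return pilot_config()


@pytest.fixture
def toy():
    """A hand-traceable 3-unit, 6-indicator problem.

    One indicator per component except public health effects (two, one of
    them missing for unit Z) and a beneficial income-style indicator o1.
    Expected scores are worked out by hand in test_scoring.
    """
    definitions = [
        IndicatorDefinition(id="e1", component="exposures"),
        IndicatorDefinition(id="h1", component="public_health_effects"),
        IndicatorDefinition(id="h2", component="public_health_effects"),
        IndicatorDefinition(id="v1", component="environmental_effects"),
        IndicatorDefinition(id="s1", component="sensitive_populations"),
        IndicatorDefinition(id="o1", component="socioeconomic_factors", higher_is_worse=False),
    ]
    references = {
        "e1": ReferenceDistribution.from_values("e1", range(1, 11)),
        "h1": ReferenceDistribution.from_values("h1", range(1, 6)),
        "h2": ReferenceDistribution.from_values("h2", [2, 4, 6, 8]),
        "v1": ReferenceDistribution.from_values("v1", range(1, 6)),
        "s1": ReferenceDistribution.from_values("s1", [1, 2, 3]),
        "o1": ReferenceDistribution.from_values("o1", [10, 20, 30, 40]),
    }
    matrix = IndicatorValueMatrix(
        unit_ids=["X", "Y", "Z"],
        indicator_ids=["e1", "h1", "h2", "v1", "s1", "o1"],
        values=np.array(
            [
                [10, 3, 8, 1, 2, 10],
                [1, 5, 2, 5, 1, 40],
                [5, np.nan, 6, 3, 3, 25],
            ],
            dtype=float,
        ),
    )
    return definitions, references, matrix
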