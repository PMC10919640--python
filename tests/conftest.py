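import pytest

from lifetables.cohort import Cohort, LifeHistory
from lifetables.synthetic import CohortConfig, StageDistributionSpec


@pytest.fixture
def simple_cohort() -> Cohort:
    """Three individuals at 26 degC; one dies as a larva."""
    return Cohort(
        temperature=26.0,
        stage_sequence=("egg", "larva", "pupa"),
        individuals=[
            LifeHistory("A", {"egg": 2, "larva": 3, "pupa": 4}),
            LifeHistory("B", {"egg": 2}, death_stage="larva"),
            LifeHistory("C", {"egg": 3, "larva": 5, "pupa": 4}),
        ],
    )


@pytest.fixture
def bimodal_config() -> CohortConfig:
    """Bimodal larval cohort emulating two developmental groups."""
    return CohortConfig(
        temperature=26.0,
        stages={
            "egg": StageDistributionSpec("normal", {"mean": 4.8, "sd": 1.1}, 0.95),
            "larva": StageDistributionSpec(
                "mixture",
                {"components": [(0.5, 21.0, 1.0), (0.5, 33.0, 1.0)]},
                0.9,
            ),
        },
        n_initial=400,
        seed=20260930,
    )
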