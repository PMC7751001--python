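import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lsomorph import AreaSeries, CanalPhantomSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: alternating canal/intercanal toy profile with unit intercanal area
ALTERNATING_11 = [2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2]
#: flat profile with a central expansion bump
BUMP_11 = [1, 1, 1, 1, 2, 4, 2, 1, 1, 1, 1]


@pytest.fixture
def toy_series():
    return AreaSeries(
        specimen_id="toy01",
        species_id="Toyus_exemplaris",
        areas=np.array(ALTERNATING_11, dtype=float),
        section_labels=tuple(
            "canal" if i % 2 == 0 else "intercanal" for i in range(11)
        ),
        source="phantom",
    )


@pytest.fixture
def default_spec():
    return CanalPhantomSpec(recess_depth=0.5, expansion_gain=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
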