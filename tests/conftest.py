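import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sulcnet
from sulcnet.simulate import CohortSpec, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

G = sulcnet.Group


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Reduced-scale cohort spec: 48 parcels, 40/30/20 subjects."""
    return CohortSpec(
        n_parcels=48,
        group_sizes={G.H_PLUS: 40, G.H_MINUS: 30, G.HC: 20},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    cohort, manifest = generate_cohort(small_spec)
    return cohort


@pytest.fixture(scope="session")
def small_residuals(small_cohort):
    from sulcnet.covnet import residualize

    return residualize(small_cohort.lgi, small_cohort.subjects)


@pytest.fixture()
def two_network_atlas():
    """Hand atlas: networks A={p1,p2}, B={p3,p4}."""
    table = pd.DataFrame(
        {
            "network": ["A", "A", "B", "B"],
            "hemisphere": ["L", "R", "L", "R"],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="parcel_id"),
    )
    return sulcnet.AtlasMap(table)
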