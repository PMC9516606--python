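import numpy as np
import pytest

from hypermorb import DiseaseCatalog, SyntheticConfig, generate_cohort

#: Worked example: 5 participants, 3 diseases. Profiles {H,O}, {H,O},
#: {H,O,D}, {H}, {D}. Hand-derived expectations (verified by enumeration):
#: edges {H,O} (support 3, W_E = 3/min(4,3) = 1.0) and {H,O,D}
#: (support 1, W_E = 1/min(4,3,2) = 0.5).
TOY_DISEASES = ("hypertension", "obesity", "diabetes")
TOY_PROFILES = [
    ("hypertension", "obesity"),
    ("hypertension", "obesity"),
    ("hypertension", "obesity", "diabetes"),
    ("hypertension",),
    ("diabetes",),
]


@pytest.fixture(scope="session")
def toy_catalog() -> DiseaseCatalog:
    return DiseaseCatalog(TOY_DISEASES)


@pytest.fixture(scope="session")
def toy_matrix(toy_catalog) -> np.ndarray:
    m = np.zeros((len(TOY_PROFILES), len(TOY_DISEASES)), dtype=np.int8)
    for i, profile in enumerate(TOY_PROFILES):
        for d in profile:
            m[i, toy_catalog.index(d)] = 1
    return m


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-participant default-condition cohort shared across tests."""
    return generate_cohort(SyntheticConfig(n_participants=400, seed=11))


def clean_config(**kwargs) -> SyntheticConfig:
    """Default-disease config with no missingness (for exact-count checks)."""
    kwargs.setdefault("missingness", {})
    return SyntheticConfig(**kwargs)
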