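import numpy as np
import pytest

from connkit import (
    ConnectivityMatrix,
    RegionAtlas,
    SyntheticCohortConfig,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_weighted_net(rng, n, density=0.6, modality="structural"):
    """Random symmetric nonnegative weighted network with zero diagonal."""
    w = rng.random((n, n))
    w[rng.random((n, n)) > density] = 0.0
    w = np.triu(w, 1)
    w = w + w.T
    if modality == "functional":
        w = np.clip(w, 0.0, 1.0)
    return ConnectivityMatrix(
        subject_id="rand", modality=modality, weights=w,
        labels=tuple(f"R{i}" for i in range(n)),
    )


@pytest.fixture
def toy_atlas():
    """4-region atlas: 2 left, 2 right, mirror-symmetric volumes."""
    return RegionAtlas(
        labels=("A.L", "A.R", "B.L", "B.R"),
        hemispheres=("L", "R", "L", "R"),
        dmn=(True, True, False, False),
        volumes=np.array([100.0, 100.0, 200.0, 200.0]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small effectful cohort shared across pipeline-level tests."""
    cfg = SyntheticCohortConfig(
        n_tea=5, n_nontea=6, n_regions=20, n_timepoints=80,
        dmn_effect=0.25, sc_global_effect=0.15, seed=202,
    )
    return generate_cohort(cfg)
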