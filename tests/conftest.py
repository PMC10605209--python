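import numpy as np
import pytest

from scnkit import SyntheticSpec, generate_cohort, residualize


def star_adjacency(n: int) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.int8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


def complete_adjacency(n: int) -> np.ndarray:
    a = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(a, 0)
    return a


def path_adjacency(n: int) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.int8)
    idx = np.arange(n - 1)
    a[idx, idx + 1] = 1
    a[idx + 1, idx] = 1
    return a


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A 30-region, 6-module cohort spec used across tests."""
    return SyntheticSpec(n_subjects_per_group=20, n_regions=30,
                         module_sizes=(5,) * 6, seed=11)


@pytest.fixture(scope="session")
def default_residuals():
    """Residualized default synthetic cohort (30/group, 90 regions)."""
    gmv, cov = generate_cohort(SyntheticSpec(), seed=5)
    return residualize(gmv, cov)
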