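"""Shared fixtures: small synthetic cohorts and a warm compiled kernel."""

import numpy as np
import pytest

import thalnet as tn


@pytest.fixture(scope="session")
def default_cohort() -> tn.CohortTable:
    """Full three-group cohort (25/25/40) with the default atrophy pattern."""
    return tn.generate_cohort(tn.SyntheticCohortSpec(seed=7))


@pytest.fixture(scope="session")
def null_pair_spec() -> tn.SyntheticCohortSpec:
    """Two patient groups drawn from one identical distribution (25/25)."""
    return tn.SyntheticCohortSpec(
        group_sizes={"F-MS": 25, "NF-MS": 25},
        atrophy={"F-MS": {}, "NF-MS": {}},
        etiv={"F-MS": (1336.74, 256.13), "NF-MS": (1336.74, 256.13)},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort() -> tn.CohortTable:
    """Tiny three-group cohort for I/O and CLI tests."""
    return tn.generate_cohort(
        tn.SyntheticCohortSpec(group_sizes={"F-MS": 6, "NF-MS": 6, "HC": 8},
                               seed=3))


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Compile the numba kernels once so individual timings are meaningful."""
    rng = np.random.default_rng(0)
    A = np.triu(rng.random((6, 6)) < 0.5, 1)
    tn.all_pairs_shortest_paths((A | A.T).astype(bool))
    yield
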