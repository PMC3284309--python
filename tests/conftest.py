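"""Shared fixtures: expensive model runs are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from polyclust.analytic_models import (AnalyticModelParams,
                                       linear_dissimilarity,
                                       sinusoid_dissimilarity)
from polyclust.helix_dynamics import (freezing_config, init_ideal_helix,
                                      run_fold_unfold)
from polyclust.structure_metrics import rmsd_to_reference

DYNAMIC_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def linear_X():
    return linear_dissimilarity(AnalyticModelParams(n=1000))


@pytest.fixture(scope="session")
def sinusoid_X():
    return sinusoid_dissimilarity(AnalyticModelParams(n=1000, z=1.01))


@pytest.fixture(scope="session")
def ideal_helix():
    return init_ideal_helix(freezing_config())


@pytest.fixture(scope="session")
def dynamic_runs():
    """Full freezing+melting runs for three seeds: {seed: (freeze, melt, concat)}."""
    return {seed: run_fold_unfold(seed) for seed in DYNAMIC_SEEDS}


@pytest.fixture(scope="session")
def helix_rmsd_series(dynamic_runs, ideal_helix):
    """Per-seed RMSD-to-ideal-helix over the concatenated trajectory."""
    return {seed: rmsd_to_reference(concat, ideal_helix)
            for seed, (_, _, concat) in dynamic_runs.items()}


def rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Pair-counting agreement between two partitions (1.0 = identical)."""
    a = np.asarray(a)
    b = np.asarray(b)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(len(a), 1)
    return float((same_a[iu] == same_b[iu]).mean())
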