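import logging

import numpy as np
import pytest

from musicstates import (
    GeneratorConfig,
    compute_phases,
    generate_cohort,
    label_timepoints,
    leading_eigenvector_series,
    table1_schedule,
)

# the generator logs (expected) amplitude clipping; keep test output readable
logging.getLogger("musicstates").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def schedule():
    """The packaged 13-piece stimulus schedule."""
    return table1_schedule()


@pytest.fixture(scope="session")
def labels250(schedule):
    """Condition labels for a 250-volume acquisition at TR = 2 s."""
    return label_timepoints(schedule, tr_s=2.0, n_volumes=250)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small synthetic cohort shared by read-only tests."""
    cfg = GeneratorConfig(n_subjects=6, n_rois=30, n_volumes=120, planted_k=5, seed=1)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_eigs(tiny_cohort):
    _, cohort = tiny_cohort
    return [leading_eigenvector_series(compute_phases(ts)) for ts in cohort.timeseries]


def matched_accuracy(truth: np.ndarray, recovered: np.ndarray, k_true: int, k_rec: int) -> float:
    """Assignment accuracy after optimal (Hungarian) label matching."""
    from scipy.optimize import linear_sum_assignment

    confusion = np.zeros((k_true, k_rec))
    for a, b in zip(truth, recovered):
        confusion[a - 1, b - 1] += 1
    rows, cols = linear_sum_assignment(-confusion)
    return confusion[rows, cols].sum() / truth.size
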