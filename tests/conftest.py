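import numpy as np
import pytest

from tsclust import TimeCourseExperiment

DEFAULT_TIMES = np.array([0.5, 1.0, 2.0, 4.0, 6.0, 24.0])


def make_experiment(ratios, times=None, gene_ids=None, **kwargs):
    """Build a TimeCourseExperiment from a (genes, times, reps) array."""
    ratios = np.asarray(ratios, dtype=float)
    if times is None:
        times = DEFAULT_TIMES[: ratios.shape[1]]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(ratios.shape[0])]
    return TimeCourseExperiment(
        gene_ids=gene_ids, times=np.asarray(times, dtype=float), ratios=ratios, **kwargs
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def six_point_experiment(rng):
    """10 genes x 6 times x 4 replicates of smooth noisy curves."""
    base = rng.normal(0, 1, size=(10, 6, 1))
    return make_experiment(base + rng.normal(0, 0.2, size=(10, 6, 4)))
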