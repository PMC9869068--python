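import numpy as np
import pytest

from restfc import (
    GeneratorConfig,
    RoiTimeSeriesMatrix,
    default_block_spec,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_ts():
    """Factory for small labelled time-series containers."""

    def _make(values, labels=None, subject_id="s1", tr=3.0):
        values = np.asarray(values, dtype=float)
        if labels is None:
            labels = tuple(f"R{i + 1}" for i in range(values.shape[1]))
        return RoiTimeSeriesMatrix(subject_id, tuple(labels), values, tr)

    return _make


@pytest.fixture(scope="session")
def tiny_cohort():
    """Deterministic 2-group, 3-subjects-each cohort of 6-ROI band-limited series."""
    config = GeneratorConfig(
        n_per_group={"HC": 3, "AD": 3}, n_rois=6, n_timepoints=140, seed=7
    )
    return simulate_cohort(config, default_block_spec(6, 2))
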