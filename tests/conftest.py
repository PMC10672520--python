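import numpy as np
import pytest

from caminet import (
    SegmentationParams,
    SyntheticConfig,
    generate,
    generate_worked_fixture,
    segment_recording,
)


@pytest.fixture(scope="session")
def worked():
    """Tiny deterministic 3-unit recording with hand-checkable segmentation."""
    rec, gt = generate_worked_fixture()
    return rec, gt


@pytest.fixture(scope="session")
def small_recording():
    """12-unit, 1-minute synthetic recording with two correlated groups."""
    cfg = SyntheticConfig(
        n_units=12, n_frames=1200, seed=11, n_correlated_groups=2, group_size=4
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_mask(small_recording):
    rec, _ = small_recording
    return segment_recording(rec, SegmentationParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, n_units=10, n_frames=600, p=0.2):
    """Random binary activity mask for oracle comparisons."""
    from caminet import ActivityMask

    return ActivityMask.from_binary(rng.random((n_units, n_frames)) < p)
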