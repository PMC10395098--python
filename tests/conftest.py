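import numpy as np
import pytest

from depcalc.fitting import ROIDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20230719)


@pytest.fixture
def small_dataset():
    """A tiny hand-written ROI dataset whose condition means are known."""
    # Means: 0.3, 0.1, 0.5, 0.2 (the worked fitting example).
    data = np.array(
        [
            [0.25, 0.05, 0.45, 0.15],
            [0.35, 0.15, 0.55, 0.25],
            [0.30, 0.10, 0.50, 0.20],
        ]
    )
    return ROIDataset(region="TEST", event="SUBJECTS_PLUS", data=data)
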