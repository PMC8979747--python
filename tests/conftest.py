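import logging

import numpy as np
import pytest

from dyndet.data_synth import PhantomConfig, generate_dataset
from dyndet.detector import DetectorConfig, build_detector

logging.getLogger("dyndet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_phantoms():
    """A small three-class phantom dataset with masks kept for box checks."""
    cfg = PhantomConfig(image_size=96, class_counts=(4, 3, 3), seed=42,
                        keep_masks=True)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def overfit_run():
    """A detector overfit on a fixed 2-image batch; shared by several tests.

    Returns (detector, state, dataset, first_total_loss, last_total_loss).
    """
    ds = generate_dataset(PhantomConfig(image_size=96, class_counts=(1, 1, 0), seed=7))
    det = build_detector(DetectorConfig(input_size=96, seed=0, cadence=50))
    state = det.new_training_state()
    batch = [(ds.images[0], ds.boxes[0]), (ds.images[1], ds.boxes[1])]
    first = last = None
    for _ in range(220):
        losses, state = det.training_step(batch, state)
        if first is None:
            first = losses["total"]
        last = losses["total"]
    return det, state, ds, first, last


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
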