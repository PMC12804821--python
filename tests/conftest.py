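import time
import warnings

import numpy as np
import pytest

from caucseg.model import build_cauc, forward, shape_report
from caucseg.synthetic import SynthConfig, generate_dataset
from caucseg.train import bundle_arrays, fit_model
from caucseg.model import CAUCNet

warnings.filterwarnings("ignore", message="zero denominator")


@pytest.fixture(scope="session")
def tiny_bundle():
    """Eight 32px synthetic samples spanning all three crops."""
    cfg = SynthConfig(image_size=32, seed=5)
    return generate_dataset(cfg, {"carrot": 3, "sugar_beet": 3, "sunflower": 2}, seed=5)


@pytest.fixture(scope="session")
def tiny_arrays(tiny_bundle):
    return bundle_arrays(tiny_bundle)


@pytest.fixture(scope="session")
def full_model():
    return build_cauc()


@pytest.fixture(scope="session")
def stage_report(full_model):
    return dict(shape_report(full_model))


@pytest.fixture(scope="session")
def overfit_run(tiny_arrays):
    """Tiny-overfit sanity run: 8 images, 60 epochs, CPU.

    Uses the desk-scale overfit setting (32px inputs, batch 2, Adam lr 0.01)
    so the epoch budget yields enough optimizer steps to fit the data.
    """
    images, classes = tiny_arrays
    model = CAUCNet(input_size=32, seed=1)
    t0 = time.perf_counter()
    logs = fit_model(model, images, classes, epochs=60, batch_size=2,
                     learning_rate=1e-2, seed=1)
    elapsed = time.perf_counter() - t0
    probs = forward(model, images)
    return {"model": model, "logs": logs, "probs": probs, "classes": classes,
            "images": images, "elapsed": elapsed}
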