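import numpy as np
import pytest

import wsimil as w
from wsimil.losses import LossConfig
from wsimil.train import TrainConfig

RECOVERY_SEED = 11


@pytest.fixture(scope="session")
def small_params():
    return w.init_params("small", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def one_blob_slide():
    """1024x1024 toy slide with a single 512x512 tissue blob on patch cells
    (1,1),(1,2),(2,1),(2,2) of the 256-px grid."""
    spec = w.ToySlideSpec(width=1024, height=1024, blob_boxes=[(256, 256, 512, 512)], seed=0)
    img, truth = w.render_toy_slide(spec)
    return img, truth


@pytest.fixture(scope="session")
def recovery_run():
    """Train at the synthetic parameter-recovery study conditions:
    witness rate 0.1, 3-sigma mean separation, 200/50/100 split.

    Session-scoped because training takes tens of seconds; every consumer
    treats the result as read-only.
    """
    spec = w.BagSimSpec(
        n_bags=350, prevalence=0.5, witness_rate=0.1, dim=16,
        mu_background=0.0, mu_signal=3.0, sigma=1.0, seed=RECOVERY_SEED,
    )
    data = w.simulate_bags(spec)
    bags, flags = data.bags, data.instance_flags
    train_b, val_b, test_b = bags[:200], bags[200:250], bags[250:350]
    params0 = w.init_params("small", seed=0)
    result = w.train(train_b, val_b, params0, LossConfig(),
                     TrainConfig(seed=0, max_epochs=60))
    report, preds, cm = w.evaluate(result.best_params, test_b)
    return {
        "result": result,
        "report": report,
        "cm": cm,
        "test_bags": test_b,
        "test_flags": flags[250:350],
    }
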