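import numpy as np
import pytest

from rsvpsearch import SimConfig, simulate_image_database
from rsvpsearch._seeds import child_rng


@pytest.fixture(scope="session")
def small_db():
    """200-image, 5-class database with the default cluster spread."""
    cfg = SimConfig(n_images_db=200, n_classes=5, seed=7)
    return simulate_image_database(cfg)


@pytest.fixture(scope="session")
def tight_db():
    """Well-separated clusters: propagation from a few correct labels
    should rank essentially perfectly."""
    cfg = SimConfig(n_images_db=200, n_classes=5, cluster_sd=0.05, seed=7)
    return simulate_image_database(cfg)


@pytest.fixture()
def rng():
    return child_rng(123, "tests")


def make_rng(seed, label="tests"):
    return child_rng(seed, label)
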