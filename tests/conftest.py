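import numpy as np
import pytest

from wakesleep.data import GlyphConfig, generate_glyphs
from wakesleep.model import (
    NetworkConfig,
    freeze_norms,
    init_network,
    sample_sleep,
    sample_wake,
)
from wakesleep.training import TrainConfig, train


def calibrate(net, rng, n_batches=20, batch=64):
    """Accumulate normalization statistics without learning, then freeze."""
    d = net.config.stimulus_dim
    for _ in range(n_batches):
        sample_wake(net, rng.random((batch, d)), rng, training=True)
        sample_sleep(net, batch, rng, training=True)
    return freeze_norms(net)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    return NetworkConfig(
        layer_widths=(5, 4, 3), stimulus_dim=6, n_branches=2, seed=1
    )


@pytest.fixture(scope="session")
def tiny_net(tiny_config):
    """Small network with calibrated, frozen normalization statistics."""
    net = init_network(tiny_config)
    return calibrate(net, np.random.default_rng(2))


@pytest.fixture(scope="session")
def glyphs():
    """14x14 glyph ensemble: (flattened images [600, 196], labels)."""
    images, labels = generate_glyphs(
        GlyphConfig(image_size=(14, 14), n_per_class=60, seed=0)
    )
    return images.reshape(len(images), -1), labels


SMALL_WIDTHS = (16, 8, 4)


def train_small(glyph_x, seed):
    """Coarse-then-fine Wake-Sleep training of a [16, 8, 4] net on 14x14 glyphs."""
    cfg = NetworkConfig(layer_widths=SMALL_WIDTHS, stimulus_dim=196, seed=seed)
    net = init_network(cfg)
    log = None
    for phase, (lr, n_epochs) in enumerate(((2e-3, 150), (5e-4, 50))):
        for _, p in net.compartments():
            p.branch_norm.mode = "training"
            if p.soma_norm is not None:
                p.soma_norm.mode = "training"
        tc = TrainConfig(batch_size=128, n_epochs=n_epochs, learning_rate=lr, seed=seed)
        net, log = train(net, glyph_x, tc, np.random.default_rng(seed + 100 + phase))
    return net, log


@pytest.fixture(scope="session")
def trained_small(glyphs):
    """Wake-Sleep-trained [16, 8, 4] network on the 14x14 glyphs."""
    X, _ = glyphs
    net, log = train_small(X, seed=1)
    return net


@pytest.fixture(scope="session")
def untrained_small():
    """Untrained control: initialized network with calibrated norms only."""
    cfg = NetworkConfig(layer_widths=SMALL_WIDTHS, stimulus_dim=196, seed=7)
    net = init_network(cfg)
    return calibrate(net, np.random.default_rng(8), n_batches=10)
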