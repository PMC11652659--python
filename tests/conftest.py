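import numpy as np
import pytest

from raffmap.mapping import WeightedSeries

#: the printed five-contrast preparation abscissae (ms)
PREP_MS = np.array([0.0, 22.98, 46.66, 70.34, np.inf])


def forward_signal(prep_ms, a=0.8, b=0.2, traff2=80.0):
    prep_ms = np.asarray(prep_ms, float)
    e = np.where(np.isfinite(prep_ms), np.exp(-prep_ms / traff2), 0.0)
    return a * e + b


@pytest.fixture
def forward_series():
    """Factory: noiseless/noisy forward-model series on an ny x nx grid."""

    def build(a=0.8, b=0.2, traff2=80.0, shape=(1, 1), sigma=0.0, seed=0,
              prep_ms=PREP_MS):
        y = forward_signal(prep_ms, a, b, traff2)
        images = np.broadcast_to(y[:, None, None], (len(prep_ms),) + shape).copy()
        if sigma > 0:
            rng = np.random.default_rng(seed)
            images += rng.normal(0.0, sigma, images.shape)
        return WeightedSeries(images=images, prep_ms=prep_ms)

    return build
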