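import numpy as np
import pytest

from subplate.spiketrain import SpikeTrain, ensure_strictly_increasing


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_train(times, channel_id="ch", region="S1Bf", layer="SP", t_stop=None):
    times = np.asarray(times, dtype=float)
    return SpikeTrain(
        channel_id=channel_id,
        region=region,
        layer=layer,
        times=times,
        t_start=0.0,
        t_stop=t_stop if t_stop is not None else (times[-1] + 1.0 if times.size else 1.0),
    )


def poisson_train(rng, rate_hz, span, **kw):
    n = rng.poisson(rate_hz * span)
    times = ensure_strictly_increasing(np.sort(rng.uniform(0.0, span, n)))
    return make_train(times, t_stop=span, **kw)
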