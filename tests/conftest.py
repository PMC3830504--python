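import numpy as np
import pytest

from eogkit import EOGModel, synthetic


def bench_config(seed: int, **overrides) -> synthetic.SimConfig:
    """The end-to-end benchmark conditions: 60 s at 500 Hz, 40 saccades of
    5-10 deg over 8 directions, 15 blinks, moderate drift/noise."""
    kwargs = dict(seed=seed, saccade_amplitudes_deg=(5.0, 7.5, 10.0),
                  n_artifacts=0)
    kwargs.update(overrides)
    return synthetic.SimConfig(**kwargs)


def separation_config(seed: int) -> synthetic.SimConfig:
    """Controlled conditions enforcing event peaks >= 5x the noise floor:
    horizontal saccades and blinks only, low broadband noise."""
    return synthetic.SimConfig(
        seed=seed, duration_s=50.0, n_saccades=20, n_blinks=12,
        saccade_amplitudes_deg=(7.5, 10.0), directions_deg=(0, 180),
        noise_white_sd_uV=0.3, blink_amplitude_jitter_uV=30.0,
        n_artifacts=0, duration_jitter=False)


@pytest.fixture(scope="session")
def bench_run():
    """One fitted benchmark recording shared across tests."""
    rec, truth = synthetic.generate(bench_config(seed=11))
    res = EOGModel(rec).fit(filters=True)
    return rec, truth, res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
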