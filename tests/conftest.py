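import numpy as np
import pytest

from spiketrack.synthetic import ScenarioConfig, generate_scenario
from spiketrack.waveform import SpikeUnit, Waveform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def biphasic(m=48, trough=-400.0, peak=200.0, tc=15.0, pc=27.0, tw=2.0, pw=4.0):
    """A realistic biphasic average waveform for feature tests."""
    i = np.arange(m)
    return Waveform(
        trough * np.exp(-((i - tc) ** 2) / (2 * tw**2))
        + peak * np.exp(-((i - pc) ** 2) / (2 * pw**2))
    )


@pytest.fixture
def biphasic_pair():
    return biphasic(), biphasic(trough=-430.0, peak=180.0, tc=16.0, pc=30.0)


def make_unit(rng, channel=0, day=0, label=0, n_spikes=60, rate=10.0, m=48,
              template=None, noise=5.0):
    """A SpikeUnit with gamma ISIs and noisy copies of a biphasic template."""
    if template is None:
        template = biphasic(m).samples
    isis = 0.0015 + rng.gamma(2.0, 1.0 / (2.0 * rate), size=n_spikes)
    t = np.cumsum(isis)
    w = template[None, :] + rng.normal(0, noise, size=(n_spikes, m))
    return SpikeUnit(channel_id=channel, day=day, unit_label=label,
                     waveforms=w, timestamps=t)


@pytest.fixture(scope="session")
def small_scenario():
    """An 8-channel, 8-day, 2-minute scenario shared by slower tests."""
    cfg = ScenarioConfig(channels=8, days=8, duration=120.0, seed=7)
    sessions, truth = generate_scenario(cfg)
    return cfg, sessions, truth


@pytest.fixture(scope="session")
def frozen_scenario_training(small_scenario):
    """Training vectors + trained models reused across tracker/eval tests."""
    from spiketrack.classifiers import train
    from spiketrack.synthetic import make_labeled_vectors

    _, sessions, truth = small_scenario
    ts = make_labeled_vectors(sessions[:4], truth, 4, days=[0, 1, 2, 3])
    return ts, {kind: train(ts, kind, seed=0) for kind in ("SVM", "RVM")}
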