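"""Synthetic multi-day chronic recording scenarios with known unit identity.

Real chronic microelectrode-array recordings of the kind this tracker targets
are rarely shareable, so the generator emulates their essential statistics:

* a multi-channel array with 1-4 spike-sorted units per channel;
* biphasic extracellular spike templates (a negative trough followed by a
  positive peak, each a Gaussian lobe) with 300-1200 uV peak-to-peak range
  and 0.3-0.5 ms trough-to-peak transition at 30 kHz;
* gamma-distributed inter-spike intervals above an absolute refractory
  period, giving realistic ISIH shapes;
* day-to-day electrode drift: multiplicative log-normal amplitude steps,
  bounded jitter of lobe centres/widths, log-normal firing-rate steps, and
  additive white noise on every sampled spike;
* stochastic permanent unit dropout and new-unit appearance.

Every (day, channel, unit_label) record carries a hidden true identity, so
tracking output can be scored exactly.  All randomness flows from one master
seed through named substreams (templates, drift, spikes, noise, labels), so
one stage can be perturbed without disturbing the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classifiers import TrainingSet, build_training_set
from .waveform import SpikeUnit, Waveform, peak_matching_dissimilarity

__all__ = [
    "UnitTemplate",
    "DriftModel",
    "ScenarioConfig",
    "generate_scenario",
    "make_labeled_vectors",
    "paper_like_config",
]


@dataclass(frozen=True)
class UnitTemplate:
    """Biphasic spike template plus firing statistics for one neuron.

    Amplitudes in microvolts (trough negative), lobe centres/widths in
    samples; ISIs follow ``refractory + Gamma(isi_shape, scale)`` with the
    scale set so the mean interval matches ``firing_rate``.
    """

    trough_amp: float
    peak_amp: float
    trough_center: float
    peak_center: float
    trough_width: float
    peak_width: float
    isi_shape: float
    firing_rate: float
    refractory: float = 0.0015

    def __post_init__(self) -> None:
        if self.trough_amp >= 0 or self.peak_amp <= 0:
            raise ValueError("template must have a negative trough and positive peak")
        if self.refractory < 0.001:
            raise ValueError("refractory period must be >= 1 ms")
        if self.firing_rate <= 0:
            raise ValueError("firing rate must be positive")

    def waveform(self, m: int) -> np.ndarray:
        i = np.arange(m)
        trough = self.trough_amp * np.exp(
            -((i - self.trough_center) ** 2) / (2 * self.trough_width**2)
        )
        peak = self.peak_amp * np.exp(
            -((i - self.peak_center) ** 2) / (2 * self.peak_width**2)
        )
        return trough + peak


@dataclass(frozen=True)
class DriftModel:
    """Day-to-day instability parameters.

    ``sigma_amp``: std of the log-normal multiplicative amplitude step per
    day.  ``sigma_shape``: relative jitter of lobe centres and widths per day
    (bounded so lobes cannot wander off the waveform).  ``noise_sigma``:
    additive white noise per waveform sample, microvolts.  ``sigma_rate``:
    std of the log-normal firing-rate step per day.  With every sigma at
    zero, each day reproduces the template exactly.
    """

    sigma_amp: float = 0.05
    sigma_shape: float = 0.02
    noise_sigma: float = 20.0
    sigma_rate: float = 0.1

    def __post_init__(self) -> None:
        if min(self.sigma_amp, self.sigma_shape, self.noise_sigma, self.sigma_rate) < 0:
            raise ValueError("drift sigmas must be >= 0")

    @classmethod
    def zero(cls) -> "DriftModel":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Scale and dynamics of a simulated chronic recording scenario.

    Defaults mirror the tracker's intended regime: 15-minute (900 s)
    sessions from a multi-channel array sampled at 30 kHz with 48-sample
    spike snippets, 1-4 units per channel, moderate drift, and a small daily
    probability of permanent unit loss or of a new unit appearing.
    """

    channels: int = 32
    units_min: int = 1
    units_max: int = 4
    days: int = 15
    duration: float = 900.0
    dropout_p: float = 0.02
    new_unit_p: float = 0.02
    sampling_rate: float = 30000.0
    m: int = 48
    seed: int = 0
    drift: DriftModel = field(default_factory=DriftModel)
    min_template_distance: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_p <= 1 and 0 <= self.new_unit_p <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.days < 1 or self.channels < 1:
            raise ValueError("need at least one day and one channel")
        if not 1 <= self.units_min <= self.units_max:
            raise ValueError("require 1 <= units_min <= units_max")


def paper_like_config(seed: int = 0) -> ScenarioConfig:
    """A training-scale preset: many channels, ~6 sessions, 15 min each.

    Sized so that consecutive-day positive pairs and same-day negative pairs
    land on the order of 900 and 600 vectors respectively.
    """
    return ScenarioConfig(channels=96, units_min=1, units_max=3, days=6, seed=seed)


@dataclass
class _LiveUnit:
    identity: str
    base: UnitTemplate
    amp_scale: float = 1.0
    trough_center: float = 0.0
    peak_center: float = 0.0
    trough_width: float = 0.0
    peak_width: float = 0.0
    rate: float = 0.0

    @classmethod
    def fresh(cls, identity: str, base: UnitTemplate) -> "_LiveUnit":
        return cls(
            identity=identity, base=base,
            trough_center=base.trough_center, peak_center=base.peak_center,
            trough_width=base.trough_width, peak_width=base.peak_width,
            rate=base.firing_rate,
        )

    def evolve(self, rng: np.random.Generator, drift: DriftModel) -> None:
        self.amp_scale *= float(np.exp(rng.normal(0.0, drift.sigma_amp)))
        b = self.base
        jitter = drift.sigma_shape
        if jitter > 0:
            self.trough_center = float(
                np.clip(self.trough_center + rng.normal(0, jitter * b.trough_width),
                        b.trough_center - 2, b.trough_center + 2)
            )
            self.peak_center = float(
                np.clip(self.peak_center + rng.normal(0, jitter * b.peak_width),
                        b.peak_center - 2, b.peak_center + 2)
            )
            self.trough_width = float(
                np.clip(self.trough_width * np.exp(rng.normal(0, jitter)),
                        0.5 * b.trough_width, 2.0 * b.trough_width)
            )
            self.peak_width = float(
                np.clip(self.peak_width * np.exp(rng.normal(0, jitter)),
                        0.5 * b.peak_width, 2.0 * b.peak_width)
            )
        self.rate = float(
            np.clip(self.rate * np.exp(rng.normal(0.0, drift.sigma_rate)), 0.5, 25.0)
        )

    def waveform_today(self, m: int) -> np.ndarray:
        t = replace(
            self.base,
            trough_center=self.trough_center, peak_center=self.peak_center,
            trough_width=self.trough_width, peak_width=self.peak_width,
        )
        return self.amp_scale * t.waveform(m)


def _draw_template(rng: np.random.Generator) -> UnitTemplate:
    trough = -float(rng.uniform(220.0, 750.0))
    peak = float(rng.uniform(0.4, 0.6)) * abs(trough)
    tc = float(rng.uniform(12.0, 18.0))
    pc = tc + float(rng.uniform(8.0, 16.0))  # 0.27-0.53 ms at 30 kHz
    return UnitTemplate(
        trough_amp=trough, peak_amp=peak,
        trough_center=tc, peak_center=pc,
        trough_width=float(rng.uniform(1.5, 3.0)),
        peak_width=float(rng.uniform(3.0, 6.0)),
        isi_shape=float(rng.uniform(1.5, 6.0)),
        firing_rate=float(rng.uniform(1.5, 8.0)),
    )


def _draw_distinct_template(
    rng: np.random.Generator, existing: list[UnitTemplate], cfg: ScenarioConfig,
    max_tries: int = 200,
) -> UnitTemplate:
    """A new template whose base shape is peak-matching-distinct from peers."""
    waves = [Waveform(t.waveform(cfg.m), cfg.sampling_rate) for t in existing]
    for _ in range(max_tries):
        cand = _draw_template(rng)
        wc = Waveform(cand.waveform(cfg.m), cfg.sampling_rate)
        if all(
            peak_matching_dissimilarity(wc, w) > cfg.min_template_distance
            for w in waves
        ):
            return cand
    raise RuntimeError(
        "could not draw a sufficiently distinct unit template; "
        "lower min_template_distance or units per channel"
    )


def _spike_times(
    rng: np.random.Generator, unit: _LiveUnit, duration: float
) -> np.ndarray:
    shape = unit.base.isi_shape
    refractory = unit.base.refractory
    mean_isi = 1.0 / unit.rate
    scale = max(mean_isi - refractory, 1e-4) / shape
    n_draw = int(duration / mean_isi * 1.5) + 20
    times = np.cumsum(refractory + rng.gamma(shape, scale, size=n_draw))
    while times.size and times[-1] < duration:  # rare under-draw
        extra = np.cumsum(refractory + rng.gamma(shape, scale, size=n_draw)) + times[-1]
        times = np.concatenate([times, extra])
    return times[times < duration]


def generate_scenario(cfg: ScenarioConfig):
    """Simulate a full multi-day scenario.

    Returns ``(sessions, truth)``: ``sessions[d]`` maps channel ->
    list of SpikeUnit for day d, and ``truth`` (a GroundTruth) records every
    record's hidden identity.  Bit-reproducible from ``cfg.seed``.
    """
    from .evaluation import GroundTruth  # local: evaluation imports this module

    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_templates, rng_drift, rng_spikes, rng_noise, rng_labels = (
        np.random.default_rng(s) for s in streams
    )

    channel_units: dict[int, list[_LiveUnit]] = {}
    serial: dict[int, int] = {}

    def new_unit(chan: int, peers: list[_LiveUnit]) -> _LiveUnit:
        tmpl = _draw_distinct_template(rng_templates, [u.base for u in peers], cfg)
        serial[chan] = serial.get(chan, 0) + 1
        return _LiveUnit.fresh(f"c{chan}u{serial[chan]}", tmpl)

    for chan in range(cfg.channels):
        count = int(rng_templates.integers(cfg.units_min, cfg.units_max + 1))
        units: list[_LiveUnit] = []
        for _ in range(count):
            units.append(new_unit(chan, units))
        channel_units[chan] = units

    sessions: list[dict[int, list[SpikeUnit]]] = []
    labels: dict[tuple[int, int, int], str] = {}

    for day in range(cfg.days):
        session: dict[int, list[SpikeUnit]] = {}
        for chan in range(cfg.channels):
            units = channel_units[chan]
            if day > 0:
                # permanent dropout, then evolve survivors, then new arrivals
                units = [u for u in units if rng_drift.random() >= cfg.dropout_p]
                for u in units:
                    u.evolve(rng_drift, cfg.drift)
                if len(units) < cfg.units_max and rng_drift.random() < cfg.new_unit_p:
                    units.append(new_unit(chan, units))
                channel_units[chan] = units
            order = rng_labels.permutation(len(units))
            day_units: list[SpikeUnit] = []
            for lbl, k in enumerate(order):
                u = units[k]
                t = _spike_times(rng_spikes, u, cfg.duration)
                if t.size < 2:  # silent unit today: not sorted, not recorded
                    continue
                base_wave = u.waveform_today(cfg.m).astype(np.float32)
                w = np.tile(base_wave, (t.size, 1))
                if cfg.drift.noise_sigma > 0:
                    w = w + rng_noise.normal(
                        0.0, cfg.drift.noise_sigma, size=w.shape
                    ).astype(np.float32)
                day_units.append(
                    SpikeUnit(
                        channel_id=chan, day=day, unit_label=lbl,
                        waveforms=w, timestamps=t,
                        sampling_rate=cfg.sampling_rate,
                    )
                )
                labels[(day, chan, lbl)] = u.identity
            session[chan] = day_units
        sessions.append(session)
    return sessions, GroundTruth(labels)


def make_labeled_vectors(
    sessions: list[dict],
    truth,
    feature_set_id: int,
    *,
    days: list[int] | None = None,
    smoothing_sigma: float = 1.0,
    binning=None,
) -> TrainingSet:
    """Labelled training vectors from simulator truth.

    Positives: consecutive-session pairs of the same identity (newer unit
    vs older reference).  Negatives: all unordered pairs of units co-recorded
    on one channel on one day.  ``days`` gives the truth day index of each
    entry of ``sessions`` (defaults to 0..len-1).
    """
    if len(sessions) < 2:
        raise ValueError("need at least two sessions for cross-day positives")
    if days is None:
        days = list(range(len(sessions)))
    by_key: dict[tuple[int, int, int], SpikeUnit] = {}
    for d, session in zip(days, sessions):
        for chan, units in session.items():
            for u in units:
                by_key[(d, chan, u.unit_label)] = u

    positives = []
    for prev_day, next_day in zip(days[:-1], days[1:]):
        channels = {c for (d, c, _) in by_key if d in (prev_day, next_day)}
        for chan in sorted(channels):
            prev_ids = truth.identities_on(prev_day, chan)
            next_ids = truth.identities_on(next_day, chan)
            for ident in sorted(set(prev_ids) & set(next_ids)):
                newer = by_key.get((next_day, chan, next_ids[ident]))
                older = by_key.get((prev_day, chan, prev_ids[ident]))
                if newer is not None and older is not None:
                    positives.append((newer, older))

    same_day = [
        sorted(units, key=lambda u: u.unit_label)
        for d, session in zip(days, sessions)
        for units in session.values()
        if len(units) >= 2
    ]
    return build_training_set(
        positives, same_day, feature_set_id,
        smoothing_sigma=smoothing_sigma, binning=binning,
    )
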