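"""Average-spike-waveform features and dissimilarity measures.

A chronically recorded putative single unit is summarised, per session, by the
average of its sampled spike waveforms.  Four dissimilarity measures compare
two average waveforms recorded on the same channel on different days:

``PC``
    Pearson-correlation dissimilarity, ``1 - r``.  Sensitive to overall shape,
    invariant to positive affine rescaling.
``PH``
    Normalised peak-to-peak height difference: the difference of the two
    waveforms' peak-to-peak amplitudes, normalised by the amplitude of the
    reference waveform.  The same absolute amplitude change counts for more
    between two small units than between two large ones.
``PT``
    Normalised peak-to-peak transition-time difference: the difference of the
    signed sample-index intervals between each waveform's global maximum and
    minimum, normalised by the reference waveform's interval.
``PM``
    Peak-matching dissimilarity: a heuristic comparison of the detected peaks
    of the two waveforms (amplitude-weighted peaks, Gaussian closeness factors
    in time and amplitude, geometric mean of the two asymmetric similarities).

``PH`` and ``PT`` are asymmetric: their second argument is the *reference*
(normalising) waveform, by convention the stored profile instance.  ``PC`` and
``PM`` are symmetric.  All four are zero on identical waveforms.

Amplitudes are in microvolts; waveform time is measured in samples internally,
with the sampling rate carried for conversion at API boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "Waveform",
    "SpikeUnit",
    "PeakMatchParams",
    "average_waveform",
    "smooth_waveform",
    "pearson_dissimilarity",
    "peak_height_dissimilarity",
    "peak_time_dissimilarity",
    "peak_matching_dissimilarity",
]


@dataclass(frozen=True)
class Waveform:
    """A sampled voltage trace (microvolts) at a fixed sampling rate."""

    samples: np.ndarray
    sampling_rate: float = 30000.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("waveform must be a 1-D sequence of >= 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must all be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def m(self) -> int:
        return int(self.samples.size)


@dataclass
class SpikeUnit:
    """One spike-sorted unit on one channel on one recording day.

    ``waveforms`` is the l x m matrix of sampled spike waveforms (microvolts),
    ``timestamps`` the l spike times in seconds, strictly ascending.
    """

    channel_id: int
    day: int
    unit_label: int
    waveforms: np.ndarray
    timestamps: np.ndarray
    sampling_rate: float = 30000.0

    def __post_init__(self) -> None:
        w = np.asarray(self.waveforms)
        t = np.asarray(self.timestamps, dtype=float)
        if w.ndim != 2 or w.shape[0] < 1:
            raise ValueError("waveforms must be a non-empty l x m matrix")
        if t.shape != (w.shape[0],):
            raise ValueError("timestamps must have one entry per spike waveform")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly ascending")
        self.waveforms = w
        self.timestamps = t

    @property
    def n_spikes(self) -> int:
        return int(self.waveforms.shape[0])

    @property
    def m(self) -> int:
        return int(self.waveforms.shape[1])


def average_waveform(unit: SpikeUnit) -> Waveform:
    """Sample-wise mean of a unit's spike waveforms."""
    if unit.waveforms.size == 0:
        raise ValueError("unit has no spike waveforms; cannot average")
    return Waveform(unit.waveforms.mean(axis=0, dtype=float), unit.sampling_rate)


def smooth_waveform(w: Waveform, kernel_sigma: float) -> Waveform:
    """Low-pass an average waveform with a Gaussian kernel.

    ``kernel_sigma`` is the kernel standard deviation in samples.  Edges are
    handled by reflection, which conserves the total sample mass; a sigma of
    zero returns the input unchanged.
    """
    if kernel_sigma < 0:
        raise ValueError("kernel_sigma must be >= 0")
    if kernel_sigma == 0:
        return w
    smoothed = gaussian_filter1d(w.samples, sigma=kernel_sigma, mode="reflect")
    return Waveform(smoothed, w.sampling_rate)


def pearson_dissimilarity(wx: Waveform, wy: Waveform) -> float:
    """Shape dissimilarity ``1 - r`` with r the Pearson correlation.

    0 for any positive affine relation, 2 for perfect anticorrelation.
    """
    _check_equal_length(wx, wy)
    x, y = wx.samples, wy.samples
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("degenerate (constant) waveform: correlation undefined")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return 1.0 - r


def peak_height_dissimilarity(wx: Waveform, wy: Waveform) -> float:
    """Peak-to-peak amplitude difference, normalised by the reference ``wy``.

    ``|(ptp(wy) - ptp(wx)) / ptp(wy)|`` with ptp = max - min.  Asymmetric:
    the second argument normalises.
    """
    _check_equal_length(wx, wy)
    ptp_y = float(np.ptp(wy.samples))
    if ptp_y == 0:
        raise ValueError("flat reference waveform: peak-to-peak height is zero")
    ptp_x = float(np.ptp(wx.samples))
    return abs((ptp_y - ptp_x) / ptp_y)


def _transition(w: Waveform) -> int:
    """Signed sample-index interval from global minimum to global maximum.

    Ties in max/min break toward the earliest index.
    """
    return int(np.argmax(w.samples)) - int(np.argmin(w.samples))


def peak_time_dissimilarity(wx: Waveform, wy: Waveform) -> float:
    """Min-to-max transition-time difference, normalised by the reference.

    Both transitions are signed sample-index differences (argmax - argmin);
    the sign is kept inside the formula, the outer absolute value is taken
    last.  Asymmetric: ``wy`` normalises.
    """
    _check_equal_length(wx, wy)
    ty = _transition(wy)
    if ty == 0:
        raise ValueError("degenerate reference waveform: max and min coincide")
    tx = _transition(wx)
    return abs((ty - tx) / ty)


@dataclass(frozen=True)
class PeakMatchParams:
    """Parameters of the peak-matching dissimilarity.

    ``prominence_fraction``: minimum peak prominence as a fraction of the
    waveform's peak-to-peak amplitude.  ``tau_t``: time tolerance of the
    closeness factor in samples (default m/8).  ``tau_a_fraction``: amplitude
    tolerance as a fraction of the target waveform's peak-to-peak amplitude.
    """

    prominence_fraction: float = 0.1
    tau_t: float | None = None
    tau_a_fraction: float = 0.25


def _detect_peaks(w: Waveform, prominence_fraction: float):
    """Local extrema (both signs) of the mean-removed waveform.

    Returns (indices, mean-removed amplitudes, normalised absolute weights).
    Endpoints are not considered peaks.
    """
    z = w.samples - w.samples.mean()
    prom = prominence_fraction * float(np.ptp(w.samples))
    if prom <= 0:
        raise ValueError("featureless (flat) waveform: no detectable peaks")
    imax, _ = find_peaks(z, prominence=prom)
    imin, _ = find_peaks(-z, prominence=prom)
    idx = np.sort(np.concatenate([imax, imin]))
    if idx.size == 0:
        raise ValueError("featureless waveform: no peak exceeds the prominence floor")
    amps = z[idx]
    weights = np.abs(amps)
    return idx, amps, weights / weights.sum()


def _asymmetric_similarity(src, dst, tau_t: float, tau_a: float) -> float:
    """Sum over source peaks of weight times best closeness to a target peak."""
    si, sa, sw = src
    di, da, _ = dst
    dt = (si[:, None] - di[None, :]) / tau_t
    dv = (sa[:, None] - da[None, :]) / tau_a
    closeness = np.exp(-(dt**2 + dv**2))
    return float(np.sum(sw * closeness.max(axis=1)))


def peak_matching_dissimilarity(
    wx: Waveform, wy: Waveform, params: PeakMatchParams | None = None
) -> float:
    """Heuristic distance between the peak shapes of two waveforms.

    Peaks (local extrema of either sign, prominence-gated) are weighted by
    absolute mean-removed amplitude; each source peak contributes its weight
    times the best Gaussian closeness factor
    ``exp(-[(di/tau_t)^2 + (da/tau_a)^2])`` to any target peak.  The
    symmetric similarity is the geometric mean of the two asymmetric sums and
    the dissimilarity is one minus it; range [0, 1], 0 on identical inputs.
    Mean removal makes the measure invariant to a common constant offset.
    """
    _check_equal_length(wx, wy)
    p = params or PeakMatchParams()
    px = _detect_peaks(wx, p.prominence_fraction)
    py = _detect_peaks(wy, p.prominence_fraction)
    tau_t = p.tau_t if p.tau_t is not None else wx.m / 8.0
    s_xy = _asymmetric_similarity(px, py, tau_t, p.tau_a_fraction * float(np.ptp(wy.samples)))
    s_yx = _asymmetric_similarity(py, px, tau_t, p.tau_a_fraction * float(np.ptp(wx.samples)))
    return 1.0 - float(np.sqrt(s_xy * s_yx))


def _check_equal_length(wx: Waveform, wy: Waveform) -> None:
    if wx.m != wy.m:
        raise ValueError(f"waveform lengths differ: {wx.m} != {wy.m}")
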