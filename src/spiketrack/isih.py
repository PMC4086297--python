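"""Inter-spike-interval histograms and distribution dissimilarity measures.

A unit's firing pattern is summarised by its normalised inter-spike-interval
histogram (ISIH): the empirical probability distribution of times between
consecutive spikes.  Four measures compare two ISIHs built on the same bins:

``KLD``  symmetrised Kullback-Leibler divergence (total information divergence)
``BD``   Bhattacharyya distance, ``-ln sum sqrt(Hx * Hy)`` (overlap)
``KS``   Kolmogorov-Smirnov statistic, max absolute CDF difference
``EMD``  earth mover's distance by the running-carry recursion over the bins
         (equivalently, the sum of absolute CDF differences)

All are non-negative, symmetric, and zero on identical histograms.  The bin
layout is uniform on [0, max_isi) with one overflow bin for longer intervals;
empty bins are floored at a tiny probability and the histogram renormalised so
the logarithmic measures stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ISIH",
    "IsihBinning",
    "build_isih",
    "kl_divergence_sym",
    "bhattacharyya",
    "ks_statistic",
    "earth_movers",
]


@dataclass(frozen=True)
class IsihBinning:
    """Uniform ISIH binning: ``bin_width`` bins on [0, max_isi) plus overflow.

    ``epsilon_floor`` replaces empty bins before renormalisation so that the
    logarithmic dissimilarities remain defined.
    """

    bin_width: float = 0.001
    max_isi: float = 1.0
    epsilon_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        n = self.max_isi / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("max_isi must be a multiple of bin_width")
        if not 0 < self.epsilon_floor < self.bin_width / self.max_isi:
            raise ValueError("epsilon_floor must be small and positive")

    @property
    def edges(self) -> np.ndarray:
        n = int(round(self.max_isi / self.bin_width))
        finite = np.arange(n + 1) * self.bin_width
        return np.concatenate([finite, [np.inf]])


@dataclass(frozen=True)
class ISIH:
    """Normalised inter-spike-interval histogram (bin masses sum to one)."""

    probabilities: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        e = np.asarray(self.bin_edges, dtype=float)
        if p.size < 2:
            raise ValueError("an ISIH needs at least two bins")
        if e.size != p.size + 1 or not np.all(np.diff(e) > 0):
            raise ValueError("bin_edges must be strictly ascending with L+1 entries")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("bin masses must be non-negative and sum to 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "bin_edges", e)

    @property
    def n_bins(self) -> int:
        return int(self.probabilities.size)


def build_isih(timestamps, binning: IsihBinning | None = None) -> ISIH:
    """Histogram the successive differences of ascending spike times.

    Intervals at or beyond ``max_isi`` land in the overflow bin.  Counts are
    normalised to unit mass, empty bins floored at ``epsilon_floor`` and the
    result renormalised.
    """
    binning = binning or IsihBinning()
    t = np.asarray(timestamps, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 spikes (1 interval) to build an ISIH")
    isis = np.diff(t)
    if np.any(isis <= 0):
        raise ValueError("timestamps must be strictly ascending")
    edges = binning.edges
    n_finite = edges.size - 2
    # floor(isi / width) with a tiny tolerance so intervals sitting exactly on
    # a bin edge land in the half-open bin to their right despite round-off
    idx = np.floor(isis / binning.bin_width + 1e-9).astype(int)
    idx = np.clip(idx, 0, n_finite)  # >= max_isi collapses into the overflow bin
    counts = np.bincount(idx, minlength=n_finite + 1)
    p = counts / counts.sum()
    p = np.where(p == 0, binning.epsilon_floor, p)
    p = p / p.sum()
    return ISIH(p, edges)


def _check_same_binning(hx: ISIH, hy: ISIH) -> None:
    if hx.n_bins != hy.n_bins or not np.array_equal(hx.bin_edges, hy.bin_edges):
        raise ValueError("ISIHs have different binning; measures are undefined")


def kl_divergence_sym(hx: ISIH, hy: ISIH) -> float:
    """Symmetrised KL divergence, ``[D(Hx||Hy) + D(Hy||Hx)] / 2``."""
    _check_same_binning(hx, hy)
    px, py = hx.probabilities, hy.probabilities
    if np.any(px <= 0) or np.any(py <= 0):
        raise ValueError("KL divergence requires strictly positive bin masses")
    log_ratio = np.log(px / py)
    d = 0.5 * (np.sum(px * log_ratio) - np.sum(py * log_ratio))
    return max(float(d), 0.0)


def bhattacharyya(hx: ISIH, hy: ISIH) -> float:
    """Bhattacharyya distance, ``-ln sum sqrt(Hx * Hy)``."""
    _check_same_binning(hx, hy)
    overlap = float(np.sum(np.sqrt(hx.probabilities * hy.probabilities)))
    if overlap <= 0:
        raise ValueError("zero overlap between histograms")
    return max(-float(np.log(overlap)), 0.0)


def ks_statistic(hx: ISIH, hy: ISIH) -> float:
    """Kolmogorov-Smirnov statistic: max absolute cumulative-mass difference."""
    _check_same_binning(hx, hy)
    fx = np.cumsum(hx.probabilities)
    fy = np.cumsum(hy.probabilities)
    return float(np.max(np.abs(fx - fy)))


def earth_movers(hx: ISIH, hy: ISIH) -> float:
    """Earth mover's distance via the running-carry recursion over bins.

    With carry(0) = 0 and carry(i+1) = Hx[i] + carry(i) - Hy[i], the distance
    is the sum of |carry(i)|, i.e. the total mass moved between adjacent bins.
    Computed on probability mass per bin (unitless, not scaled by bin width).
    """
    _check_same_binning(hx, hy)
    carries = np.cumsum(hx.probabilities - hy.probabilities)
    return float(np.sum(np.abs(carries)))
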