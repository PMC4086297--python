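"""Compare the firing statistics of two spike trains via their ISIHs.

Draws two gamma-renewal spike trains — one regular, one bursty — builds
normalised inter-spike-interval histograms and prints the four distribution
distances.  Same-unit comparisons give values near 0; the bursty train is
far from the regular one under every measure.
"""

import numpy as np

from spiketrack.isih import (
    bhattacharyya,
    build_isih,
    earth_movers,
    kl_divergence_sym,
    ks_statistic,
)

rng = np.random.default_rng(0)


def gamma_train(shape, rate, n=2000):
    isis = 0.0015 + rng.gamma(shape, (1 / rate - 0.0015) / shape, size=n)
    return np.cumsum(isis)


regular_a = build_isih(gamma_train(6.0, 8.0))   # regular 8 Hz unit, day 1
regular_b = build_isih(gamma_train(6.0, 8.0))   # the same statistics, day 2
bursty = build_isih(gamma_train(0.8, 8.0))      # bursty unit, same mean rate

for name, h in [("same statistics", regular_b), ("bursty unit", bursty)]:
    print(f"regular vs {name}:")
    print(f"  KLD = {kl_divergence_sym(regular_a, h):8.4f}"
          f"  BD = {bhattacharyya(regular_a, h):7.4f}"
          f"  KS = {ks_statistic(regular_a, h):6.4f}"
          f"  EMD = {earth_movers(regular_a, h):7.4f}")
print("the two units share a mean rate, so only the ISI *shape* separates")
print("them - which is exactly what these histogram distances capture.")
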