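"""Histogram-based upscaling of capillary diameters to a goal beta law.

Measured capillary diameters in mouse cortex are systematically small
compared with the literature consensus (mean ≈ 4 μm).  The upscaling step
deterministically shifts the smallest diameters upward until the empirical
histogram matches a goal beta distribution defined on
[``d_min``, ``d_max``] with prescribed mean and standard deviation.

The algorithm works bin-by-bin from the smallest diameters to the largest:
whenever a bin holds more vessels than the beta goal allows, the surplus
vessels (the largest ones in the bin, above the cut diameter
``d_cut`` at which the bin count equals its goal) are shifted upward by
the constant ``d_bin_upper - d_cut`` so they spill into later bins.  Bins
already at or below their goal count are left untouched (deficits are not
back-filled).  The procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class UpscaleConfigError(ValueError):
    """The goal (mean, std) pair is not attainable by a beta distribution."""


@dataclass(frozen=True)
class UpscaleConfig:
    """Goal distribution and binning of the diameter upscaling.

    Defaults implement a beta distribution with mean 4.0 μm and standard
    deviation 1.0 μm on the diameter range [2.5 μm, 9.0 μm], discretized
    into 500 bins (bin width 0.013 μm).
    """

    goal_mean: float = 4.0
    goal_std: float = 1.0
    d_min: float = 2.5
    d_max: float = 9.0
    n_bins: int = 500

    def __post_init__(self):
        if not (self.d_min < self.goal_mean < self.d_max):
            raise UpscaleConfigError("goal mean must lie strictly inside [d_min, d_max]")
        if self.n_bins < 2:
            raise UpscaleConfigError("need at least 2 bins")
        # attainability checked by solving for the shapes
        self.shape_parameters()

    @property
    def bin_width(self) -> float:
        return (self.d_max - self.d_min) / self.n_bins

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.d_min, self.d_max, self.n_bins + 1)

    def shape_parameters(self) -> tuple[float, float]:
        """Beta shapes (a, b) from the goal moments on the scaled interval.

        With m = (mean - d_min)/(d_max - d_min) and v = (std/(d_max -
        d_min))^2 the standard moment equations give
        ``a = m (m(1-m)/v - 1)`` and ``b = (1-m)(m(1-m)/v - 1)``; both
        must be positive for the pair to be attainable.
        """
        span = self.d_max - self.d_min
        m = (self.goal_mean - self.d_min) / span
        v = (self.goal_std / span) ** 2
        if v >= m * (1 - m):
            raise UpscaleConfigError(
                f"std {self.goal_std} too large for a beta law on "
                f"[{self.d_min}, {self.d_max}] with mean {self.goal_mean}"
            )
        common = m * (1 - m) / v - 1.0
        a, b = m * common, (1 - m) * common
        if a <= 0 or b <= 0:
            raise UpscaleConfigError("infeasible beta parameters")
        return a, b

    def goal_distribution(self) -> stats.rv_continuous:
        a, b = self.shape_parameters()
        return stats.beta(a, b, loc=self.d_min, scale=self.d_max - self.d_min)


def goal_counts(config: UpscaleConfig, n_total: int) -> np.ndarray:
    """Integer goal count per bin.

    The beta CDF mass of each bin times the total vessel count is rounded
    half-up; the rounding remainder is carried into the next bin so the
    counts sum exactly to ``n_total``.
    """
    dist = config.goal_distribution()
    cdf = dist.cdf(config.bin_edges)
    mass = np.diff(cdf) / (cdf[-1] - cdf[0])  # normalize over the support
    counts = np.empty(config.n_bins, dtype=np.int64)
    carry = 0.0
    for i, m in enumerate(mass):
        want = m * n_total + carry
        counts[i] = int(np.floor(want + 0.5))
        carry = want - counts[i]
    return counts


def histogram_upscale(diameters, config: UpscaleConfig | None = None) -> np.ndarray:
    """Upscale a list of diameters (μm) toward the goal beta histogram.

    Returns an array of the same length and order as the input; every
    output value is >= its input value and lies within
    [``d_min``, ``d_max``].  Values below ``d_min`` are counted in the
    first bin.  The algorithm is deterministic; within-bin ordering is by
    diameter with ties broken by position (vessel id order).
    """
    if config is None:
        config = UpscaleConfig()
    original = np.asarray(diameters, dtype=float)
    d = original.copy()
    n = d.size
    if n == 0:
        return d

    edges = config.bin_edges
    goals = goal_counts(config, n)

    for i in range(config.n_bins):
        lo, hi = edges[i], edges[i + 1]
        last = i == config.n_bins - 1
        if i == 0:
            in_bin = d < hi  # sub-d_min values clamp into bin 0 for counting
        elif last:
            in_bin = (d >= lo) & (d <= hi)
        else:
            in_bin = (d >= lo) & (d < hi)
        current = int(in_bin.sum())
        if current <= goals[i]:
            continue
        # sort members by (diameter, original position); keep the goal
        # count, shift the rest up by the constant hi - d_cut
        members = np.flatnonzero(in_bin)
        order = members[np.lexsort((members, d[members]))]
        keep = int(goals[i])
        d_cut = d[order[keep - 1]] if keep > 0 else lo
        surplus = order[keep:]
        d[surplus] += hi - d_cut
    # final range: [d_min, d_max], never below the input (inputs already
    # above d_max — not capillaries by labeling — pass through unchanged)
    d = np.clip(d, config.d_min, config.d_max)
    return np.where(original > config.d_max, original, d)


def upscale_network(network, config: UpscaleConfig | None = None):
    """Return a copy of ``network`` with capillary (type C) diameters
    upscaled; all other vessels pass through unchanged."""
    net = network.copy()
    mask = (net.vessels["type"] == "C").to_numpy()
    diam = net.vessels["diameter"].to_numpy(float).copy()
    diam[mask] = histogram_upscale(diam[mask], config)
    net.vessels["diameter"] = diam
    return net
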