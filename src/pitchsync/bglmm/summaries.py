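"""Posterior summary vocabulary: probability of direction (pd), evidence
ratio (ER), highest-density intervals (HDI), and the combined summary
record used throughout the reports.

* pd: the larger of the shares of posterior draws above / below zero
  (draws exactly at zero split evenly), between 0.5 and 1.
* ER = pd / (1 - pd); a pd of 0.975 corresponds to a two-sided p of 0.05.
* HDI: the shortest contiguous interval of sorted draws containing the
  requested probability mass (ties broken towards the lower interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SummaryStats", "pd_of_draws", "pd_to_p_and_er", "hdi", "summarize_draws"]


@dataclass(frozen=True)
class SummaryStats:
    median: float
    hdi66: tuple
    hdi90: tuple
    hdi95: tuple
    pd: float
    er: float

    def __post_init__(self):
        if not 0.5 - 1e-12 <= self.pd <= 1 + 1e-12:
            raise ValueError(f"pd out of range: {self.pd}")


def pd_of_draws(samples) -> float:
    """Probability of direction: max share of draws > 0 or < 0, with draws
    exactly at zero counted half to each side."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("pd of empty sample")
    share_pos = np.mean(x > 0) + 0.5 * np.mean(x == 0)
    return float(max(share_pos, 1.0 - share_pos))


def pd_to_p_and_er(pd: float) -> tuple:
    """Two-sided p-value analogue and evidence ratio of a pd.

    p = 2 (1 - pd); ER = pd / (1 - pd), with pd = 1 mapping to inf.
    """
    if not 0.5 <= pd <= 1.0:
        raise ValueError(f"pd must lie in [0.5, 1], got {pd}")
    p = 2.0 * (1.0 - pd)
    er = math.inf if pd == 1.0 else pd / (1.0 - pd)
    return p, er


def hdi(samples, mass: float) -> tuple:
    """Highest-density interval: the shortest window of ceil(mass * n)
    sorted draws.  mass = 1 returns (min, max)."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("hdi of empty sample")
    if not 0.0 < mass <= 1.0:
        raise ValueError(f"mass must lie in (0, 1], got {mass}")
    w = int(np.ceil(mass * n))
    if w < 2:
        raise ValueError(f"too few samples ({n}) for mass {mass}")
    if w >= n:
        return float(x[0]), float(x[-1])
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))  # argmin takes the first (lowest) window on ties
    return float(x[i]), float(x[i + w - 1])


def summarize_draws(samples) -> SummaryStats:
    x = np.asarray(samples, dtype=float).ravel()
    pd_val = pd_of_draws(x)
    _, er = pd_to_p_and_er(pd_val)
    return SummaryStats(
        median=float(np.median(x)),
        hdi66=hdi(x, 0.66),
        hdi90=hdi(x, 0.90),
        hdi95=hdi(x, 0.95),
        pd=pd_val,
        er=er,
    )
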