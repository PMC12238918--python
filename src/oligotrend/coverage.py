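"""Design-based cover estimation from unequal-probability survey plots.

The estimator is the ratio (Hájek) form of the Horvitz–Thompson
estimator, Σ(cover/π) / Σ(1/π), which targets mean cover; the pure HT
total is also available.  A centered 5-year moving average smooths the
annual series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoverPlotObs",
    "CoverEstimate",
    "ht_estimate",
    "ht_total",
    "annual_estimates",
    "moving_average",
]


@dataclass
class CoverPlotObs:
    """One plot-year cover observation with its inclusion probability."""

    site_id: str
    plot_id: str
    year: int
    cover_fraction: float
    inclusion_prob: float
    panel: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.cover_fraction <= 1.0:
            raise ValueError("cover_fraction must lie in [0, 1]")
        if not 0.0 < self.inclusion_prob <= 1.0:
            raise ValueError("inclusion_prob must lie in (0, 1]")


@dataclass
class CoverEstimate:
    year: int
    ht_estimate: float
    n_plots: int
    ma5: float | None = None


def ht_estimate(observations: list[CoverPlotObs]) -> CoverEstimate:
    """Ratio-form Horvitz–Thompson estimate of mean cover for one year."""
    if not observations:
        raise ValueError("need at least one observation")
    pis = np.array([o.inclusion_prob for o in observations])
    if np.any(pis <= 0):
        raise ValueError("inclusion probabilities must be positive")
    covers = np.array([o.cover_fraction for o in observations])
    w = 1.0 / pis
    est = float(np.sum(covers * w) / np.sum(w))
    year = observations[0].year
    return CoverEstimate(year=year, ht_estimate=est, n_plots=len(observations))


def ht_total(observations: list[CoverPlotObs]) -> float:
    """Pure Horvitz–Thompson total Σ(cover/π) (population-total scale)."""
    if not observations:
        raise ValueError("need at least one observation")
    return float(
        sum(o.cover_fraction / o.inclusion_prob for o in observations)
    )


def annual_estimates(observations: list[CoverPlotObs]) -> list[CoverEstimate]:
    """Per-year ratio-HT estimates with the 5-y moving average attached."""
    by_year: dict[int, list[CoverPlotObs]] = {}
    for o in observations:
        by_year.setdefault(o.year, []).append(o)
    estimates = [ht_estimate(obs) for _, obs in sorted(by_year.items())]
    ma = moving_average({e.year: e.ht_estimate for e in estimates}, window=5)
    for e in estimates:
        e.ma5 = ma[e.year]
    return estimates


def moving_average(
    series: dict[int, float], window: int = 5
) -> dict[int, float]:
    """Centered moving average over calendar years.

    The window shrinks at the series edges; missing years inside the
    window are skipped (the mean is over available years only).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    out = {}
    for year in sorted(series):
        vals = [
            series[y]
            for y in range(year - half, year + half + 1)
            if y in series
        ]
        out[year] = float(np.mean(vals))
    return out
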