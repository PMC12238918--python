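"""Plot-harvest nutrient densities and the NDVI_max → density calibration.

Densities are areal: (dry mass / plot area) × concentration, exploiting
1 g·m⁻² ≡ 1 ton·km⁻².  The calibration is an ordinary least-squares line
fitted at site level (mean of the plots per site) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "VegPlotSample",
    "CalibrationFit",
    "QCResult",
    "plot_density",
    "qc_filter",
    "fit_calibration",
    "predict_density",
]


@dataclass
class VegPlotSample:
    """One harvested vegetation plot (0.25 m² by default)."""

    site_id: str
    plot_id: str
    dry_mass: float           # g
    conc_p: float             # mg P per g dry mass
    conc_n: float             # mg N per g dry mass
    ndvimax: float
    plot_area: float = 0.25   # m²
    qc_snow: bool = False
    qc_incomplete_removal: bool = False

    def __post_init__(self) -> None:
        if self.dry_mass < 0:
            raise ValueError("dry_mass must be nonnegative")
        if self.conc_p < 0 or self.conc_n < 0:
            raise ValueError("concentrations must be nonnegative")
        if self.plot_area <= 0:
            raise ValueError("plot_area must be positive")

    @property
    def flagged(self) -> bool:
        return self.qc_snow or self.qc_incomplete_removal


@dataclass
class CalibrationFit:
    """Linear NDVI_max → areal nutrient density model."""

    nutrient: str             # "P" or "N"
    slope: float              # ton·km⁻² per NDVI unit
    intercept: float          # ton·km⁻²
    n_sites: int
    r2: float
    p_value: float
    residual_sd: float
    level: str = "site"


@dataclass
class QCResult:
    samples: list[VegPlotSample]
    n_removed_snow: int
    n_removed_incomplete: int
    n_sites_removed: int


def plot_density(sample: VegPlotSample, nutrient: str) -> float:
    """Areal nutrient density of one plot in ton·km⁻².

    density = (dry_mass [g] / area [m²]) × conc [mg/g] / 1000, and
    1 g·m⁻² ≡ 1 ton·km⁻², so the result is already in ton·km⁻².
    Flagged samples are refused — run :func:`qc_filter` first.
    """
    if sample.flagged:
        raise ValueError(
            f"sample {sample.site_id}/{sample.plot_id} carries a QC flag; "
            "filter before computing densities"
        )
    conc = _conc(sample, nutrient)
    return (sample.dry_mass / sample.plot_area) * conc / 1000.0


def _conc(sample: VegPlotSample, nutrient: str) -> float:
    nutrient = nutrient.upper()
    if nutrient == "P":
        return sample.conc_p
    if nutrient == "N":
        return sample.conc_n
    raise ValueError(f"unknown nutrient {nutrient!r}")


def qc_filter(
    samples: list[VegPlotSample],
    site_policy: str = "strict",
) -> QCResult:
    """Remove QC-flagged plots.

    ``site_policy='strict'`` (default) drops the whole site when any of
    its plots is flagged, so planting nine flags on nine distinct sites
    takes 38 sites down to 29.  ``site_policy='plots'`` drops only the
    flagged plots, then removes sites left with zero plots.
    """
    if site_policy not in ("strict", "plots"):
        raise ValueError("site_policy must be 'strict' or 'plots'")
    n_snow = sum(1 for s in samples if s.qc_snow)
    n_inc = sum(1 for s in samples if s.qc_incomplete_removal and not s.qc_snow)
    if site_policy == "strict":
        bad_sites = {s.site_id for s in samples if s.flagged}
        kept = [s for s in samples if s.site_id not in bad_sites]
        n_sites_removed = len(bad_sites)
    else:
        kept = [s for s in samples if not s.flagged]
        before = {s.site_id for s in samples}
        after = {s.site_id for s in kept}
        n_sites_removed = len(before - after)
    if samples and not kept:
        import warnings

        warnings.warn("qc_filter removed every sample", stacklevel=2)
    return QCResult(kept, n_snow, n_inc, n_sites_removed)


def fit_calibration(
    samples: list[VegPlotSample],
    nutrient: str,
    level: str = "site",
) -> CalibrationFit:
    """OLS of areal density on NDVI_max.

    ``level='site'`` (default) averages the plots of each site first,
    mirroring a site-scale scatter; ``level='plot'`` fits on raw plots.
    Requires ≥ 3 units and non-constant NDVI.
    """
    if any(s.flagged for s in samples):
        raise ValueError("flagged samples present; run qc_filter first")
    if level not in ("site", "plot"):
        raise ValueError("level must be 'site' or 'plot'")
    if level == "site":
        by_site: dict[str, list[VegPlotSample]] = {}
        for s in samples:
            by_site.setdefault(s.site_id, []).append(s)
        x = np.array(
            [np.mean([s.ndvimax for s in grp]) for grp in by_site.values()]
        )
        y = np.array(
            [
                np.mean([plot_density(s, nutrient) for s in grp])
                for grp in by_site.values()
            ]
        )
    else:
        x = np.array([s.ndvimax for s in samples])
        y = np.array([plot_density(s, nutrient) for s in samples])
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 {level}s to fit, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("singular design: NDVI_max is constant")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    resid = y - fitted
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return CalibrationFit(
        nutrient=nutrient.upper(),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_sites=n,
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        residual_sd=residual_sd,
        level=level,
    )


def predict_density(fit: CalibrationFit, ndvimax: float) -> float:
    """Predicted areal density, clamped at zero (no negative biomass)."""
    return max(0.0, fit.intercept + fit.slope * ndvimax)
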