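"""Seeded synthetic landscapes and observation products.

Generates everything the analysis consumes — a DEM with closed lake
depressions, dated NDVI scene stacks with a logistic greening ramp,
vegetation plot harvests with a planted linear NDVI→density truth, lake
chemistry log-linearly tied to catchment NDVI_max with lake random
intercepts, and rotating-panel cover surveys — so every downstream stage
is testable offline and every planted truth is recoverable.

Randomness: one root seed, one named child stream per product
(``_stream``), so adding a product never perturbs the draws of another.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from . import ndvi as ndvi_mod
from . import watershed as ws
from .calib import VegPlotSample
from .coverage import CoverPlotObs
from .ndvi import NDVIScene
from .raster import GridRaster
from .trends import ChemSample
from .watershed import LakeSite

__all__ = [
    "SynthConfig",
    "SynthBundle",
    "generate_dem",
    "generate_scenes",
    "generate_veg_plots",
    "generate_chem",
    "generate_cover_survey",
    "generate_bundle",
    "delineate_lakes",
    "content_hash",
]

# fixed spawn keys for named child streams — append-only
_STREAMS = {"dem": 0, "scenes": 1, "veg": 2, "chem": 3, "cover": 4}


@dataclass
class GreeningParams:
    ramp_center_year: float = 1995.0
    ramp_width_years: float = 3.0
    amplitude: float = 0.25

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")


@dataclass
class CalibTruth:
    slope_p: float = 2.2      # ton·km⁻² per NDVI unit
    intercept_p: float = -0.1  # ton·km⁻²
    slope_n: float = 24.0
    intercept_n: float = -1.0
    noise_sd_p: float = 0.12
    noise_sd_n: float = 1.2


@dataclass
class ChemLink:
    gamma_p: float = 2.0       # log-concentration decline per NDVI unit
    gamma_n: float = 1.5
    base_total_p: float = 12.0  # μg/L at NDVI_max = 0
    base_din: float = 60.0
    base_toc: float = 3.0
    lake_intercept_sd: float = 0.3
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.gamma_p < 0 or self.gamma_n < 0:
            raise ValueError("gamma values must be nonnegative")


@dataclass
class CoverTruth:
    year_start: int = 2003
    year_end: int = 2020
    cover_start: float = 0.15
    cover_end: float = 0.22
    n_sites: int = 59
    plots_per_site: int = 3
    n_panels: int = 5
    obs_binomial_m: int = 200  # observation noise: Binomial(m, p)/m


@dataclass
class SynthConfig:
    """Full parameterization of the synthetic landscape and products."""

    seed: int = 0
    grid_nrows: int = 48
    grid_ncols: int = 48
    cell_size: float = 100.0   # meters
    n_lakes: int = 3
    year_start: int = 1983
    year_end: int = 2020
    scenes_per_year: int = 12
    greening: GreeningParams = field(default_factory=GreeningParams)
    calib_truth: CalibTruth = field(default_factory=CalibTruth)
    chem_link: ChemLink = field(default_factory=ChemLink)
    cover_truth: CoverTruth = field(default_factory=CoverTruth)
    # DEM shape
    regional_slope: float = 0.01          # m per m, dipping to the south
    hill_amplitude: float = 12.0          # m
    n_hills: int = 10
    lake_depth: float = 10.0              # m
    lake_radius_cells: float = 2.5
    # scenes
    morning_scene_fraction: float = 0.15  # scenes stamped before 07:00
    snow_doy_margin: float = 45.0         # snow likely this far from midsummer bounds
    scene_noise_sd: float = 0.02
    base_ndvi_low: float = 0.22
    base_ndvi_high: float = 0.45
    # anomaly lake: delayed greening ramp (last lake), mirrors a
    # high-elevation site that greens late
    delayed_lake: bool = True
    delayed_ramp_shift_years: float = 15.0
    # veg plots
    n_veg_sites: int = 38
    plots_per_veg_site: int = 3
    veg_plot_area: float = 0.25
    n_flag_incomplete: int = 5
    n_flag_snow: int = 4
    veg_ndvi_low: float = 0.25
    veg_ndvi_high: float = 0.75
    snap_radius_m: float = 250.0

    def __post_init__(self) -> None:
        if self.scenes_per_year < 1:
            raise ValueError("scenes_per_year must be >= 1")
        if self.year_end < self.year_start:
            raise ValueError("year range must be non-empty")
        if self.grid_nrows < 8 or self.grid_ncols < 8:
            raise ValueError("grid must be at least 8x8")
        if not 0.0 <= self.morning_scene_fraction <= 1.0:
            raise ValueError("morning_scene_fraction must lie in [0, 1]")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


@dataclass
class SynthBundle:
    """Everything the pipeline consumes, generated from one config."""

    config: SynthConfig
    dem: GridRaster
    lakes: list[LakeSite]
    scenes: list[NDVIScene]
    annual_ndvimax: dict[str, dict[int, float]]
    veg_plots: list[VegPlotSample]
    chem: list[ChemSample]
    cover_survey: list[CoverPlotObs]


def _stream(cfg: SynthConfig, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(_STREAMS[name],))
    )


# ---------------------------------------------------------------------------
# DEM and lakes


def generate_dem(cfg: SynthConfig, max_retries: int = 25) -> GridRaster:
    """Smooth terrain with ``n_lakes`` closed depressions.

    A regional slope plus Gaussian hills, carved by Gaussian pits at
    well-separated interior locations.  Each pit is verified to be a
    closed depression (depression filling raises it); generation retries
    with fresh placements and fails explicitly if that cannot be achieved.
    """
    rng = _stream(cfg, "dem")
    nr, nc, cs = cfg.grid_nrows, cfg.grid_ncols, cfg.cell_size
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")

    for _ in range(max_retries):
        z = cfg.regional_slope * cs * rows.astype(float)  # dips south
        for _ in range(cfg.n_hills):
            cr, cc = rng.uniform(0, nr), rng.uniform(0, nc)
            amp = rng.uniform(0.3, 1.0) * cfg.hill_amplitude
            sig = rng.uniform(3.0, 8.0)
            z += amp * np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * sig**2))
        centers = _separated_points(rng, cfg.n_lakes, nr, nc, margin=4,
                                    min_sep=4 * cfg.lake_radius_cells)
        if centers is None:
            continue
        for cr, cc in centers:
            z -= cfg.lake_depth * np.exp(
                -((rows - cr) ** 2 + (cols - cc) ** 2)
                / (2 * cfg.lake_radius_cells**2)
            )
        dem = GridRaster(values=z, cell_size=cs)
        filled = ws.fill_depressions(dem)
        raised = filled.values - dem.values > 1e-6
        if all(raised[cr, cc] for cr, cc in centers):
            return dem
    raise RuntimeError(
        f"could not place {cfg.n_lakes} closed depressions in "
        f"{max_retries} attempts; enlarge the grid or reduce n_lakes"
    )


def _separated_points(
    rng: np.random.Generator,
    n: int,
    nrows: int,
    ncols: int,
    margin: int,
    min_sep: float,
) -> list[tuple[int, int]] | None:
    points: list[tuple[int, int]] = []
    if n == 0:
        return points
    if margin >= nrows - margin or margin >= ncols - margin:
        return None
    for _ in range(200):
        r = int(rng.integers(margin, nrows - margin))
        c = int(rng.integers(margin, ncols - margin))
        if all(np.hypot(r - pr, c - pc) >= min_sep for pr, pc in points):
            points.append((r, c))
            if len(points) == n:
                return points
    return None


def delineate_lakes(cfg: SynthConfig, dem: GridRaster) -> list[LakeSite]:
    """Full watershed pipeline on the synthetic DEM.

    Lake masks are the flooded depression interiors (cells raised by
    filling); the outlet is snapped from the deepest lake cell to the
    local flow-accumulation maximum, and each catchment is delineated
    upstream of that outlet.
    """
    filled = ws.fill_depressions(dem)
    flow = ws.compute_d8(filled)
    accum = ws.flow_accumulation(flow)
    ponded = filled.values - dem.values > 1e-6
    labels, n_comp = ndimage.label(ponded, structure=np.ones((3, 3)))
    if n_comp < cfg.n_lakes:
        raise RuntimeError(
            f"expected {cfg.n_lakes} flooded depressions, found {n_comp}"
        )
    # keep the n_lakes largest components, ordered by (row, col) of their pit
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
    keep = np.argsort(sizes)[::-1][: cfg.n_lakes] + 1
    sites: list[LakeSite] = []
    for i, lab in enumerate(sorted(keep, key=lambda L: _pit_of(dem, labels, L))):
        lake_mask = labels == lab
        acc_in_lake = np.where(lake_mask, accum.values, -1.0)
        out_r, out_c = np.unravel_index(np.argmax(acc_in_lake), acc_in_lake.shape)
        outlet_xy = dem.cell_center(int(out_r), int(out_c))
        snapped = ws.snap_outlet(outlet_xy, accum, radius=cfg.snap_radius_m)
        catchment = ws.delineate(flow, snapped)
        catchment |= lake_mask  # the flooded interior drains to the outlet
        catch_km2, lake_km2, drain_km2 = ws.areas(
            catchment, lake_mask, dem.cell_size
        )
        sites.append(
            LakeSite(
                id=f"lake_{i}",
                name=f"Synthetic lake {i}",
                outlet_xy=outlet_xy,
                lake_mask=dem.like(lake_mask.astype(float), nodata=-1.0),
                catchment_mask=dem.like(catchment.astype(float), nodata=-1.0),
                catchment_km2=catch_km2,
                lake_km2=lake_km2,
                drainage_km2=drain_km2,
            )
        )
    return sites


def _pit_of(dem: GridRaster, labels: np.ndarray, lab: int) -> tuple[int, int]:
    vals = np.where(labels == lab, dem.values, np.inf)
    r, c = np.unravel_index(np.argmin(vals), vals.shape)
    return int(r), int(c)


# ---------------------------------------------------------------------------
# NDVI scenes


def _logistic(u: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(u, dtype=float)))


def _season(doy: np.ndarray | float) -> np.ndarray | float:
    """Seasonal greenness factor, ≈ 1 at midsummer (doy 200)."""
    return np.exp(-(((np.asarray(doy, dtype=float) - 200.0) / 80.0) ** 2))


def generate_scenes(
    cfg: SynthConfig, dem: GridRaster, lakes: list[LakeSite]
) -> list[NDVIScene]:
    """Dated NDVI stack with the planted greening ramp.

    Per pixel and date, NDVI = clamp(season(doy)·(base + ramp(year)) + ε),
    where ramp = amplitude·logistic((year − center)/width).  Early/late
    scenes can be snow-covered (NDVI pushed below 0.2), a configured
    fraction of scenes is stamped before 07:00, and lake pixels carry
    water-like negative NDVI.  The last lake's catchment region can green
    on a delayed ramp (``cfg.delayed_lake``).
    """
    rng = _stream(cfg, "scenes")
    nr, nc = dem.shape
    base = rng.uniform(cfg.base_ndvi_low, cfg.base_ndvi_high, size=(nr, nc))
    base = ndimage.uniform_filter(base, size=3, mode="nearest")
    base = np.clip(base, cfg.base_ndvi_low, cfg.base_ndvi_high)

    water = np.zeros((nr, nc), dtype=bool)
    for lk in lakes:
        water |= lk.lake_mask.values > 0.5

    delayed_region = np.zeros((nr, nc), dtype=bool)
    if cfg.delayed_lake and lakes:
        cm = lakes[-1].catchment_mask
        if cm is not None:
            delayed_region = cm.values > 0.5

    g = cfg.greening
    doys = np.linspace(90, 300, cfg.scenes_per_year).round().astype(int)
    scenes: list[NDVIScene] = []
    for year in cfg.years:
        ramp = g.amplitude * _logistic(
            (year - g.ramp_center_year) / g.ramp_width_years
        )
        ramp_delayed = g.amplitude * _logistic(
            (year - g.ramp_center_year - cfg.delayed_ramp_shift_years)
            / g.ramp_width_years
        )
        green = np.where(delayed_region, base + ramp_delayed, base + ramp)
        for doy in doys:
            season = _season(doy)
            values = season * green + rng.normal(0, cfg.scene_noise_sd, (nr, nc))
            # snow probability rises toward the season edges
            dist_from_summer = abs(doy - 200)
            p_snow = _logistic((dist_from_summer - (110 - cfg.snow_doy_margin)) / 10.0)
            if rng.random() < p_snow:
                values = rng.uniform(0.0, 0.15, (nr, nc))
            values[water] = -0.1 + rng.normal(0, 0.02, int(water.sum()))
            hour = 6.0 if rng.random() < cfg.morning_scene_fraction else 10.5
            scenes.append(
                NDVIScene(
                    grid=dem.like(np.clip(values, -1.0, 1.0), nodata=-9999.0),
                    year=int(year),
                    doy=int(doy),
                    acquisition_hour=hour,
                )
            )
    return scenes


def annual_drainage_ndvimax(
    cfg: SynthConfig, scenes: list[NDVIScene], lakes: list[LakeSite]
) -> dict[str, dict[int, float]]:
    """Per-lake annual NDVI_max series via the catchment extraction rules."""
    out: dict[str, dict[int, float]] = {}
    by_year: dict[int, list[NDVIScene]] = {}
    for s in scenes:
        by_year.setdefault(s.year, []).append(s)
    for lk in lakes:
        drainage = (lk.catchment_mask.values > 0.5) & ~(lk.lake_mask.values > 0.5)
        series: dict[int, float] = {}
        for year in sorted(by_year):
            rec = ndvi_mod.catchment_ndvimax(
                by_year[year], drainage, unit_id=lk.id, year=year
            )
            if rec.value is not None:
                series[year] = rec.value
        out[lk.id] = series
    return out


# ---------------------------------------------------------------------------
# vegetation plots


def generate_veg_plots(
    cfg: SynthConfig, scenes: list[NDVIScene] | None = None
) -> list[VegPlotSample]:
    """Plot harvests with the planted linear NDVI→density truth.

    Site NDVI_max values are drawn uniformly over the configured range (or
    extracted from the supplied scene stack via the plot mean-then-max
    rule when ``scenes`` is given).  Dry mass and concentrations are
    back-calculated so that (dry_mass/area)·conc reproduces the planted
    density plus Gaussian noise; negative densities are resampled.  QC
    flags are planted on distinct sites.
    """
    ct = cfg.calib_truth
    if ct.slope_p <= 0 or ct.slope_n <= 0:
        raise ValueError("calibration truth slopes must be positive")
    rng = _stream(cfg, "veg")
    n_sites = cfg.n_veg_sites

    if scenes is None:
        site_ndvi = rng.uniform(cfg.veg_ndvi_low, cfg.veg_ndvi_high, n_sites)
    else:
        site_ndvi = _site_ndvi_from_scenes(cfg, scenes, rng, n_sites)

    samples: list[VegPlotSample] = []
    for i in range(n_sites):
        nd = float(site_ndvi[i])
        dens_p_true = ct.intercept_p + ct.slope_p * nd
        dens_n_true = ct.intercept_n + ct.slope_n * nd
        for j in range(cfg.plots_per_veg_site):
            dens_p = _positive_noise(rng, dens_p_true, ct.noise_sd_p)
            dens_n = _positive_noise(rng, dens_n_true, ct.noise_sd_n)
            conc_p = float(np.clip(rng.normal(1.3, 0.15), 0.5, 3.0))  # mg/g
            dry_mass = dens_p * 1000.0 * cfg.veg_plot_area / conc_p
            conc_n = dens_n * 1000.0 * cfg.veg_plot_area / dry_mass
            samples.append(
                VegPlotSample(
                    site_id=f"site_{i:02d}",
                    plot_id=f"site_{i:02d}_p{j}",
                    dry_mass=dry_mass,
                    conc_p=conc_p,
                    conc_n=conc_n,
                    ndvimax=nd,
                    plot_area=cfg.veg_plot_area,
                )
            )
    _plant_qc_flags(cfg, rng, samples)
    return samples


def _positive_noise(
    rng: np.random.Generator, truth: float, sd: float, retries: int = 50
) -> float:
    if sd == 0:
        if truth < 0:
            raise ValueError(f"planted density {truth} negative with zero noise")
        return truth
    for _ in range(retries):
        v = truth + rng.normal(0, sd)
        if v > 0:
            return float(v)
    raise RuntimeError(
        f"could not draw a positive density around {truth} (sd {sd}) "
        f"in {retries} tries"
    )


def _site_ndvi_from_scenes(
    cfg: SynthConfig,
    scenes: list[NDVIScene],
    rng: np.random.Generator,
    n_sites: int,
) -> np.ndarray:
    last_year = max(s.year for s in scenes)
    stack = [s for s in scenes if s.year == last_year]
    nr, nc = stack[0].grid.shape
    land = np.ones((nr, nc), dtype=bool)
    # avoid water by rejecting pixels that never exceed the snow screen
    pixel_max = np.max(np.stack([s.grid.values for s in stack]), axis=0)
    land &= pixel_max > ndvi_mod.NDVI_SNOW_THRESHOLD
    choices = np.argwhere(land)
    idx = rng.choice(len(choices), size=n_sites, replace=False)
    out = np.empty(n_sites)
    for k, (r, c) in enumerate(choices[idx]):
        footprint = np.zeros((nr, nc), dtype=bool)
        footprint[r, c] = True
        rec = ndvi_mod.plot_ndvimax(stack, footprint)
        out[k] = rec.value
    return out


def _plant_qc_flags(
    cfg: SynthConfig, rng: np.random.Generator, samples: list[VegPlotSample]
) -> None:
    n_flags = cfg.n_flag_incomplete + cfg.n_flag_snow
    site_ids = sorted({s.site_id for s in samples})
    if n_flags > len(site_ids):
        raise ValueError("more QC flags than sites")
    flagged_sites = rng.choice(site_ids, size=n_flags, replace=False)
    by_site: dict[str, list[VegPlotSample]] = {}
    for s in samples:
        by_site.setdefault(s.site_id, []).append(s)
    for k, site in enumerate(flagged_sites):
        plot = by_site[site][int(rng.integers(len(by_site[site])))]
        if k < cfg.n_flag_incomplete:
            plot.qc_incomplete_removal = True
        else:
            plot.qc_snow = True


# ---------------------------------------------------------------------------
# chemistry


def generate_chem(
    cfg: SynthConfig, annual_ndvimax_by_lake: dict[str, dict[int, float]]
) -> list[ChemSample]:
    """Lake chemistry log-linearly tied to the NDVI_max series.

    log C = α_lake − γ·NDVI_max(lake, year) + ε per sampling occasion,
    with α_lake drawn once per lake (sd ``lake_intercept_sd``) and 3–4
    occasions per year.
    """
    link = cfg.chem_link
    rng = _stream(cfg, "chem")
    samples: list[ChemSample] = []
    for lake_id in sorted(annual_ndvimax_by_lake):
        series = annual_ndvimax_by_lake[lake_id]
        a_p = np.log(link.base_total_p) + rng.normal(0, link.lake_intercept_sd)
        a_n = np.log(link.base_din) + rng.normal(0, link.lake_intercept_sd)
        a_t = np.log(link.base_toc) + rng.normal(0, link.lake_intercept_sd)
        for year in sorted(series):
            nd = series[year]
            n_dates = int(rng.integers(3, 5))  # 3 or 4 occasions
            doys = np.sort(rng.choice(np.arange(60, 330), n_dates, replace=False))
            for doy in doys:
                tp = np.exp(a_p - link.gamma_p * nd + rng.normal(0, link.noise_sd))
                din = np.exp(a_n - link.gamma_n * nd + rng.normal(0, link.noise_sd))
                toc = np.exp(a_t + rng.normal(0, link.noise_sd))
                samples.append(
                    ChemSample(
                        lake_id=lake_id,
                        year=int(year),
                        doy=int(doy),
                        total_p=float(tp),
                        din=float(din),
                        toc=float(toc),
                    )
                )
    return samples


# ---------------------------------------------------------------------------
# cover survey


def generate_cover_survey(cfg: SynthConfig) -> list[CoverPlotObs]:
    """Rotating-panel cover survey with a planted linear trend.

    Sites split into five panels, one panel observed per year; each
    plot-year carries its inclusion probability (correlated with the site
    effect, so inverse-probability weighting matters) and binomial
    observation noise around the site's true cover.
    """
    tr = cfg.cover_truth
    rng = _stream(cfg, "cover")
    site_effect = rng.normal(0, 0.02, tr.n_sites)
    # oversample greener sites: π increases with the site effect
    pis = np.clip(0.6 + 8.0 * site_effect, 0.2, 1.0)
    panels = np.arange(tr.n_sites) % tr.n_panels
    span = tr.year_end - tr.year_start
    obs: list[CoverPlotObs] = []
    for year in range(tr.year_start, tr.year_end + 1):
        frac = (year - tr.year_start) / span if span else 0.0
        base = tr.cover_start + (tr.cover_end - tr.cover_start) * frac
        panel = (year - tr.year_start) % tr.n_panels
        for i in np.where(panels == panel)[0]:
            if rng.random() >= pis[i]:
                continue  # site not drawn into this year's sample
            p_true = float(np.clip(base + site_effect[i], 0.0, 1.0))
            for j in range(tr.plots_per_site):
                noisy = rng.binomial(tr.obs_binomial_m, p_true) / tr.obs_binomial_m
                obs.append(
                    CoverPlotObs(
                        site_id=f"cov_{i:03d}",
                        plot_id=f"cov_{i:03d}_p{j}",
                        year=int(year),
                        cover_fraction=float(noisy),
                        inclusion_prob=float(pis[i]),
                        panel=int(panel + 1),
                    )
                )
    return obs


def cover_truth_series(cfg: SynthConfig) -> dict[int, float]:
    """The planted population-mean cover per year (no noise, no design)."""
    tr = cfg.cover_truth
    span = tr.year_end - tr.year_start
    return {
        y: tr.cover_start
        + (tr.cover_end - tr.cover_start) * ((y - tr.year_start) / span if span else 0.0)
        for y in range(tr.year_start, tr.year_end + 1)
    }


# ---------------------------------------------------------------------------
# bundle


def generate_bundle(cfg: SynthConfig) -> SynthBundle:
    """Generate every product from one config, deterministically."""
    dem = generate_dem(cfg)
    lakes = delineate_lakes(cfg, dem)
    scenes = generate_scenes(cfg, dem, lakes)
    annual = annual_drainage_ndvimax(cfg, scenes, lakes)
    veg = generate_veg_plots(cfg)
    chem = generate_chem(cfg, annual)
    cover = generate_cover_survey(cfg)
    return SynthBundle(
        config=cfg,
        dem=dem,
        lakes=lakes,
        scenes=scenes,
        annual_ndvimax=annual,
        veg_plots=veg,
        chem=chem,
        cover_survey=cover,
    )


def content_hash(bundle: SynthBundle) -> str:
    """SHA-256 digest of every array and record in the bundle."""
    h = hashlib.sha256()
    h.update(json.dumps(asdict(bundle.config), sort_keys=True, default=str).encode())
    h.update(np.ascontiguousarray(bundle.dem.values).tobytes())
    for lk in bundle.lakes:
        h.update(lk.id.encode())
        h.update(np.ascontiguousarray(lk.lake_mask.values).tobytes())
        h.update(np.ascontiguousarray(lk.catchment_mask.values).tobytes())
        h.update(np.float64(lk.drainage_km2).tobytes())
    for s in bundle.scenes:
        h.update(np.int64([s.year, s.doy]).tobytes())
        h.update(np.float64(s.acquisition_hour).tobytes())
        h.update(np.ascontiguousarray(s.grid.values).tobytes())
    for lake_id, series in sorted(bundle.annual_ndvimax.items()):
        h.update(lake_id.encode())
        h.update(json.dumps(sorted(series.items())).encode())
    for v in bundle.veg_plots:
        h.update(
            f"{v.site_id},{v.plot_id},{v.dry_mass!r},{v.conc_p!r},{v.conc_n!r},"
            f"{v.ndvimax!r},{v.qc_snow},{v.qc_incomplete_removal}".encode()
        )
    for c in bundle.chem:
        h.update(
            f"{c.lake_id},{c.year},{c.doy},{c.total_p!r},{c.din!r},{c.toc!r}".encode()
        )
    for o in bundle.cover_survey:
        h.update(
            f"{o.site_id},{o.plot_id},{o.year},{o.cover_fraction!r},"
            f"{o.inclusion_prob!r},{o.panel}".encode()
        )
    return h.hexdigest()
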