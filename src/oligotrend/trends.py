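"""Trend statistics for lake chemistry series.

Contains annual aggregation, the Mann–Kendall test with tie-corrected
variance and continuity correction, Sen's slope, the percent-per-year
decline convention, and a penalized-spline smooth with per-lake random
intercepts fitted by backfitting (a light-weight stand-in for a Gaussian
additive mixed model).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

__all__ = [
    "ChemSample",
    "TrendResult",
    "MixedSmoothFit",
    "annual_mean",
    "annual_means",
    "mann_kendall",
    "mann_kendall_exact_p",
    "sen_slope",
    "percent_decline",
    "fit_mixed_smooth",
]


@dataclass
class ChemSample:
    """One water-chemistry sampling occasion for a lake.

    ``din`` is dissolved inorganic nitrogen, the sum of NO₂-N, NO₃-N and
    NH₄-N (μg/L); ``total_p`` in μg/L; ``toc`` in mg/L.
    """

    lake_id: str
    year: int
    doy: int
    total_p: float
    din: float
    toc: float = 0.0

    def __post_init__(self) -> None:
        if self.total_p < 0 or self.din < 0 or self.toc < 0:
            raise ValueError("concentrations must be nonnegative")

    def value(self, response: str) -> float:
        return {"total_p": self.total_p, "din": self.din, "toc": self.toc}[response]


@dataclass
class TrendResult:
    series_id: str
    n: int
    s: int
    var_s: float
    z: float
    p_two_sided: float
    kendall_tau: float
    sen_slope: float | None
    sen_intercept: float | None


@dataclass
class MixedSmoothFit:
    """Penalized-spline smooth plus per-lake random intercepts."""

    response: str
    predictor: str
    basis_dim: int
    smoothing_parameter: float
    coefficients: np.ndarray
    knots: np.ndarray
    degree: int
    random_intercepts: dict[str, float]
    fitted: np.ndarray
    deviance_explained: float
    n_iter: int

    def predict_smooth(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the smooth (without lake intercepts) at new x, clamped
        to the fitted range."""
        x = np.clip(np.asarray(x, dtype=float), self.knots[self.degree],
                    self.knots[-self.degree - 1])
        design = BSpline.design_matrix(
            x, self.knots, self.degree, extrapolate=False
        ).toarray()
        return design @ self.coefficients


def annual_mean(samples: list[ChemSample], response: str = "total_p") -> float:
    """Arithmetic mean of within-year sampling occasions."""
    if not samples:
        raise ValueError("need at least one sample")
    return float(np.mean([s.value(response) for s in samples]))


def annual_means(
    samples: list[ChemSample], response: str = "total_p"
) -> dict[str, dict[int, float]]:
    """Per-lake, per-year mean series from a flat sample list."""
    grouped: dict[str, dict[int, list[float]]] = {}
    for s in samples:
        grouped.setdefault(s.lake_id, {}).setdefault(s.year, []).append(
            s.value(response)
        )
    return {
        lake: {year: float(np.mean(vals)) for year, vals in sorted(by_year.items())}
        for lake, by_year in grouped.items()
    }


def _mk_s_and_var(x: np.ndarray) -> tuple[int, float]:
    n = len(x)
    s = 0
    for i in range(n - 1):
        s += int(np.sign(x[i + 1:] - x[i]).sum())
    # tie-corrected variance
    _, counts = np.unique(x, return_counts=True)
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in counts if t > 1)
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    return s, var_s


def mann_kendall(
    series: dict[int, float] | list[tuple[int, float]],
    series_id: str = "",
) -> TrendResult:
    """Mann–Kendall trend test with Sen's slope.

    Uses the normal approximation with continuity correction,
    z = (S ∓ 1)/√var_S (0 when S = 0), tie-corrected variance, and
    tau-b for the reported correlation.  Requires ≥ 4 points; an
    all-tied series yields S = 0, p = 1.
    """
    t, x = _as_series(series)
    n = len(x)
    if n < 4:
        raise ValueError(f"Mann-Kendall requires n >= 4, got {n}")
    s, var_s = _mk_s_and_var(x)
    if var_s <= 0:
        z, p = 0.0, 1.0
    elif s > 0:
        z = (s - 1) / np.sqrt(var_s)
        p = 2.0 * stats.norm.sf(abs(z))
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        z, p = 0.0, 1.0
    # tau-b: tie-adjusted denominator
    n0 = n * (n - 1) / 2
    _, counts = np.unique(x, return_counts=True)
    n_ties = sum(c * (c - 1) / 2 for c in counts)
    denom = np.sqrt(n0 * (n0 - n_ties)) if n0 > n_ties else 0.0
    tau = s / denom if denom > 0 else 0.0
    try:
        slope, intercept = sen_slope(list(zip(t, x)))
    except ValueError:
        slope, intercept = None, None
    return TrendResult(
        series_id=series_id,
        n=n,
        s=s,
        var_s=var_s,
        z=float(z),
        p_two_sided=float(min(1.0, p)),
        kendall_tau=float(tau),
        sen_slope=slope,
        sen_intercept=intercept,
    )


def mann_kendall_exact_p(series: dict[int, float] | list[tuple[int, float]]) -> float:
    """Exact two-sided permutation p-value for the MK S statistic.

    Enumerates all orderings; only feasible for n ≤ 10.  Serves as an
    independent oracle for the normal approximation.
    """
    _, x = _as_series(series)
    n = len(x)
    if n > 10:
        raise ValueError("exact enumeration limited to n <= 10")
    s_obs, _ = _mk_s_and_var(x)
    count = 0
    total = 0
    for perm in itertools.permutations(x):
        s_perm, _ = _mk_s_and_var(np.array(perm))
        if abs(s_perm) >= abs(s_obs):
            count += 1
        total += 1
    return count / total


def sen_slope(
    series: dict[int, float] | list[tuple[int, float]],
) -> tuple[float, float]:
    """Median-of-pairwise-slopes trend estimate.

    Pairs with duplicate timestamps are excluded; intercept is
    median(x − slope·t).
    """
    t, x = _as_series(series)
    if len(x) < 2:
        raise ValueError("Sen's slope requires n >= 2")
    slopes = [
        (x[j] - x[i]) / (t[j] - t[i])
        for i in range(len(x) - 1)
        for j in range(i + 1, len(x))
        if t[j] != t[i]
    ]
    if not slopes:
        raise ValueError("all timestamps duplicate; slope undefined")
    slope = float(np.median(slopes))
    intercept = float(np.median(x - slope * t))
    return slope, intercept


def percent_decline(
    c_start: float, c_end: float, year_start: int, year_end: int
) -> float:
    """Mean annual percent decline between two endpoint concentrations.

    Uses the inclusive-year denominator (year_end − year_start + 1):
    100 × (c_start − c_end) / c_start / (span + 1).
    """
    if c_start <= 0:
        raise ValueError("c_start must be positive")
    if year_end <= year_start:
        raise ValueError("year_end must exceed year_start")
    n_years = year_end - year_start + 1
    return 100.0 * (c_start - c_end) / c_start / n_years


def _as_series(
    series: dict[int, float] | list[tuple[int, float]],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, dict):
        items = sorted(series.items())
    else:
        items = sorted(series)
    t = np.array([float(k) for k, _ in items])
    x = np.array([float(v) for _, v in items])
    keep = np.isfinite(x)
    return t[keep], x[keep]


# ---------------------------------------------------------------------------
# penalized-spline mixed smooth


def _spline_basis(
    x: np.ndarray, basis_dim: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """B-spline design matrix with ``basis_dim`` functions.

    Degree is cubic when the dimension allows, lower otherwise (dimension
    2 gives hat functions spanning exactly the linear polynomials, so the
    model collapses to an OLS line).
    """
    degree = min(3, basis_dim - 1)
    n_interior = basis_dim - degree - 1
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        hi = lo + 1.0
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)]
    )
    design = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    return design, knots, degree


def _second_diff_penalty(k: int) -> np.ndarray:
    if k < 3:
        return np.zeros((k, k))
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


def fit_mixed_smooth(
    x: np.ndarray,
    y: np.ndarray,
    lakes: np.ndarray,
    basis_dim: int = 10,
    lambda_grid: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    response: str = "y",
    predictor: str = "x",
) -> MixedSmoothFit:
    """Penalized cubic regression spline in ``x`` plus per-lake random
    intercepts, fitted by iterated backfitting.

    Alternates (i) penalized least squares for the smooth given the
    intercepts, with the smoothing parameter chosen by generalized
    cross-validation on ``lambda_grid``, and (ii) shrinkage-weighted lake
    means of the residuals for the intercepts, with the shrinkage ratio
    re-estimated from within/between-lake variance each pass.  Intercepts
    are centered to sum ≈ 0; the overall level lives in the smooth.
    Deviance explained is 1 − RSS/TSS for the Gaussian fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lakes = np.asarray(lakes)
    n = len(y)
    if len(x) != n or len(lakes) != n:
        raise ValueError("x, y and lakes must share length")
    lake_ids = np.unique(lakes)
    if len(lake_ids) < 2:
        if basis_dim > 2 or n < 10:
            raise ValueError("need >= 2 lakes and >= 10 points")
    elif n < 10:
        raise ValueError("need >= 10 points")
    if lambda_grid is None:
        lambda_grid = np.logspace(-5, 7, 25)

    design, knots, degree = _spline_basis(x, basis_dim)
    penalty = _second_diff_penalty(design.shape[1])
    bt = design.T

    b = {lid: 0.0 for lid in lake_ids}
    lake_index = {lid: np.where(lakes == lid)[0] for lid in lake_ids}
    coef = np.zeros(design.shape[1])
    lam = float(lambda_grid[0])
    prev_fit = np.zeros(n)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        offsets = np.zeros(n)
        for lid, idx in lake_index.items():
            offsets[idx] = b[lid]
        target = y - offsets

        # GCV over the grid for the smooth
        best = None
        btb = bt @ design
        bty = bt @ target
        for lam_try in lambda_grid:
            a = btb + lam_try * penalty
            try:
                coef_try = np.linalg.solve(a, bty)
            except np.linalg.LinAlgError:
                continue
            fit_try = design @ coef_try
            rss = float(np.sum((target - fit_try) ** 2))
            edf = float(np.trace(np.linalg.solve(a, btb)))
            denom = max(n - edf, 1e-10)
            gcv = n * rss / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam_try, coef_try, fit_try)
        if best is None:
            raise np.linalg.LinAlgError("smooth fit failed on the whole grid")
        _, lam, coef, smooth_fit = best

        # shrinkage-weighted lake means of residuals
        resid = y - smooth_fit
        lake_means = np.array([resid[lake_index[lid]].mean() for lid in lake_ids])
        within = np.concatenate(
            [resid[lake_index[lid]] - m for lid, m in zip(lake_ids, lake_means)]
        )
        sigma2 = float(np.mean(within**2)) if len(within) else 0.0
        tau2 = max(float(np.var(lake_means)), 1e-12)
        kappa = sigma2 / tau2
        new_b = {}
        for lid, m in zip(lake_ids, lake_means):
            n_l = len(lake_index[lid])
            new_b[lid] = n_l * m / (n_l + kappa)
        center = float(np.mean(list(new_b.values())))
        new_b = {lid: v - center for lid, v in new_b.items()}
        b = new_b

        offsets = np.zeros(n)
        for lid, idx in lake_index.items():
            offsets[idx] = b[lid]
        fitted = smooth_fit + offsets
        denom = np.sum(prev_fit**2)
        change = np.sum((fitted - prev_fit) ** 2) / (denom + 1e-300)
        prev_fit = fitted
        if n_iter > 1 and change < tol:
            break
    else:
        raise RuntimeError(
            f"mixed smooth did not converge in {max_iter} iterations "
            f"(last relative change {change:.3e})"
        )

    rss = float(np.sum((y - prev_fit) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    dev_expl = 1.0 - rss / tss if tss > 0 else 1.0
    return MixedSmoothFit(
        response=response,
        predictor=predictor,
        basis_dim=basis_dim,
        smoothing_parameter=float(lam),
        coefficients=coef,
        knots=knots,
        degree=degree,
        random_intercepts={str(k): float(v) for k, v in b.items()},
        fitted=prev_fit,
        deviance_explained=float(dev_expl),
        n_iter=n_iter,
    )
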