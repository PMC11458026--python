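"""Variography and optimal-grid-size selection.

The analysis grid's cell side length is chosen from the spatial covariance
structure of the data: for each taxon a semivariogram is estimated and
fitted, and candidate cell sizes v are scored by an information content

    f(v) = PN(v) · PS(v),

where PN(v) = 1 − 1/n̄(v) is the proportion of (undesirable) nugget variance
removed by averaging the expected n̄(v) stations falling in a v×v cell, and
PS(v) = 1 − γ̄_struct(v)/c1 is the proportion of spatially structured (sill)
variance retained after block-averaging over the cell.  Small cells remove
no nugget noise; large cells smooth away the spatial signal; the optimum
Lopt maximizes the product.  A consensus over taxa is the median of the
per-taxon optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "VariogramModel",
    "EmpiricalVariogram",
    "InformationCurve",
    "ConsensusLopt",
    "detrend",
    "empirical_variogram",
    "fit_variogram",
    "block_mean_structured_variogram",
    "information_curve",
    "consensus_lopt",
]


def _gamma_struct(h: np.ndarray, family: str, c1: float, a: float) -> np.ndarray:
    """Structured (nugget-free) semivariance at lag h."""
    h = np.asarray(h, dtype=float)
    if family == "spherical":
        r = np.clip(h / a, 0.0, 1.0)
        return c1 * (1.5 * r - 0.5 * r**3)
    if family == "exponential":
        # practical-range parameterization: gamma reaches 0.95*c1 at h = a
        return c1 * (1.0 - np.exp(-3.0 * h / a))
    raise ValueError(f"unknown variogram family {family!r}")


@dataclass
class VariogramModel:
    """Fitted semivariogram: nugget c0, partial sill c1, range a (km)."""

    family: str
    nugget: float
    partial_sill: float
    range_km: float
    trend_order: int = 0

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_km <= 0:
            raise ValueError("require c0 >= 0, c1 >= 0, a > 0")
        if self.family not in ("spherical", "exponential"):
            raise ValueError(f"unknown variogram family {self.family!r}")

    def gamma_struct(self, h) -> np.ndarray:
        return _gamma_struct(h, self.family, self.partial_sill, self.range_km)

    def gamma(self, h) -> np.ndarray:
        """Total semivariance: 0 at h=0, c0 + structured part for h > 0."""
        h = np.asarray(h, dtype=float)
        out = self.nugget + self.gamma_struct(h)
        return np.where(h > 0, out, 0.0)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


@dataclass
class EmpiricalVariogram:
    lag_center: np.ndarray
    gamma_hat: np.ndarray
    n_pairs: np.ndarray
    trend_order: int = 0


def _design_matrix(points: np.ndarray, order: int) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    cols = [np.ones_like(x)]
    if order >= 1:
        cols += [x, y]
    if order >= 2:
        cols += [x * y, x**2, y**2]
    return np.column_stack(cols)


def detrend(points: np.ndarray, values: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Remove a polynomial spatial trend by OLS.

    order 0 returns the values unchanged (zero trend); order 1 fits a plane,
    order 2 the full quadratic in (x, y).  Returns (residuals, coefficients).
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if order == 0:
        return values.copy(), np.zeros(0)
    X = _design_matrix(points, order)
    if len(values) < X.shape[1]:
        raise ValueError("fewer points than trend terms")
    coef, _, rank, _ = np.linalg.lstsq(X, values, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient trend design (collinear stations)")
    return values - X @ coef, coef


def select_trend_order(points: np.ndarray, values: np.ndarray) -> int:
    """Pick the trend order (0/1/2) with the lowest OLS AIC."""
    n = len(values)
    best_order, best_aic = 0, np.inf
    for order in (0, 1, 2):
        p = (1, 3, 6)[order]
        if n <= p:
            continue
        if order == 0:
            rss = float(np.sum((values - values.mean()) ** 2))
            p = 1
        else:
            resid, _ = detrend(points, values, order)
            rss = float(np.sum(resid**2))
        if rss <= 0:
            rss = 1e-300
        aic = n * np.log(rss / n) + 2 * (p + 1)
        if aic < best_aic:
            best_order, best_aic = order, aic
    return best_order


def empirical_variogram(
    points: np.ndarray,
    values: np.ndarray,
    n_lags: int = 15,
    max_lag: float | None = None,
    trend_order: int = 0,
) -> EmpiricalVariogram:
    """Method-of-moments semivariogram on equal-width lag bins.

    γ̂(b) = Σ_{(i,j) in b} (z_i − z_j)² / (2 N_b) over unordered station
    pairs whose separation falls in bin b; bins partition (0, max_lag]
    (default: half the maximum pairwise distance) and empty bins are omitted.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least two points")
    if trend_order:
        values, _ = detrend(points, values, trend_order)
    d = pdist(points)
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    inside = (d > 0) & (d <= max_lag)
    if not inside.any():
        raise ValueError("no station pairs within max_lag")
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    idx = np.clip(np.searchsorted(edges, d[inside], side="left") - 1, 0, n_lags - 1)
    counts = np.bincount(idx, minlength=n_lags)
    sums = np.bincount(idx, weights=sq[inside], minlength=n_lags)
    keep = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(
        lag_center=centers[keep],
        gamma_hat=sums[keep] / counts[keep],
        n_pairs=counts[keep],
        trend_order=trend_order,
    )


def fit_variogram(
    emp: EmpiricalVariogram, family: str = "spherical", seed: int = 0
) -> VariogramModel:
    """Fit (c0, c1, a) by Cressie-weighted least squares with multistart.

    Minimizes Σ_b N_b (γ̂_b − γ(h_b))² / γ(h_b)² over c0, c1 ≥ 0 and
    h_min ≤ a ≤ 2·max_lag, from 5 seeded starting points; the best local
    optimum is kept.
    """
    h = np.asarray(emp.lag_center, dtype=float)
    g = np.asarray(emp.gamma_hat, dtype=float)
    w = np.asarray(emp.n_pairs, dtype=float)
    if len(h) < 4:
        raise ValueError("need at least 4 variogram bins to fit 3 parameters")
    h_max = float(h.max())
    a_lo, a_hi = float(h.min()), 2.0 * h_max
    sill0 = float(g[-3:].mean()) if len(g) >= 3 else float(g.mean())
    sill0 = max(sill0, 1e-12)

    def objective(theta: np.ndarray) -> float:
        c0, c1, a = theta
        model = np.where(h > 0, c0 + _gamma_struct(h, family, c1, a), 0.0)
        denom = np.maximum(model, 1e-12) ** 2
        return float(np.sum(w * (g - model) ** 2 / denom))

    rng = np.random.default_rng(seed)
    starts = [
        (0.1 * sill0, 0.9 * sill0, 0.3 * h_max),
        (0.5 * sill0, 0.5 * sill0, 0.7 * h_max),
        (0.0, sill0, h_max),
    ]
    while len(starts) < 5:
        starts.append(
            (
                float(rng.uniform(0, sill0)),
                float(rng.uniform(0.1 * sill0, 1.5 * sill0)),
                float(rng.uniform(a_lo, a_hi)),
            )
        )
    bounds = [(0.0, None), (0.0, None), (a_lo, a_hi)]
    best = None
    for start in starts:
        res = minimize(objective, np.asarray(start), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("variogram fit failed on all starting points")
    c0, c1, a = best.x
    return VariogramModel(family, max(c0, 0.0), max(c1, 0.0), float(a),
                          trend_order=emp.trend_order)


def block_mean_structured_variogram(model: VariogramModel, v: float, m: int = 10) -> float:
    """Average structured semivariance γ̄_struct within a v×v cell.

    Regularization by numerical integration: the cell is discretized to an
    m×m uniform lattice and γ_struct is averaged over all distinct point
    pairs (self-pairs excluded).
    """
    if v <= 0:
        raise ValueError("cell size must be positive")
    if m < 2:
        raise ValueError("need m >= 2 lattice points per side")
    ticks = (np.arange(m) + 0.5) / m * v
    xx, yy = np.meshgrid(ticks, ticks)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    d = pdist(pts)
    return float(np.mean(model.gamma_struct(d)))


@dataclass
class InformationCurve:
    v: np.ndarray
    n_bar: np.ndarray
    PN: np.ndarray
    PS: np.ndarray
    f: np.ndarray
    Lopt: float
    f_at_Lopt: float

    def f_at(self, v: float, model: VariogramModel | None = None) -> float:
        """Interpolated f at an arbitrary cell size inside the search range."""
        return float(np.interp(v, self.v, self.f))


def information_curve(
    model: VariogramModel,
    station_density: float,
    v_grid: tuple[float, float, float],
    m: int = 10,
) -> InformationCurve:
    """Score candidate cell sizes and locate the optimum Lopt.

    n̄(v) = max(1, density·v²) stations per cell; PN(v) = 1 − 1/n̄(v);
    PS(v) = 1 − γ̄_struct(v)/c1 (identically 1 for a pure-nugget model);
    f(v) = PN·PS.  Lopt is the argmax, ties broken toward the smallest v.
    """
    if station_density <= 0:
        raise ValueError("station density must be positive")
    v_min, v_max, step = v_grid
    v = np.arange(v_min, v_max + 0.5 * step, step)
    n_bar = np.maximum(1.0, station_density * v**2)
    PN = 1.0 - 1.0 / n_bar
    if model.partial_sill > 0:
        gbar = np.array([block_mean_structured_variogram(model, vi, m) for vi in v])
        PS = np.clip(1.0 - gbar / model.partial_sill, 0.0, 1.0)
    else:
        PS = np.ones_like(v)
    f = PN * PS
    i_opt = int(np.argmax(f))  # argmax returns the first (smallest v) maximum
    return InformationCurve(v, n_bar, PN, PS, f, float(v[i_opt]), float(f[i_opt]))


@dataclass
class ConsensusLopt:
    per_taxon_lopt: dict[str, float]
    consensus: float
    max_relative_f_loss: float
    empty_cell_counts: dict[str, int] = field(default_factory=dict)


def consensus_lopt(curves: dict[str, InformationCurve]) -> ConsensusLopt:
    """Median of per-taxon optima, with the worst relative loss in f.

    The loss for taxon t is (f_t(Lopt_t) − f_t(consensus)) / f_t(Lopt_t),
    clamped at zero from below; the maximum over taxa quantifies how much
    information the compromise cell size sacrifices for any single taxon.
    """
    if not curves:
        raise ValueError("need at least one taxon curve")
    lopts = {t: c.Lopt for t, c in curves.items()}
    consensus = float(np.median(list(lopts.values())))
    losses = []
    for c in curves.values():
        if c.f_at_Lopt > 0:
            losses.append(max(0.0, (c.f_at_Lopt - c.f_at(consensus)) / c.f_at_Lopt))
        else:
            losses.append(0.0)
    return ConsensusLopt(lopts, consensus, float(max(losses)))
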