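"""Ks density estimation and Gaussian multi-peak fitting.

The Ks distribution of collinear duplicates is smoothed with a Gaussian
kernel density estimate, and a sum of k Gaussian components is fitted to the
smoothed curve by nonlinear least squares.  The smallest k whose coefficient
of determination reaches ``r2_min`` (default 0.95) is accepted; if no k does,
the best fit is returned flagged below threshold.  Fitting targets the curve,
not the raw values, and component weights are unconstrained positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger("paleoploid")


@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    ks_ceiling: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        area = float(np.trapezoid(self.density, self.grid))
        if not (0.99 <= area <= 1.01):
            raise ValueError(f"density integral {area:.4f} outside [0.99, 1.01]")

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass
class PeakModel:
    """Fitted Gaussian mixture approximation of a Ks density curve.

    ``components`` are (weight, mean, sd) sorted by ascending mean.
    """

    components: list[tuple[float, float, float]]
    r_squared: float
    n_components: int
    below_threshold: bool = False
    event_assignment: dict[int, str] = field(default_factory=dict)

    @property
    def means(self) -> list[float]:
        return [mu for _, mu, _ in self.components]


def estimate_density(ks_values, bandwidth: float | str = "auto",
                     ks_ceiling: float = 2.5, n_grid: int = 512) -> DensityCurve:
    """Gaussian KDE of Ks values on a grid over [0, ks_ceiling].

    Values above the ceiling, non-finite or negative are excluded (counts
    logged).  ``bandwidth='auto'`` uses Silverman's rule.  The curve is
    renormalised to unit mass over the grid so truncation at the ceiling does
    not break the density invariant.
    """
    vals = np.asarray(ks_values, dtype=float)
    kept = vals[np.isfinite(vals) & (vals >= 0) & (vals <= ks_ceiling)]
    if len(kept) < len(vals):
        logger.info("density: excluded %d of %d Ks values (ceiling %.3g)",
                    len(vals) - len(kept), len(vals), ks_ceiling)
    if len(kept) < 10:
        raise ValueError(f"need >= 10 usable Ks values, got {len(kept)}")
    if np.ptp(kept) == 0:
        # point mass: gaussian_kde cannot handle zero variance
        bw = 0.05 if bandwidth == "auto" else float(bandwidth)
        grid = np.linspace(0, ks_ceiling, n_grid)
        dens = stats.norm.pdf(grid, loc=kept[0], scale=bw)
    else:
        if bandwidth == "auto":
            kde = stats.gaussian_kde(kept, bw_method="silverman")
        else:
            kde = stats.gaussian_kde(kept, bw_method=float(bandwidth) / kept.std(ddof=1))
        grid = np.linspace(0, ks_ceiling, n_grid)
        dens = kde(grid)
        bw = float(kde.factor * kept.std(ddof=1))
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("degenerate density")
    return DensityCurve(grid=grid, density=dens / area, bandwidth=bw,
                        ks_ceiling=ks_ceiling)


def _gauss_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        w, mu, sigma = params[i:i + 3]
        y = y + w * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return y


def r_squared(y: np.ndarray, y_fit: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _fit_k(curve: DensityCurve, k: int, rng: np.random.Generator,
           n_starts: int = 5):
    x, y = curve.grid, curve.density
    span = x[-1] - x[0]
    lo = [0.0, x[0], 1e-4] * k
    hi = [np.inf, x[-1], span] * k
    # quantile-based means from the curve treated as a weight function
    cdf = np.cumsum(y)
    cdf /= cdf[-1]
    q_means = np.interp((np.arange(k) + 0.5) / k, cdf, x)
    best = None
    for s in range(n_starts):
        p0 = []
        for j in range(k):
            mu0 = q_means[j] if s == 0 else float(
                np.clip(q_means[j] + rng.normal(0, span / 10), x[0], x[-1]))
            p0 += [float(y.max()), mu0, span / (4 * k)]
        try:
            popt, _ = optimize.curve_fit(_gauss_sum, x, y, p0=p0,
                                         bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        r2 = r_squared(y, _gauss_sum(x, *popt))
        if best is None or r2 > best[1]:
            best = (popt, r2)
    return best


def fit_peak_model(curve: DensityCurve, n_max: int = 4, r2_min: float = 0.95,
                   seed: int = 0) -> PeakModel:
    """Fit Gaussian sums with k = 1..n_max components; accept the smallest k
    reaching ``r2_min``; otherwise return the best fit flagged."""
    if not 1 <= n_max <= 6:
        raise ValueError("n_max must be in 1..6")
    rng = np.random.default_rng(seed)
    best_overall = None
    for k in range(1, n_max + 1):
        fit = _fit_k(curve, k, rng)
        if fit is None:
            continue
        popt, r2 = fit
        comps = sorted(
            ((float(popt[i]), float(popt[i + 1]), float(popt[i + 2]))
             for i in range(0, len(popt), 3)),
            key=lambda c: c[1],
        )
        model = PeakModel(components=comps, r_squared=r2, n_components=k)
        if r2 >= r2_min:
            return model
        if best_overall is None or r2 > best_overall.r_squared:
            best_overall = model
    if best_overall is None:
        raise RuntimeError("gaussian fitting failed at every component count")
    best_overall.below_threshold = True
    return best_overall


def assign_events(model: PeakModel, labels: list[str]) -> PeakModel:
    """Label components by ascending mean (youngest event first), e.g.
    ['α', 'ω'] for a two-peak within-genome curve."""
    for i, lab in enumerate(labels[: model.n_components]):
        model.event_assignment[i] = lab
    return model


def write_peak_report(models: dict[str, PeakModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("dataset\tk\tcomponent\tweight\tmu\tsigma\tr_squared\n")
        for name, m in models.items():
            for i, (w, mu, sd) in enumerate(m.components):
                fh.write(f"{name}\t{m.n_components}\t{i}\t{w:.6g}\t{mu:.6g}\t"
                         f"{sd:.6g}\t{m.r_squared:.4f}\n")
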