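"""Penalized-spline smooths of z-values over distance axes.

Curves along phylogenetic distance (Ma) and tensor-product surfaces over
(physical distance, phylogenetic distance) are fit as P-splines: a cubic
B-spline basis of ``k`` functions with a second-order difference penalty,
smoothing parameter chosen by generalized cross-validation.  Pointwise 95%
bands come from the posterior coefficient covariance sigma^2 (X'X + lam*P)^-1.
Grid points whose fitted value lies outside the two-sided null band
[-1.96, +1.96] are flagged significant; the rest are the "gray" region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.stats import norm

Z_NULL_BAND = norm.ppf(0.975)  # |z| below this is indistinguishable from the null


@dataclass
class SmoothFit:
    """A fitted penalized-spline curve or surface on a prediction grid."""

    grid: np.ndarray            # (m,) x values, or (m, 2) (physical m, phylo Ma) for surfaces
    fitted: np.ndarray
    se: np.ndarray
    lower: np.ndarray           # pointwise 95% band
    upper: np.ndarray
    k_used: int | tuple[int, int]
    lam: float | tuple[float, float]
    edf: float
    significant: np.ndarray     # fitted value outside the null z band

    @property
    def is_surface(self) -> bool:
        return np.ndim(self.grid) == 2


def _bspline_basis(x: np.ndarray, k: int, xmin: float, xmax: float) -> np.ndarray:
    """k cubic (or lower-degree for k < 4) B-spline basis functions on [xmin, xmax].

    Equally spaced knots extended beyond the domain, so the difference
    penalty's nullspace contains polynomials up to the penalty order exactly.
    """
    degree = 3 if k >= 4 else k - 1
    span = xmax - xmin or 1.0
    h = span / (k - degree)
    t = xmin + h * np.arange(-degree, k + 1)
    xq = np.clip(x, xmin, xmax)
    return BSpline.design_matrix(xq, t, degree, extrapolate=True).toarray()


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=min(order, k - 1), axis=0)
    return d.T @ d


def _solve(X, y, P, lam):
    XtX = X.T @ X
    A = XtX + lam * P
    beta = np.linalg.solve(A, X.T @ y)
    Ainv = np.linalg.inv(A)
    edf = float(np.trace(Ainv @ XtX))
    resid = y - X @ beta
    rss = float(resid @ resid)
    return beta, Ainv, edf, rss


def _gcv(rss, n, edf):
    denom = max(n - edf, 1e-8)
    return n * rss / denom**2


def fit_curve(x, y, k: int = 10, lam_grid=None, grid=None) -> SmoothFit:
    """Penalized cubic regression spline of y on x with GCV-chosen smoothing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if k < 3:
        raise ValueError("k must be >= 3")
    if x.size < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} points, got {x.size}")
    xmin, xmax = float(x.min()), float(x.max())
    X = _bspline_basis(x, k, xmin, xmax)
    P = _difference_penalty(k)
    if lam_grid is None:
        lam_grid = np.logspace(-5, 7, 49)
    best = None
    # descending: among numerically tied GCV scores prefer the smoothest fit
    for lam in sorted(lam_grid, reverse=True):
        beta, Ainv, edf, rss = _solve(X, y, P, lam)
        score = _gcv(rss, x.size, edf)
        if best is None or score < best[0] * (1 - 1e-9):
            best = (score, lam, beta, Ainv, edf, rss)
    _, lam, beta, Ainv, edf, rss = best
    sigma2 = rss / max(x.size - edf, 1e-8)
    if grid is None:
        grid = np.linspace(xmin, xmax, 200)
    Xg = _bspline_basis(np.asarray(grid, dtype=float), k, xmin, xmax)
    fitted = Xg @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, sigma2 * Ainv, Xg), 0.0))
    lower, upper = fitted - 1.96 * se, fitted + 1.96 * se
    return SmoothFit(grid=np.asarray(grid, dtype=float), fitted=fitted, se=se,
                     lower=lower, upper=upper, k_used=k, lam=float(lam), edf=edf,
                     significant=np.abs(fitted) > Z_NULL_BAND)


def _residual_autocorr_p(x, y, fit_at_x) -> float:
    """Two-sided p for lag-1 autocorrelation of residuals ordered by x."""
    order = np.argsort(x)
    r = (y - fit_at_x)[order]
    n = r.size
    if n < 4 or r.std() <= 1e-8 * (y.std() or 1.0):  # numerically perfect fit
        return 1.0
    r = r - r.mean()
    rho = float(np.sum(r[:-1] * r[1:]) / np.sum(r * r))
    zstat = rho * np.sqrt(n)
    return float(2.0 * norm.sf(abs(zstat)))


def choose_k(x, y, k_grid=None) -> int:
    """Smallest basis size whose diagnostics pass (an automated gam.check analogue).

    A candidate k passes when the effective degrees of freedom stay comfortably
    below the basis ceiling (edf < 0.9 (k-1)) and the residuals show no
    x-ordered lag-1 autocorrelation (p > 0.05).  If none passes, the largest
    candidate is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if k_grid is None:
        k_grid = range(4, min(20, x.size - 2) + 1)
    k_grid = [k for k in k_grid if x.size >= k + 2]
    if not k_grid:
        raise ValueError("no feasible basis size for this sample")
    for k in k_grid:
        fit = fit_curve(x, y, k=k, grid=x)
        if fit.edf < 0.9 * (k - 1) and _residual_autocorr_p(x, y, fit.fitted) > 0.05:
            return k
    warnings.warn("no basis size passed the diagnostics; using the largest candidate")
    return max(k_grid)


def fit_surface(physical, phylo, z, k: tuple[int, int] = (6, 8), lam_grid=None,
                grid_shape: tuple[int, int] = (40, 60)) -> SmoothFit:
    """Tensor-product P-spline surface of z over (physical distance, phylogenetic distance).

    The two smoothing parameters (one per axis) are chosen jointly by GCV on a
    log-spaced grid.
    """
    x1 = np.asarray(physical, dtype=float)
    x2 = np.asarray(phylo, dtype=float)
    y = np.asarray(z, dtype=float)
    ok = np.isfinite(x1) & np.isfinite(x2) & np.isfinite(y)
    x1, x2, y = x1[ok], x2[ok], y[ok]
    if np.unique(x1).size < 2 or np.unique(x2).size < 3:
        raise ValueError("surface fit needs >= 2 physical and >= 3 phylogenetic positions")
    k1, k2 = k
    k1 = min(k1, max(np.unique(x1).size, 2))
    k2 = min(k2, max(np.unique(x2).size, 3))
    b1min, b1max = float(x1.min()), float(x1.max())
    b2min, b2max = float(x2.min()), float(x2.max())
    B1 = _bspline_basis(x1, k1, b1min, b1max)
    B2 = _bspline_basis(x2, k2, b2min, b2max)
    X = (B1[:, :, None] * B2[:, None, :]).reshape(x1.size, k1 * k2)
    P1 = np.kron(_difference_penalty(k1), np.eye(k2))
    P2 = np.kron(np.eye(k1), _difference_penalty(k2))
    if lam_grid is None:
        lam_grid = np.logspace(-3, 5, 9)
    best = None
    XtX = X.T @ X
    Xty = X.T @ y
    for l1 in sorted(lam_grid, reverse=True):
        for l2 in sorted(lam_grid, reverse=True):
            A = XtX + l1 * P1 + l2 * P2
            Ainv = np.linalg.inv(A)
            beta = Ainv @ Xty
            edf = float(np.trace(Ainv @ XtX))
            resid = y - X @ beta
            rss = float(resid @ resid)
            score = _gcv(rss, y.size, edf)
            if best is None or score < best[0]:
                best = (score, (l1, l2), beta, Ainv, edf, rss)
    _, lams, beta, Ainv, edf, rss = best
    sigma2 = rss / max(y.size - edf, 1e-8)
    g1 = np.linspace(b1min, b1max, grid_shape[0])
    g2 = np.linspace(b2min, b2max, grid_shape[1])
    G1, G2 = np.meshgrid(g1, g2, indexing="ij")
    Bg1 = _bspline_basis(G1.ravel(), k1, b1min, b1max)
    Bg2 = _bspline_basis(G2.ravel(), k2, b2min, b2max)
    Xg = (Bg1[:, :, None] * Bg2[:, None, :]).reshape(G1.size, k1 * k2)
    fitted = Xg @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, sigma2 * Ainv, Xg), 0.0))
    grid = np.stack([G1.ravel(), G2.ravel()], axis=1)
    return SmoothFit(grid=grid, fitted=fitted, se=se, lower=fitted - 1.96 * se,
                     upper=fitted + 1.96 * se, k_used=(k1, k2), lam=tuple(map(float, lams)),
                     edf=edf, significant=np.abs(fitted) > Z_NULL_BAND)


def surface_cross_sections(fit: SmoothFit) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Phylo-axis profiles of a surface fit, one per physical grid line."""
    if not fit.is_surface:
        raise ValueError("cross sections are defined for surface fits")
    out = {}
    for v in np.unique(fit.grid[:, 0]):
        m = fit.grid[:, 0] == v
        out[float(v)] = (fit.grid[m, 1], fit.fitted[m])
    return out


def locate_extrema(fit: SmoothFit, min_prominence: float = 0.0) -> list[dict]:
    """Interior peaks/valleys of a fitted curve whose band excludes the shoulders.

    A local extremum qualifies when the fitted values at its flanking
    turning points (or curve ends) fall outside the extremum's 95% band.
    Results are sorted by prominence (depth/height against the shoulders).
    """
    if fit.is_surface:
        raise ValueError("locate_extrema expects a curve fit; use surface_cross_sections")
    f = fit.fitted
    n = f.size
    d = np.diff(f)
    turning = [i for i in range(1, n - 1) if d[i - 1] * d[i] < 0 or (d[i - 1] != 0 and d[i] == 0)]
    anchors = [0] + turning + [n - 1]
    out = []
    for i in turning:
        kind = "peak" if f[i] > f[i - 1] else "valley"
        left = max(a for a in anchors if a < i)
        right = min(a for a in anchors if a > i)
        shoulder = max(f[left], f[right]) if kind == "valley" else min(f[left], f[right])
        prominence = abs(f[i] - shoulder)
        band_excludes = shoulder < fit.lower[i] or shoulder > fit.upper[i]
        if band_excludes and prominence > min_prominence:
            out.append({"kind": kind, "x": float(fit.grid[i]), "value": float(f[i]),
                        "prominence": float(prominence)})
    out.sort(key=lambda e: -e["prominence"])
    return out
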