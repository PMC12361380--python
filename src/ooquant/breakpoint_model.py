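"""Two-segment (broken-line) regression for radial intensity profiles.

Radial organelle distributions in oocytes are summarised by the distance at
which the mean intensity profile changes slope: the breakpoint psi of a
continuous two-segment linear model

    y = a + b1 * x + (b2 - b1) * (x - psi)_+

fitted to the per-distance mean curve.  The estimator is the classical
iterative-linearisation scheme for segmented regression (Muggeo-type): at a
working breakpoint psi0 the kinked term is linearised and y is regressed on
{1, x, (x - psi0)_+, -1[x > psi0]}; the ratio of the last two coefficients
updates psi.  The standard error of psi follows from the delta method on that
ratio, giving Wald confidence intervals.

An exhaustive grid-search estimator over candidate breakpoints is provided as
an independent oracle for the iterative fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BreakpointFit",
    "fit_segmented",
    "grid_search_oracle",
    "breakpoint_ci",
    "compare_conditions",
]


@dataclass(frozen=True)
class BreakpointFit:
    """Result of a continuous two-segment linear fit.

    Attributes
    ----------
    psi : float
        Estimated breakpoint (µm).
    se_psi : float
        Delta-method standard error of ``psi``; ``inf`` when the slope
        change is indistinguishable from zero.
    ci95 : tuple of float
        95% Wald confidence interval for ``psi``, clipped to the data range.
    intercept, slope_left, slope_right : float
        Parameters of the continuous two-segment model; ``slope_right``
        equals ``slope_left`` plus the hinge coefficient.
    rss : float
        Residual sum of squares of the final model.
    n_points : int
        Number of (x, y) observations.
    n_iter : int
        Iterations used by the linearisation scheme.
    converged : bool
        Whether |delta psi| fell below tolerance within ``max_iter``.
    x_min, x_max : float
        Extent of the fitted distance grid (µm).
    """

    psi: float
    se_psi: float
    ci95: tuple[float, float]
    intercept: float
    slope_left: float
    slope_right: float
    rss: float
    n_points: int
    n_iter: int
    converged: bool
    x_min: float
    x_max: float


_Z95 = 1.959964


def _validate_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be one-dimensional arrays of equal length")
    if x.size < 5:
        raise ValueError(f"need at least 5 points for a two-segment fit, got {x.size}")
    if not np.all(np.diff(x) > 0):
        raise ValueError("x must be strictly increasing")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    return x, y


def _hinge_ols(x: np.ndarray, y: np.ndarray, psi: float):
    """OLS of y on {1, x, (x-psi)_+}; returns (coef, rss)."""
    X = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _batched_rss(x: np.ndarray, y: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """RSS of the continuous two-segment model at each candidate breakpoint.

    Solves the 3x3 normal equations for all candidates at once.
    """
    n = x.size
    u = np.clip(x[None, :] - cand[:, None], 0.0, None)  # (n_cand, n)
    Sx, Sxx = x.sum(), float(x @ x)
    Sy, Sxy, Syy = y.sum(), float(x @ y), float(y @ y)
    Su = u.sum(axis=1)
    Sxu = u @ x
    Suu = np.einsum("ij,ij->i", u, u)
    Suy = u @ y

    A = np.empty((cand.size, 3, 3))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = Sx
    A[:, 0, 2] = A[:, 2, 0] = Su
    A[:, 1, 1] = Sxx
    A[:, 1, 2] = A[:, 2, 1] = Sxu
    A[:, 2, 2] = Suu
    b = np.stack([np.full(cand.size, Sy), np.full(cand.size, Sxy), Suy], axis=1)
    # Tiny ridge keeps near-degenerate candidates (u almost collinear) solvable.
    A += 1e-12 * np.eye(3)
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    return Syy - np.einsum("ij,ij->i", coef, b)


def grid_search_oracle(
    x: np.ndarray, y: np.ndarray, resolution: float = 0.01
) -> tuple[float, float]:
    """Exhaustive breakpoint search on a regular grid.

    For every candidate psi between the second and the second-to-last
    x value the continuous two-segment model is solved in closed form;
    the global minimiser of the residual sum of squares on the grid is
    returned as ``(psi_best, rss_best)``.
    """
    x, y = _validate_xy(x, y)
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lo, hi = x[1], x[-2]
    cand = np.arange(lo, hi + resolution / 2, resolution)
    cand = cand[(cand >= lo) & (cand <= hi)]
    if cand.size == 0:
        cand = np.array([(lo + hi) / 2])
    rss = _batched_rss(x, y, cand)
    best = int(np.argmin(rss))
    # Recompute the winner without ridge for an exact RSS.
    _, rss_best = _hinge_ols(x, y, float(cand[best]))
    return float(cand[best]), rss_best


def fit_segmented(
    x: np.ndarray,
    y: np.ndarray,
    psi0: float | None = None,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> BreakpointFit:
    """Fit the continuous two-segment model by iterative linearisation.

    Parameters
    ----------
    x, y : arrays
        Strictly increasing distances (µm) and mean intensities.
    psi0 : float, optional
        Initial breakpoint guess, strictly inside ``(min(x), max(x))``.
        When omitted, the best candidate on a coarse grid is used.
    tol : float
        Convergence tolerance on |delta psi| in µm.
    max_iter : int
        Maximum number of linearisation steps.

    Raises
    ------
    ValueError
        For fewer than 5 points, a non-increasing grid, an out-of-range
        ``psi0``, or when the breakpoint escapes the data range from every
        restart.
    """
    x, y = _validate_xy(x, y)
    lo, hi = float(x[0]), float(x[-1])
    # Interior bounds: keep at least two points on each side of the kink.
    blo, bhi = float(x[1]), float(x[-2])
    if psi0 is not None:
        if not (lo < psi0 < hi):
            raise ValueError(f"psi0={psi0} must lie strictly inside ({lo}, {hi})")
        starts = [float(np.clip(psi0, blo, bhi))]
    else:
        coarse = max((bhi - blo) / 50.0, tol)
        starts = [grid_search_oracle(x, y, resolution=coarse)[0]]
    # Fallback restarts if the update escapes the data range.
    starts += [lo + f * (hi - lo) for f in (0.25, 0.5, 0.75)]

    last_err: Exception | None = None
    for start in starts:
        try:
            return _muggeo_iterate(x, y, start, blo, bhi, tol, max_iter)
        except _BreakpointEscaped as err:  # try the next restart
            last_err = err
    raise ValueError(f"breakpoint left the data range from every start: {last_err}")


class _BreakpointEscaped(RuntimeError):
    pass


def _muggeo_iterate(x, y, psi, blo, bhi, tol, max_iter) -> BreakpointFit:
    n = x.size
    ones = np.ones_like(x)
    converged = False
    unidentified = False
    n_iter = 0
    beta = gamma = 0.0
    for n_iter in range(1, max_iter + 1):
        u = np.clip(x - psi, 0.0, None)
        v = -(x > psi).astype(float)
        X = np.column_stack([ones, x, u, v])
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        beta, gamma = float(coef[2]), float(coef[3])
        if abs(beta) < 1e-12:
            # No detectable slope change: psi is unidentified; stop here.
            converged = True
            unidentified = True
            break
        step = gamma / beta
        psi_new = psi + step
        if not (blo <= psi_new <= bhi):
            # One damped retry before declaring escape.
            psi_half = psi + step / 2
            if not (blo <= psi_half <= bhi):
                raise _BreakpointEscaped(f"psi -> {psi_new:.3f}")
            psi_new = psi_half
        if abs(psi_new - psi) < tol:
            psi = psi_new
            converged = True
            break
        psi = psi_new

    if not unidentified:
        # On noisy data the linearisation oscillates near the optimum and the
        # RSS profile has micro-minima between neighbouring x values: scan a
        # fine local window, then polish inside the best cell.
        step = 0.01
        lo_b = max(blo, psi - 2.0)
        hi_b = min(bhi, psi + 2.0)
        if lo_b < hi_b:
            cand = np.arange(lo_b, hi_b + step / 2, step)
            best = cand[int(np.argmin(_batched_rss(x, y, cand)))]
            res = optimize.minimize_scalar(
                lambda p: _hinge_ols(x, y, p)[1],
                bounds=(max(lo_b, best - step), min(hi_b, best + step)),
                method="bounded",
                options={"xatol": 1e-8},
            )
            for candidate in ((float(res.x) if res.success else None), float(best)):
                if candidate is not None and (
                    _hinge_ols(x, y, candidate)[1] < _hinge_ols(x, y, psi)[1]
                ):
                    psi = candidate
                    converged = True
                    break

    # Final working model at the converged psi, for the delta-method SE.
    u = np.clip(x - psi, 0.0, None)
    v = -(x > psi).astype(float)
    X = np.column_stack([ones, x, u, v])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss4 = float(resid @ resid)
    beta, gamma = float(coef[2]), float(coef[3])
    dof = max(n - 4, 1)
    sigma2 = rss4 / dof
    if abs(beta) < 1e-12 or sigma2 < 0:
        se_psi = np.inf
    else:
        XtX = X.T @ X
        try:
            cov = sigma2 * np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            cov = sigma2 * np.linalg.pinv(XtX)
        r = gamma / beta
        var_psi = (cov[3, 3] + r * r * cov[2, 2] - 2 * r * cov[2, 3]) / beta**2
        se_psi = float(np.sqrt(max(var_psi, 0.0)))

    # Report the continuous model refitted at the final breakpoint.
    (a, b1, db), rss = _hinge_ols(x, y, psi)
    ci = _wald_ci(psi, se_psi, _Z95, x[0], x[-1])
    return BreakpointFit(
        psi=float(psi),
        se_psi=se_psi,
        ci95=ci,
        intercept=float(a),
        slope_left=float(b1),
        slope_right=float(b1 + db),
        rss=rss,
        n_points=n,
        n_iter=n_iter,
        converged=converged,
        x_min=float(x[0]),
        x_max=float(x[-1]),
    )


def _wald_ci(psi, se, z, lo, hi) -> tuple[float, float]:
    if not np.isfinite(se):
        return (float(lo), float(hi))
    return (float(max(psi - z * se, lo)), float(min(psi + z * se, hi)))


def breakpoint_ci(fit: BreakpointFit, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval psi ± z(level)·se, clipped to the data range.

    Raises on a non-converged fit; warns when clipping occurs.
    """
    if not fit.converged:
        raise ValueError("confidence interval requested for a non-converged fit")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    z = float(stats.norm.ppf(0.5 + level / 2))
    if not np.isfinite(fit.se_psi):
        warnings.warn("breakpoint standard error is infinite; CI spans the data range")
        return (fit.x_min, fit.x_max)
    raw = (fit.psi - z * fit.se_psi, fit.psi + z * fit.se_psi)
    ci = _wald_ci(fit.psi, fit.se_psi, z, fit.x_min, fit.x_max)
    if ci != tuple(np.round(raw, 15)) and (raw[0] < fit.x_min or raw[1] > fit.x_max):
        warnings.warn("confidence interval clipped to the data range")
    return ci


def compare_conditions(fit_a: BreakpointFit, fit_b: BreakpointFit) -> dict:
    """Compare two breakpoints by 95% CI overlap.

    Returns ``{"overlap": bool, "gap": float}`` where ``gap`` is the signed
    distance between the nearest CI endpoints: positive when the intervals
    are disjoint, non-positive when they intersect.
    """
    for f in (fit_a, fit_b):
        if not f.converged:
            raise ValueError("compare_conditions requires converged fits")
    lo = max(fit_a.ci95[0], fit_b.ci95[0])
    hi = min(fit_a.ci95[1], fit_b.ci95[1])
    gap = lo - hi
    return {"overlap": bool(gap <= 0), "gap": float(gap)}
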