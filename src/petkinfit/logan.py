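"""Logan graphical analysis with plasma input.

For a reversibly binding tracer the transformed coordinates

    x(T) = int_0^T Cp dt / Ct(T),    y(T) = int_0^T Ct dt / Ct(T)

become linear in T once the tissue has equilibrated with plasma; the
asymptotic slope of y against x equals the total distribution volume Vt.
The start of the linear section, t*, is selected by a maximum-relative-error
criterion: the earliest frame such that every included point lies within a
stated fraction (default 10%) of the fitted line.

Cumulative integrals use the trapezoid rule on the union grid of frame
mid-times and input knots; the plasma integral is exact there because the
input contract is piecewise linear.  The line itself is an ordinary
least-squares fit — the usual practice, with the known caveat that Logan
slopes are biased low under noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plasma_input import InputFunction
from .tac_io import TimeActivityCurve

__all__ = ["LoganPoints", "LoganResult", "logan_transform", "select_tstar",
           "fit_logan", "logan_vt"]


@dataclass(frozen=True)
class LoganPoints:
    """Graphical-plot coordinates at frame mid-times with Ct(T) > 0."""

    x: np.ndarray  # int Cp / Ct(T), minutes
    y: np.ndarray  # int Ct / Ct(T), minutes
    T: np.ndarray  # frame mid-times, minutes

    def __post_init__(self) -> None:
        x, y, T = (np.asarray(v, dtype=float) for v in (self.x, self.y, self.T))
        if not (x.shape == y.shape == T.shape) or x.ndim != 1:
            raise ValueError("x, y, T must be 1-D and equal length")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise ValueError("Logan coordinates must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "T", T)


@dataclass(frozen=True)
class LoganResult:
    t_star: float          # minutes; a frame mid-time
    slope: float           # mL/ccm, the Vt estimate
    intercept: float       # minutes
    max_rel_error: float   # max |residual| / |fitted y| over included points
    n_points: int
    converged: bool = True


def logan_transform(tac: TimeActivityCurve, input_fn: InputFunction) -> LoganPoints:
    """Map a TAC and input function into the Logan plane.

    Tissue activity between frame mid-times is treated as piecewise linear
    starting from Ct(0) = 0; points are emitted only for frames where
    Ct(T) > 0.
    """
    T = tac.frame_mid
    ct = tac.activity
    # integrate Ct on the union grid of {0}, frame mids and input knots
    knots = input_fn.knot_time
    grid = np.union1d(np.concatenate([[0.0], T]),
                      knots[knots <= T[-1]])
    ct_grid = np.interp(grid, np.concatenate([[0.0], T]),
                        np.concatenate([[0.0], ct]))
    cum_ct_grid = np.concatenate(
        [[0.0], np.cumsum(np.diff(grid) * (ct_grid[:-1] + ct_grid[1:]) / 2.0)])
    cum_ct = np.interp(T, grid, cum_ct_grid)
    cum_cp = np.atleast_1d(input_fn.cumulative_integral(T))

    pos = ct > 0
    if not np.any(pos):
        raise ValueError("no valid Logan points: tissue curve is non-positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        x = cum_cp[pos] / ct[pos]
        y = cum_ct[pos] / ct[pos]
    if np.any(~np.isfinite(x)):
        raise ValueError("undefined Logan abscissa (zero input integral)")
    return LoganPoints(x=x, y=y, T=T[pos])


def _ols(x: np.ndarray, y: np.ndarray):
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx <= 0:
        raise ValueError("degenerate Logan fit: no variance in x")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return slope, ym - slope * xm


def _max_rel_error(x, y, slope, intercept) -> float:
    fit = slope * x + intercept
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(y - fit) / np.abs(fit)
    return float(np.max(rel))


def select_tstar(points: LoganPoints, criterion: float = 0.10) -> tuple[float, bool]:
    """Earliest linear-section start satisfying the relative-error criterion.

    Scans candidate start times from the first point; for each, an OLS line
    is fitted to all points at T >= t and accepted when the maximum absolute
    relative deviation from the fitted line is <= ``criterion``.  Returns
    ``(t_star, converged)``; when no start qualifies, the latest start
    leaving >= 3 points is returned with ``converged=False``.
    """
    n = points.T.size
    if n < 3:
        raise ValueError("need at least 3 Logan points")
    for i in range(n - 2):
        x, y = points.x[i:], points.y[i:]
        slope, intercept = _ols(x, y)
        if _max_rel_error(x, y, slope, intercept) <= criterion:
            return float(points.T[i]), True
    return float(points.T[n - 3]), False


def fit_logan(points: LoganPoints, t_star: float) -> LoganResult:
    """OLS line through points at T >= t_star; the slope is the Vt estimate."""
    sel = points.T >= t_star - 1e-12
    if np.count_nonzero(sel) < 3:
        raise ValueError("fewer than 3 Logan points at T >= t_star")
    x, y = points.x[sel], points.y[sel]
    slope, intercept = _ols(x, y)
    return LoganResult(t_star=float(t_star), slope=float(slope),
                       intercept=float(intercept),
                       max_rel_error=_max_rel_error(x, y, slope, intercept),
                       n_points=int(x.size))


def logan_vt(tac: TimeActivityCurve, input_fn: InputFunction,
             criterion: float = 0.10) -> LoganResult:
    """Convenience pipeline: transform, select t*, fit; flags non-convergence."""
    points = logan_transform(tac, input_fn)
    t_star, ok = select_tstar(points, criterion)
    res = fit_logan(points, t_star)
    if not ok:
        res = LoganResult(**{**res.__dict__, "converged": False})
    return res
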