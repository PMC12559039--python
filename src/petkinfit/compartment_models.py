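"""One- and two-tissue compartment models for reversible tracer kinetics.

Model structure
---------------
With a metabolite-corrected plasma input Cp(t), the tissue concentration of
the one-tissue model (1TCM) obeys

    dCt/dt = K1*Cp - k2*Ct,

and the two-tissue model (2TCM), with a free+non-specific compartment C1 in
exchange with a specifically bound compartment C2,

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2,          Ct = C1 + C2.

K1 (mL/ccm/min) is plasma-to-tissue transfer across the blood-brain barrier,
k2 (1/min) back-diffusion to plasma, and k3/k4 (1/min) association to and
dissociation from the specific binding site.  The measured PET signal adds a
fractional blood volume vB:

    Cm(t) = (1 - vB)*Ct(t) + vB*Cb(t),

where Cb is the blood-activity curve (total plasma by default here).

Both models have exponential impulse responses, so Ct is a convolution
h (*) Cp.  Because the input contract is piecewise linear, that convolution
is evaluated *exactly* segment-by-segment (no quadrature grid); the repeated-
eigenvalue 2TCM case uses the analytic confluent t*exp(-theta*t) form.

The total distribution volume is Vt = K1/k2 (1TCM) and (K1/k2)(1 + k3/k4)
(2TCM) — the macroparameter that stays identifiable when the individual rate
constants do not.

Fitting minimises a weighted residual sum of squares with
``scipy.optimize.least_squares`` (trust-region reflective; LM-equivalent on
these smooth low-dimensional problems but supporting the physical bounds
rates >= 0, vB in [0, 0.2]).  Parameter uncertainty comes from the
Gauss-Newton covariance sigma^2 (J^T J)^-1 and is reported as %COV
(100*SE/|estimate|); the Vt uncertainty uses the delta method on the full
parameter covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .plasma_input import InputFunction
from .tac_io import FrameSchedule, TimeActivityCurve

__all__ = [
    "KineticParams1T",
    "KineticParams2T",
    "VbPolicy",
    "FitResult",
    "solve_1tcm",
    "solve_2tcm",
    "model_tac",
    "fit_model",
    "compute_vt",
    "model_criteria",
    "DEFAULT_INIT",
]

# standard nonlinear-fit starting values for this tracer's models
DEFAULT_INIT = {"K1": 0.5, "k2": 0.035, "k3": 0.01, "k4": 0.01, "vB": 0.05}


@dataclass(frozen=True)
class KineticParams1T:
    K1: float  # mL/ccm/min
    k2: float  # 1/min
    vB: float = 0.0

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("rate constants must be >= 0")
        if not 0 <= self.vB < 1:
            raise ValueError("vB must lie in [0, 1)")


@dataclass(frozen=True)
class KineticParams2T:
    K1: float  # mL/ccm/min
    k2: float  # 1/min
    k3: float  # 1/min
    k4: float  # 1/min
    vB: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be >= 0")
        if not 0 <= self.vB < 1:
            raise ValueError("vB must lie in [0, 1)")


@dataclass(frozen=True)
class VbPolicy:
    """Whether the blood-volume fraction is fitted or held fixed."""

    mode: str  # "fixed" | "free"
    fixed_value: float = 0.03

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "free"):
            raise ValueError("vB mode must be 'fixed' or 'free'")
        if self.mode == "fixed" and not 0 <= self.fixed_value <= 0.2:
            raise ValueError("fixed vB must lie in [0, 0.2]")

    @classmethod
    def fixed(cls, value: float = 0.03) -> "VbPolicy":
        return cls("fixed", value)

    @classmethod
    def free(cls) -> "VbPolicy":
        return cls("free")


# ---------------------------------------------------------------------------
# exact convolution of exp / t*exp kernels with a piecewise-linear input
# ---------------------------------------------------------------------------

def _phi(theta: float, tau: np.ndarray):
    """(phi1, phi2): int_0^tau e^{-theta u} du and int e^{-theta(tau-s)} s ds.

    Scalar theta >= 0, array tau >= 0; a short series replaces the closed
    form where theta*tau is small enough for cancellation to matter.
    """
    tau = np.asarray(tau, dtype=float)
    if theta == 0.0:
        return tau.copy(), tau * tau / 2.0
    x = theta * tau
    small = x < 1e-3
    phi1_f = -np.expm1(-x) / theta
    phi1 = np.where(small, tau * (1 - x / 2 + x * x / 6 - x ** 3 / 24), phi1_f)
    phi2 = np.where(small, tau * tau * (0.5 - x / 6 + x * x / 24),
                    (tau - phi1_f) / theta)
    return phi1, phi2


def _psi(theta: float, tau: np.ndarray):
    """(psi1, psi2) for the confluent kernel (tau-s)*e^{-theta(tau-s)}:

    psi1 = int_0^tau u e^{-theta u} du,
    psi2 = int_0^tau e^{-theta(tau-s)} (tau-s) s ds = tau*psi1 - int u^2 e^{-theta u} du.
    """
    tau = np.asarray(tau, dtype=float)
    if theta == 0.0:
        return tau**2 / 2.0, tau**3 / 6.0
    x = theta * tau
    small = x < 1e-3
    ex = np.exp(-x)
    psi1 = np.where(small, tau**2 * (0.5 - x / 3 + x * x / 8),
                    (1.0 - (1.0 + x) * ex) / theta**2)
    i2 = np.where(small, tau**3 * (1 / 3 - x / 4 + x * x / 10),
                  (2.0 - ex * (x * x + 2 * x + 2.0)) / theta**3)
    return psi1, tau * psi1 - i2


def _exp_conv(theta: float, input_fn: InputFunction, t_eval: np.ndarray,
              confluent: bool = False):
    """Exact C1(t) = int_0^t e^{-theta(t-s)} Cp(s) ds at requested times.

    With ``confluent`` also returns C2(t) = int (t-s) e^{-theta(t-s)} Cp ds.
    Cp is piecewise linear on the input knots, zero before the first knot and
    constant after the last; both integrals are closed-form per segment, so
    the only error is floating point.  Per-segment quantities are vectorised;
    only the O(n_knots) state recursion is a scalar loop.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    kt, kv = input_fn.knot_time, input_fn.knot_value
    n = kt.size

    # per-segment linear coefficients and propagation factors
    dt = np.diff(kt)
    a = kv[:-1]
    b = np.diff(kv) / dt if n > 1 else np.empty(0)
    E = np.exp(-theta * dt)
    p1, p2 = _phi(theta, dt)
    L1 = a * p1 + b * p2
    if confluent:
        q1, q2 = _psi(theta, dt)
        L2 = a * q1 + b * q2

    # state recursion at the knots: C(t_{j+1}) = C(t_j) e^{-theta dt} + local
    C1 = np.zeros(n)
    c = 0.0
    if confluent:
        C2 = np.zeros(n)
        c2 = 0.0
        for j in range(n - 1):
            c2 = E[j] * (c2 + dt[j] * c) + L2[j]
            c = c * E[j] + L1[j]
            C1[j + 1] = c
            C2[j + 1] = c2
    else:
        for j in range(n - 1):
            c = c * E[j] + L1[j]
            C1[j + 1] = c

    # place each eval time inside its segment (zero before the first knot,
    # constant-input tail after the last)
    idx = np.searchsorted(kt, t_eval, side="right") - 1
    out1 = np.zeros_like(t_eval)
    mid = (idx >= 0) & (idx < n - 1)
    last = idx >= n - 1
    j = idx[mid]
    tau_m = t_eval[mid] - kt[j]
    e_m = np.exp(-theta * tau_m)
    pm1, pm2 = _phi(theta, tau_m)
    out1[mid] = C1[j] * e_m + a[j] * pm1 + b[j] * pm2
    tau_l = t_eval[last] - kt[-1]
    e_l = np.exp(-theta * tau_l)
    pl1, _ = _phi(theta, tau_l)
    out1[last] = C1[-1] * e_l + kv[-1] * pl1
    if not confluent:
        return out1
    out2 = np.zeros_like(t_eval)
    qm1, qm2 = _psi(theta, tau_m)
    out2[mid] = e_m * (C2[j] + tau_m * C1[j]) + a[j] * qm1 + b[j] * qm2
    ql1, _ = _psi(theta, tau_l)
    out2[last] = e_l * (C2[-1] + tau_l * C1[-1]) + kv[-1] * ql1
    return out1, out2


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def _tissue_1t(K1: float, k2: float, input_fn: InputFunction, times) -> np.ndarray:
    return K1 * _exp_conv(k2, input_fn, np.asarray(times, dtype=float))


def _tissue_2t(K1: float, k2: float, k3: float, k4: float,
               input_fn: InputFunction, times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    disc = max(disc, 0.0)
    root = np.sqrt(disc)
    th1 = (s - root) / 2.0
    th2 = (s + root) / 2.0
    if root <= 1e-9 * max(s, 1e-30):
        # repeated eigenvalue: h(t) = K1 e^{-th t} (1 + (k3 + k4 - th) t)
        th = s / 2.0
        c1, c2 = _exp_conv(th, input_fn, times, confluent=True)
        return K1 * (c1 + (k3 + k4 - th) * c2)
    A = K1 * (k3 + k4 - th1) / (th2 - th1)
    B = K1 * (th2 - k3 - k4) / (th2 - th1)
    return A * _exp_conv(th1, input_fn, times) + B * _exp_conv(th2, input_fn, times)


def _blood_curve(blood, input_fn):
    return input_fn if blood is None else blood


def solve_1tcm(params: KineticParams1T, input_fn: InputFunction, times,
               blood: InputFunction | None = None) -> np.ndarray:
    """Model PET signal Cm = (1-vB)*Ct + vB*Cb at the requested times.

    ``blood`` is the curve used for the vascular term; when omitted the
    input function itself is used.
    """
    times = np.asarray(times, dtype=float)
    ct = _tissue_1t(params.K1, params.k2, input_fn, times)
    cb = _blood_curve(blood, input_fn)
    return (1.0 - params.vB) * ct + params.vB * cb(times)


def solve_2tcm(params: KineticParams2T, input_fn: InputFunction, times,
               blood: InputFunction | None = None) -> np.ndarray:
    """2TCM analogue of :func:`solve_1tcm`; handles the repeated-root case."""
    times = np.asarray(times, dtype=float)
    ct = _tissue_2t(params.K1, params.k2, params.k3, params.k4, input_fn, times)
    cb = _blood_curve(blood, input_fn)
    return (1.0 - params.vB) * ct + params.vB * cb(times)


def model_tac(params, input_fn: InputFunction, schedule: FrameSchedule,
              blood: InputFunction | None = None, sampling: str = "midpoint",
              dt: float = 0.05) -> np.ndarray:
    """Model TAC on a frame schedule.

    ``sampling='midpoint'`` evaluates Cm at frame mid-times (the common TAC
    convention); ``'average'`` integrates Cm over each frame on an internal
    grid of step ``dt`` minutes and divides by the frame duration, matching
    how a scanner actually bins counts.
    """
    solve = solve_1tcm if isinstance(params, KineticParams1T) else solve_2tcm
    if sampling == "midpoint":
        return solve(params, input_fn, schedule.frame_mid, blood=blood)
    if sampling != "average":
        raise ValueError("sampling must be 'midpoint' or 'average'")
    # one dense solve over the whole scan, then per-frame trapezoid averages
    end = schedule.frame_end[-1]
    grid = np.union1d(np.arange(0.0, end + dt / 2, dt),
                      np.union1d(schedule.frame_start, schedule.frame_end))
    vals = solve(params, input_fn, grid, blood=blood)
    out = np.empty(schedule.n_frames)
    for i, (s, e) in enumerate(zip(schedule.frame_start, schedule.frame_end)):
        sel = (grid >= s - 1e-12) & (grid <= e + 1e-12)
        out[i] = np.trapezoid(vals[sel], grid[sel]) / (e - s)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Kinetic fit output: estimates, uncertainty, fit-quality criteria."""

    model: str                     # "1tcm" | "2tcm"
    params: KineticParams1T | KineticParams2T
    param_names: tuple             # free parameters, in fit order
    estimates: np.ndarray
    se: np.ndarray                 # standard error per free parameter
    pcov_percent: np.ndarray       # 100 * se / |estimate|
    vt: float
    vt_se: float
    vt_pcov_percent: float
    wrss: float
    chi2: float
    aic: float
    n_frames: int
    converged: bool
    fitted_curve: np.ndarray

    def as_dict(self) -> dict:
        d = {"model": self.model, "vt": self.vt, "vt_pcov": self.vt_pcov_percent,
             "wrss": self.wrss, "chi2": self.chi2, "aic": self.aic,
             "converged": self.converged}
        for name in ("K1", "k2", "k3", "k4", "vB"):
            d[name] = getattr(self.params, name, np.nan)
        for name, se, pc in zip(self.param_names, self.se, self.pcov_percent):
            d[f"se_{name}"] = se
            d[f"pcov_{name}"] = pc
        return d


def compute_vt(params) -> float:
    """Total distribution volume: K1/k2, times (1 + k3/k4) for the 2TCM."""
    if params.k2 <= 0:
        raise ValueError("Vt undefined for k2 <= 0")
    if isinstance(params, KineticParams1T):
        return params.K1 / params.k2
    if params.k4 <= 0:
        raise ValueError("irreversible limit, Vt undefined (k4 = 0)")
    return (params.K1 / params.k2) * (1.0 + params.k3 / params.k4)


def _vt_gradient(params, names) -> np.ndarray:
    """d(Vt)/d(free params) for delta-method error propagation."""
    g = {"vB": 0.0}
    if isinstance(params, KineticParams1T):
        g["K1"] = 1.0 / params.k2
        g["k2"] = -params.K1 / params.k2**2
    else:
        vt = compute_vt(params)
        g["K1"] = vt / params.K1 if params.K1 > 0 else 1.0 / params.k2 * (1 + params.k3 / params.k4)
        g["k2"] = -vt / params.k2
        g["k3"] = params.K1 / (params.k2 * params.k4)
        g["k4"] = -params.K1 * params.k3 / (params.k2 * params.k4**2)
    return np.array([g[n] for n in names])


def _weights(scheme, schedule: FrameSchedule, n: int) -> np.ndarray:
    if scheme == "frame_duration":
        if schedule is None:
            raise ValueError("frame_duration weighting needs a schedule")
        d = schedule.frame_duration
        return d / d.sum()
    if scheme == "uniform":
        return np.full(n, 1.0 / n)
    raise ValueError("weights must be 'uniform' or 'frame_duration'")


def fit_model(tac: TimeActivityCurve, input_fn: InputFunction, model: str,
              schedule: FrameSchedule | None = None,
              vb_policy: VbPolicy = VbPolicy.fixed(0.03),
              init: dict | None = None, weights: str = "frame_duration",
              blood: InputFunction | None = None,
              sampling: str = "midpoint") -> FitResult:
    """Weighted nonlinear least-squares fit of a compartment model to a TAC.

    Parameters
    ----------
    model : "1tcm" or "2tcm".
    vb_policy : fix vB (default 3%) or fit it within [0, 0.2].
    init : optional overrides of the default starting values
        (K1=0.5, k2=0.035, k3=0.01, k4=0.01).
    weights : "frame_duration" (w_i proportional to frame length, the
        dynamic-PET count-statistics surrogate) or "uniform".
    sampling : how the model TAC is sampled on frames (see ``model_tac``).

    Non-convergence is reported through ``converged=False`` with the last
    iterate; a singular Gauss-Newton matrix yields infinite SE/%COV for the
    affected parameters rather than an exception.
    """
    if model not in ("1tcm", "2tcm"):
        raise ValueError("model must be '1tcm' or '2tcm'")
    if schedule is None:
        raise ValueError("fit_model requires the frame schedule")
    if not tac.matches(schedule):
        raise ValueError("TAC and schedule disagree on frame timing")

    y = tac.activity
    n = y.size
    w = _weights(weights, schedule, n)
    sw = np.sqrt(w)

    start = dict(DEFAULT_INIT)
    start.update(init or {})
    rate_names = ("K1", "k2") if model == "1tcm" else ("K1", "k2", "k3", "k4")
    names = list(rate_names)
    lo = [0.0] * len(names)
    hi = [np.inf] * len(names)
    x0 = [start[nm] for nm in names]
    if vb_policy.mode == "free":
        names.append("vB")
        lo.append(0.0)
        hi.append(0.2)
        x0.append(min(max(start["vB"], 0.0), 0.2))

    cls = KineticParams1T if model == "1tcm" else KineticParams2T

    def make_params(x):
        kw = dict(zip(names, x))
        if vb_policy.mode == "fixed":
            kw["vB"] = vb_policy.fixed_value
        return cls(**kw)

    def resid(x):
        curve = model_tac(make_params(x), input_fn, schedule, blood=blood,
                          sampling=sampling)
        return sw * (curve - y)

    sol = least_squares(resid, x0=np.asarray(x0, dtype=float),
                        bounds=(lo, hi), method="trf", x_scale="jac",
                        xtol=1e-8, ftol=1e-10, gtol=1e-10,
                        max_nfev=200 * (len(names) + 1))
    est = sol.x
    params = make_params(est)
    fitted = model_tac(params, input_fn, schedule, blood=blood, sampling=sampling)
    wrss = float(np.sum(w * (fitted - y) ** 2))
    p = len(names)
    dof = max(n - p, 1)
    sigma2 = wrss / dof

    # Gauss-Newton covariance from the Jacobian at the solution
    J = sol.jac
    JtJ = J.T @ J
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
        if np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.inf)
        se = np.full(p, np.inf)
    rank = np.linalg.matrix_rank(JtJ)
    if rank < p:
        se = np.full(p, np.inf)
        cov = np.full((p, p), np.inf)

    with np.errstate(divide="ignore", invalid="ignore"):
        pcov = 100.0 * se / np.abs(est)
    pcov = np.where(np.abs(est) > 0, pcov, np.inf)

    try:
        vt = compute_vt(params)
        gvt = _vt_gradient(params, names)
        var_vt = float(gvt @ cov @ gvt) if np.all(np.isfinite(cov)) else np.inf
        vt_se = np.sqrt(var_vt) if var_vt >= 0 else np.inf
        vt_pcov = 100.0 * vt_se / abs(vt) if vt != 0 else np.inf
    except ValueError:
        vt, vt_se, vt_pcov = np.nan, np.nan, np.nan

    chi2, aic = _criteria(wrss, n, p)
    return FitResult(model=model, params=params, param_names=tuple(names),
                     estimates=est, se=se, pcov_percent=pcov,
                     vt=vt, vt_se=vt_se, vt_pcov_percent=vt_pcov,
                     wrss=wrss, chi2=chi2, aic=aic, n_frames=n,
                     converged=bool(sol.success), fitted_curve=fitted)


def _criteria(wrss: float, n: int, p: int):
    chi2 = wrss / max(n - p, 1)
    if wrss <= 0:
        warnings.warn("zero residual sum of squares; AIC reported as -inf")
        return chi2, -np.inf
    aic = n * np.log(wrss / n) + 2 * p
    return chi2, float(aic)


def model_criteria(fit: FitResult):
    """(reduced chi^2, AIC) of a completed fit.

    chi2 = wrss/(n-p); AIC = n*ln(wrss/n) + 2p with n the frame count and p
    the number of free parameters.
    """
    return _criteria(fit.wrss, fit.n_frames, len(fit.param_names))
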