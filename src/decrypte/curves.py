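"""Four-parameter log-logistic dose-response fitting.

Protein intensities are first expressed as ratios to the mean vehicle
(DMSO) intensity, then the sigmoid

    Y(x) = (t - b) / (1 + 10**(s * (x - x0))) + b

is fitted by bounded nonlinear least squares, where ``x`` is log10 of the
dose in nM, ``t`` is the low-dose plateau, ``b`` the high-dose plateau,
``s >= 0`` the slope between the plateaus and ``x0`` the inflection point
on the log10(nM) scale.  The potency is reported as
``pEC50 = 9 - x0`` (i.e. -log10 of the EC50 in molar units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "RatioSeries",
    "FitResult",
    "CurveMetrics",
    "llogistic4",
    "llogistic4_auc",
    "normalize_to_vehicle",
    "fit_llogistic4",
    "fit_llogistic4_batch",
    "curve_metrics",
]

_LN10 = np.log(10.0)

# optimizer bounds: plateaus in (0, 100], slope in [0, 10],
# inflection allowed two decades beyond the tested range
PLATEAU_MAX = 100.0
SLOPE_MAX = 10.0
X0_MARGIN = 2.0
_PLATEAU_MIN = 1e-6


def llogistic4(x, t, b, s, x0):
    """Evaluate the four-parameter log-logistic model at log10-dose ``x``."""
    x = np.asarray(x, dtype=float)
    return (t - b) / (1.0 + np.power(10.0, s * (x - x0))) + b


def llogistic4_auc(t: float, b: float, s: float, x0: float,
                   x_lo: float, x_hi: float) -> float:
    """Closed-form integral of the model over ``[x_lo, x_hi]``.

    The antiderivative of 1/(1+10**(s*(x-x0))) is
    x - ln(1 + 10**(s*(x-x0))) / (s * ln 10).
    """
    if x_hi < x_lo:
        raise ValueError("x_hi must be >= x_lo")
    if s == 0.0:
        # 10**0 == 1 everywhere: constant level (t+b)/2
        return 0.5 * (t + b) * (x_hi - x_lo)

    def antideriv(x: float) -> float:
        z = s * (x - x0) * _LN10
        # log1p(exp(z)) computed stably for large z
        log_term = z + np.log1p(np.exp(-z)) if z > 0 else np.log1p(np.exp(z))
        return (t - b) * (x - log_term / (s * _LN10)) + b * x

    return antideriv(x_hi) - antideriv(x_lo)


@dataclass
class RatioSeries:
    """One protein x drug dose series normalized to the vehicle mean.

    ``x`` is log10(dose in nM), strictly increasing; ``y`` are intensity
    ratios with NaN marking non-quantified doses.
    """

    x: np.ndarray
    y: np.ndarray
    n_vehicle: int
    fittable: bool = True

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")

    @property
    def n_quantified(self) -> int:
        return int(np.isfinite(self.y).sum())


@dataclass
class FitResult:
    """Optimized sigmoid parameters; NaN-filled sentinel when unfittable."""

    t: float
    b: float
    s: float
    x0: float
    converged: bool
    sse: float = np.nan
    n_points: int = 0

    @property
    def pec50_molar(self) -> float:
        # doses are in nM: log10(M) = x0 - 9
        return 9.0 - self.x0

    @property
    def fittable(self) -> bool:
        return np.isfinite(self.t)

    def predict(self, x):
        return llogistic4(x, self.t, self.b, self.s, self.x0)

    @classmethod
    def unfittable(cls) -> "FitResult":
        return cls(np.nan, np.nan, np.nan, np.nan, converged=False)


@dataclass
class CurveMetrics:
    """Descriptive curve parameters reported alongside the fit."""

    auc: float
    r2: float
    mad: float
    curve_fold_change: float
    linear_slope: float

    @classmethod
    def unfittable(cls) -> "CurveMetrics":
        return cls(np.nan, np.nan, np.nan, np.nan, np.nan)


def normalize_to_vehicle(intensities: Sequence[float],
                         doses_nM: Sequence[float],
                         vehicle_intensities: Sequence[float]) -> RatioSeries:
    """Divide per-dose intensities by the mean vehicle intensity.

    All-vehicle-missing series are returned with ``fittable=False``
    rather than raising: downstream stages treat them as not-regulated.
    """
    doses = np.asarray(doses_nM, dtype=float)
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be positive and strictly increasing")
    inten = np.asarray(intensities, dtype=float)
    veh = np.asarray(vehicle_intensities, dtype=float)
    veh = veh[np.isfinite(veh)]
    x = np.log10(doses)
    if veh.size == 0:
        return RatioSeries(x=x, y=np.full(doses.shape, np.nan),
                           n_vehicle=0, fittable=False)
    ref = float(veh.mean())
    return RatioSeries(x=x, y=inten / ref, n_vehicle=int(veh.size))


def _resid_jac(x: np.ndarray, y: np.ndarray):
    def resid(p):
        t, b, s, x0 = p
        return (t - b) / (1.0 + 10.0 ** (s * (x - x0))) + b - y

    def jac(p):
        t, b, s, x0 = p
        u = 10.0 ** (s * (x - x0))
        denom = 1.0 + u
        g = 1.0 / denom
        # d/ds and d/dx0 via the logistic derivative
        core = -(t - b) * u / (denom * denom) * _LN10
        J = np.empty((x.size, 4))
        J[:, 0] = g
        J[:, 1] = 1.0 - g
        J[:, 2] = core * (x - x0)
        J[:, 3] = core * (-s)
        return J

    return resid, jac


def _batch_model_jac(x: np.ndarray, P: np.ndarray):
    """Predictions (n, m) and Jacobian (n, m, 4) for parameter block P."""
    t = P[:, 0:1]
    b = P[:, 1:2]
    s = P[:, 2:3]
    x0 = P[:, 3:4]
    u = np.power(10.0, s * (x[None, :] - x0))
    denom = 1.0 + u
    g = 1.0 / denom
    pred = (t - b) * g + b
    core = -(t - b) * u / (denom * denom) * _LN10
    J = np.empty(pred.shape + (4,))
    J[:, :, 0] = g
    J[:, :, 1] = 1.0 - g
    J[:, :, 2] = core * (x[None, :] - x0)
    J[:, :, 3] = core * (-s)
    return pred, J


def _batch_lm(x: np.ndarray, Y: np.ndarray, W: np.ndarray, P0: np.ndarray,
              lo: np.ndarray, hi: np.ndarray,
              n_iter: int = 150, ftol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Projected Levenberg-Marquardt on a whole block of curves at once.

    ``W`` zero-weights missing points; steps leaving the box are clipped
    back onto it.  Returns (parameters, weighted SSE) per curve.
    """
    P = np.clip(P0, lo, hi)
    lam = np.full(len(P), 1e-3)
    pred, J = _batch_model_jac(x, P)
    r = (pred - Y) * W
    sse = np.einsum("ni,ni->n", r, r)
    eye = np.eye(4)
    stall = np.zeros(len(P), dtype=int)
    for _ in range(n_iter):
        Jw = J * W[:, :, None]
        A = np.einsum("nij,nik->njk", Jw, Jw)
        g = np.einsum("nij,ni->nj", Jw, r)
        # active-set projection: a parameter pinned at a bound whose
        # gradient points outward is frozen, so the others still move
        active = ((P <= lo + 1e-12) & (g > 0)) | ((P >= hi - 1e-12) & (g < 0))
        free = (~active).astype(float)
        A = A * free[:, :, None] * free[:, None, :]
        g = g * free
        diag = np.einsum("njj->nj", A)
        M = A + lam[:, None, None] * (diag[:, :, None] * eye[None]) \
            + 1e-12 * eye[None]
        M[:, range(4), range(4)] += active.astype(float)
        try:
            delta = -np.linalg.solve(M, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover
            M = M + 1e-8 * eye[None]
            delta = -np.linalg.solve(M, g[:, :, None])[:, :, 0]
        trial = np.clip(P + delta, lo, hi)
        pred_t, J_t = _batch_model_jac(x, trial)
        r_t = (pred_t - Y) * W
        sse_t = np.einsum("ni,ni->n", r_t, r_t)
        # rows stalled for several rounds are frozen for good, which keeps
        # every curve's trajectory independent of the rest of the block
        frozen = stall >= 6
        better = (sse_t < sse) & ~frozen
        P[better] = trial[better]
        r[better] = r_t[better]
        J[better] = J_t[better]
        improved = np.where(better, sse - sse_t, 0.0)
        sse = np.where(better, sse_t, sse)
        lam = np.where(frozen, lam,
                       np.clip(np.where(better, lam * 0.4, lam * 3.0),
                               1e-10, 1e8))
        # a rejected step just shrinks the trust region; only real progress
        # resets the stall counter
        stall = np.where(frozen, stall,
                         np.where(improved > ftol * (sse + 1e-30), 0,
                                  stall + 1))
        if np.all(stall >= 6):
            break
    return P, sse


def fit_llogistic4_batch(x: np.ndarray, Y: np.ndarray,
                         min_points: int = 4) -> pd.DataFrame:
    """Fit many curves sharing one log-dose grid.

    ``Y`` is (n_curves, n_doses) with NaN for missing points.  Runs a
    deterministic multi-start (inflection swept across the tested range
    plus a flat start) of a vectorized projected Levenberg-Marquardt and
    polishes near-perfect fits with a tight scalar pass.  Curves with
    fewer than ``min_points`` quantified doses come back as NaN
    sentinels.  Returns a DataFrame with columns t, b, s, x0, pec50,
    converged, fittable, sse, n_points.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    W = np.isfinite(Y).astype(float)
    n_points = W.sum(axis=1).astype(int)
    ok = n_points >= min_points
    Yz = np.where(np.isfinite(Y), Y, 0.0)

    lo = np.array([_PLATEAU_MIN, _PLATEAU_MIN, 0.0, x.min() - X0_MARGIN])
    hi = np.array([PLATEAU_MAX, PLATEAU_MAX, SLOPE_MAX, x.max() + X0_MARGIN])

    # data-driven plateau starts: first/last quantified point
    first_idx = np.argmax(W > 0, axis=1)
    last_idx = m - 1 - np.argmax(W[:, ::-1] > 0, axis=1)
    t0 = np.clip(Yz[np.arange(n), first_idx], _PLATEAU_MIN, PLATEAU_MAX)
    b0 = np.clip(Yz[np.arange(n), last_idx], _PLATEAU_MIN, PLATEAU_MAX)
    with np.errstate(invalid="ignore"):
        mean_y = np.where(n_points > 0, Yz.sum(axis=1) / np.maximum(n_points, 1), 1.0)
    c0 = np.clip(mean_y, _PLATEAU_MIN, PLATEAU_MAX)

    best_P = None
    best_sse = None
    x0_starts = list(np.linspace(x.min(), x.max(), 3))
    for kind, x0_start in [("edge", x0_starts[0]), ("edge", x0_starts[1]),
                           ("edge", x0_starts[2]), ("flat", x0_starts[1])]:
        if kind == "edge":
            P0 = np.column_stack([t0, b0, np.ones(n), np.full(n, x0_start)])
        else:
            P0 = np.column_stack([c0, c0, np.ones(n), np.full(n, x0_start)])
        P, sse = _batch_lm(x, Yz, W, P0, lo, hi)
        if best_P is None:
            best_P, best_sse = P, sse
        else:
            better = sse < best_sse - 1e-15
            best_P[better] = P[better]
            best_sse = np.where(better, sse, best_sse)

    # one restart from the winner with fresh damping: escapes the rare
    # stall where a clipped step stopped making progress
    P, sse = _batch_lm(x, Yz, W, best_P, lo, hi)
    better = sse < best_sse - 1e-15
    best_P[better] = P[better]
    best_sse = np.where(better, sse, best_sse)

    # tight scalar polish for (near-)noiseless curves
    polish = ok & (best_sse < 1e-6) & (best_sse > 0)
    for i in np.flatnonzero(polish):
        mask = W[i] > 0
        resid, jac = _resid_jac(x[mask], Y[i, mask])
        sol = least_squares(resid, best_P[i], jac=jac, bounds=(lo, hi),
                            method="trf", xtol=1e-15, ftol=1e-15,
                            gtol=1e-15, max_nfev=400)
        sse = float(np.sum(sol.fun ** 2))
        if sse <= best_sse[i]:
            best_P[i] = sol.x
            best_sse[i] = sse

    out = pd.DataFrame(best_P, columns=["t", "b", "s", "x0"])
    out["pec50"] = 9.0 - out["x0"]
    out["sse"] = best_sse
    out["n_points"] = n_points
    out["fittable"] = ok
    out["converged"] = ok
    out.loc[~ok, ["t", "b", "s", "x0", "pec50", "sse"]] = np.nan
    out.loc[~ok, "converged"] = False
    return out


def fit_llogistic4(series: RatioSeries, min_points: int = 4) -> FitResult:
    """Bounded least-squares fit of the four-parameter log-logistic model.

    Requires ``min_points`` quantified doses (default 4, one per free
    parameter); otherwise an NaN sentinel with ``converged=False`` is
    returned.  The multi-start batch engine does the heavy lifting; a
    final bounded trust-region pass polishes the winning start, so the
    result never depends on input order.
    """
    if not series.fittable:
        return FitResult.unfittable()
    mask = np.isfinite(series.y)
    if int(mask.sum()) < min_points:
        return FitResult.unfittable()
    row = fit_llogistic4_batch(series.x, series.y[None, :],
                               min_points=min_points).iloc[0]

    # always polish the scalar path: single-curve callers care about digits
    x = series.x[mask]
    y = series.y[mask]
    lo = np.array([_PLATEAU_MIN, _PLATEAU_MIN, 0.0,
                   series.x.min() - X0_MARGIN])
    hi = np.array([PLATEAU_MAX, PLATEAU_MAX, SLOPE_MAX,
                   series.x.max() + X0_MARGIN])
    resid, jac = _resid_jac(x, y)
    p0 = row[["t", "b", "s", "x0"]].to_numpy(dtype=float)
    sol = least_squares(resid, np.clip(p0, lo, hi), jac=jac, bounds=(lo, hi),
                        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                        max_nfev=400)
    sse = float(np.sum(sol.fun ** 2))
    if sse <= row["sse"]:
        t, b, s, x0 = (float(v) for v in sol.x)
    else:  # pragma: no cover - polish should not regress
        t, b, s, x0 = (float(row[k]) for k in ("t", "b", "s", "x0"))
        sse = float(row["sse"])
    return FitResult(t=t, b=b, s=s, x0=x0, converged=True,
                     sse=sse, n_points=int(mask.sum()))


def curve_metrics_batch(x: np.ndarray, Y: np.ndarray,
                        fits: pd.DataFrame) -> pd.DataFrame:
    """Vectorized descriptive metrics for a block of fitted curves.

    Mirrors :func:`curve_metrics` column-for-column; rows whose fit is a
    NaN sentinel stay NaN throughout.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    W = np.isfinite(Y)
    Yz = np.where(W, Y, 0.0)
    t = fits["t"].to_numpy()
    b = fits["b"].to_numpy()
    s = fits["s"].to_numpy()
    x0 = fits["x0"].to_numpy()
    x_lo, x_hi = float(x.min()), float(x.max())

    def antideriv(xv: float) -> np.ndarray:
        z = s * (xv - x0) * _LN10
        # stable log(1 + exp(z))
        log_term = np.where(z > 0, z, 0.0) + np.log1p(np.exp(-np.abs(z)))
        with np.errstate(divide="ignore", invalid="ignore"):
            return (t - b) * (xv - log_term / (s * _LN10)) + b * xv

    with np.errstate(divide="ignore", invalid="ignore"):
        auc = antideriv(x_hi) - antideriv(x_lo)
    flat = s == 0.0
    auc = np.where(flat, 0.5 * (t + b) * (x_hi - x_lo), auc)

    pred = llogistic4(x[None, :], t[:, None], b[:, None], s[:, None],
                      x0[:, None])
    resid = np.where(W, Yz - pred, 0.0)
    n_obs = W.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mad = np.abs(resid).sum(axis=1) / n_obs
        ybar = Yz.sum(axis=1) / n_obs
    ss_res = (resid ** 2).sum(axis=1)
    ss_tot = (np.where(W, Yz - ybar[:, None], 0.0) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    cfc = llogistic4(x_hi, t, b, s, x0)

    # OLS slope over quantified points
    Sx = (W * x[None, :]).sum(axis=1)
    Sy = Yz.sum(axis=1)
    Sxx = (W * x[None, :] ** 2).sum(axis=1)
    Sxy = (Yz * x[None, :]).sum(axis=1)
    denom = n_obs * Sxx - Sx ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where((n_obs >= 2) & (denom > 0),
                         (n_obs * Sxy - Sx * Sy) / denom, np.nan)

    out = pd.DataFrame({"auc": auc, "r2": r2, "mad": mad,
                        "curve_fold_change": cfc, "linear_slope": slope})
    bad = ~np.isfinite(t)
    out.loc[bad, :] = np.nan
    return out


def curve_metrics(fit: FitResult, series: RatioSeries) -> CurveMetrics:
    """Area under the fitted curve, goodness of fit and end-of-curve ratio.

    The AUC integrates the fitted ratio itself (no baseline subtraction)
    over the tested log-dose range; R^2 and the mean absolute residual
    use quantified points only.  Zero-variance series leave R^2 undefined
    (NaN), never 1.
    """
    if not fit.fittable:
        return CurveMetrics.unfittable()
    mask = np.isfinite(series.y)
    x = series.x[mask]
    y = series.y[mask]
    x_lo, x_hi = float(series.x.min()), float(series.x.max())

    auc = llogistic4_auc(fit.t, fit.b, fit.s, fit.x0, x_lo, x_hi)
    pred = fit.predict(x)
    resid = y - pred
    mad = float(np.mean(np.abs(resid)))
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = np.nan if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    cfc = float(fit.predict(x_hi))
    if x.size >= 2 and np.ptp(x) > 0:
        slope = float(np.polyfit(x, y, 1)[0])
    else:
        slope = np.nan
    return CurveMetrics(auc=float(auc), r2=r2, mad=mad,
                        curve_fold_change=cfc, linear_slope=slope)
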