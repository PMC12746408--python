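"""Voxel-wise T1, T2 and ADC estimation and ROI analysis.

T1 maps come from mono-exponential magnitude inversion-recovery fitting
with polarity restoration, T2 maps from mono-exponential CPMG fitting, and
ADC maps from log-linear regression of signal on b-value — mirroring how
quantitative phantom measurements are analysed.

The nonlinear fits exploit the model structure ``S = m0 * g(theta, t)``:
for fixed decay parameter theta the optimal amplitude is a linear
projection, so the sum of squares can be profiled down to a 1-D function
of theta.  That profile is minimized by a coarse log-spaced grid followed
by a vectorized golden-section refinement, which runs whole images at once
and recovers noiseless parameters to machine precision.

Magnitude IR data lose the sign of the longitudinal magnetization before
the null point.  Polarity is restored exhaustively: for each candidate
null index k the first k samples are sign-flipped, the signed model is
fitted, and the minimum-SSE candidate wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward_models import TissueTarget
from .simulator import CpmgProtocol, DwiProtocol, ImageSeries, IrProtocol

__all__ = [
    "ParametricMap",
    "RoiReport",
    "ValidationReport",
    "fit_t1_ir",
    "fit_t2_cpmg",
    "fit_adc_loglinear",
    "compute_maps",
    "roi_mean",
    "validate_against_targets",
]

#: Mask threshold: voxels whose first-frame signal is below this fraction of
#: the series-wide maximum are treated as background and not fitted.
MASK_THRESHOLD = 0.05

_T1_BOUNDS = (5.0, 20000.0)  # ms
_T2_BOUNDS = (1.0, 10000.0)  # ms
_GRID_POINTS = 96
_GOLDEN_ITERS = 40  # Gauss-Newton polish follows; no need to exhaust the bracket


# ---------------------------------------------------------------------------
# profiled 1-D least squares machinery
# ---------------------------------------------------------------------------

def _profile_sse(Y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SSE and optimal amplitude of ``Y ~ amp * G`` row-wise.

    ``Y``: (nv, npts) data; ``G``: (nv, npts) model shapes.  Returns
    (sse, amp) each of shape (nv,).
    """
    num = np.einsum("ij,ij->i", Y, G)
    den = np.einsum("ij,ij->i", G, G)
    den = np.where(den <= 0, np.finfo(float).tiny, den)
    amp = num / den
    sse = np.einsum("ij,ij->i", Y, Y) - num * amp
    return np.maximum(sse, 0.0), amp


def _fit_profiled(Y: np.ndarray, t: np.ndarray, model, dmodel,
                  bounds: tuple[float, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimize the profiled SSE over theta for every row of ``Y``.

    ``model(theta, t)`` must broadcast theta of shape (nv, 1) against t of
    shape (npts,) to a (nv, npts) array; ``dmodel`` is its derivative with
    respect to theta.  A coarse log grid brackets the minimum, a golden
    section narrows it, and a few Gauss-Newton steps on the residuals
    polish the estimate to machine precision (direct SSE minimization
    alone is limited to ~sqrt(eps) relative accuracy in theta).
    Returns (theta, amp, sse).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    log_grid = np.linspace(np.log(bounds[0]), np.log(bounds[1]), _GRID_POINTS)
    sse_grid = np.empty((len(log_grid), Y.shape[0]))
    for i, lg in enumerate(log_grid):
        G = model(np.full((Y.shape[0], 1), np.exp(lg)), t)
        sse_grid[i], _ = _profile_sse(Y, G)
    best = np.argmin(sse_grid, axis=0)
    lo = log_grid[np.maximum(best - 1, 0)]
    hi = log_grid[np.minimum(best + 1, len(log_grid) - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    for _ in range(_GOLDEN_ITERS):
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        s1, _ = _profile_sse(Y, model(np.exp(x1)[:, None], t))
        s2, _ = _profile_sse(Y, model(np.exp(x2)[:, None], t))
        take_left = s1 < s2
        b = np.where(take_left, x2, b)
        a = np.where(take_left, a, x1)
    theta = np.exp((a + b) / 2.0)
    G = model(theta[:, None], t)
    _, amp = _profile_sse(Y, G)
    # direct residual SSE: the profiled form yy - num^2/den cancels
    # catastrophically near the optimum and cannot guide the polish
    r = amp[:, None] * G - Y
    sse = np.einsum("ij,ij->i", r, r)

    # Gauss-Newton polish on (amp, theta); revert steps that do not improve.
    for _ in range(6):
        G = model(theta[:, None], t)
        dG = dmodel(theta[:, None], t)
        J2 = amp[:, None] * dG
        r = amp[:, None] * G - Y
        a11 = np.einsum("ij,ij->i", G, G)
        a12 = np.einsum("ij,ij->i", G, J2)
        a22 = np.einsum("ij,ij->i", J2, J2)
        b1 = -np.einsum("ij,ij->i", G, r)
        b2 = -np.einsum("ij,ij->i", J2, r)
        det = a11 * a22 - a12 * a12
        safe = np.abs(det) > np.finfo(float).tiny
        d_theta = np.where(safe, (a11 * b2 - a12 * b1) / np.where(safe, det, 1.0), 0.0)
        theta_new = np.clip(theta + d_theta, bounds[0], bounds[1])
        G_new = model(theta_new[:, None], t)
        _, amp_new = _profile_sse(Y, G_new)
        r_new = amp_new[:, None] * G_new - Y
        sse_new = np.einsum("ij,ij->i", r_new, r_new)
        improve = sse_new < sse
        theta = np.where(improve, theta_new, theta)
        amp = np.where(improve, amp_new, amp)
        sse = np.where(improve, sse_new, sse)
    return theta, amp, sse


def _ir_shape(t1, ti_tr):
    ti, tr = ti_tr
    return 1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr / t1)


def _ir_shape_deriv(t1, ti_tr):
    ti, tr = ti_tr
    return (-2.0 * ti * np.exp(-ti / t1) + tr * np.exp(-tr / t1)) / t1**2


def _monoexp_shape(tau, t):
    return np.exp(-t / tau)


def _monoexp_shape_deriv(tau, t):
    return t / tau**2 * np.exp(-t / tau)


def _fit_t2_image(Y: np.ndarray, tes: np.ndarray):
    """Vectorized CPMG fit; returns (t2, m0, sse) arrays over rows of Y."""
    return _fit_profiled(Y, tes, _monoexp_shape, _monoexp_shape_deriv, _T2_BOUNDS)


def _fit_t1_image(Y: np.ndarray, tis: np.ndarray, tr: float):
    """Vectorized magnitude-IR fit with exhaustive polarity restoration.

    For each candidate null index k in 0..n the first k samples are
    negated and the signed model fitted; rows where the profiled amplitude
    comes out non-positive are invalid for that k (the global sign flip is
    the mirror solution).  Returns (t1, m0, sse, null_index).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    nv, npts = Y.shape
    model = lambda t1, t: _ir_shape(t1, (t, tr))  # noqa: E731
    dmodel = lambda t1, t: _ir_shape_deriv(t1, (t, tr))  # noqa: E731
    best_sse = np.full(nv, np.inf)
    best_t1 = np.full(nv, np.nan)
    best_m0 = np.full(nv, np.nan)
    best_k = np.zeros(nv, dtype=int)
    for k in range(npts + 1):
        Yk = Y.copy()
        Yk[:, :k] *= -1.0
        t1_k, m0_k, sse_k = _fit_profiled(Yk, tis, model, dmodel, _T1_BOUNDS)
        valid = m0_k > 0
        better = valid & (sse_k < best_sse)
        best_sse[better] = sse_k[better]
        best_t1[better] = t1_k[better]
        best_m0[better] = m0_k[better]
        best_k[better] = k
    return best_t1, best_m0, best_sse, best_k


def _fit_adc_image(Y: np.ndarray, bvals: np.ndarray):
    """Vectorized log-linear ADC fit.

    OLS of ln(signal) on b; rows with any non-positive signal are flagged
    NaN.  Returns (adc in 10^-3 mm²/s, s0, sse in log space).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    ok = np.all(Y > 0, axis=1)
    adc = np.full(Y.shape[0], np.nan)
    s0 = np.full(Y.shape[0], np.nan)
    sse = np.full(Y.shape[0], np.nan)
    if ok.any():
        logy = np.log(Y[ok])
        b = np.asarray(bvals, dtype=float)
        bc = b - b.mean()
        denom = np.sum(bc**2)
        slope = (logy @ bc) / denom
        intercept = logy.mean(axis=1) - slope * b.mean()
        resid = logy - (intercept[:, None] + slope[:, None] * b[None, :])
        adc[ok] = -slope * 1000.0
        s0[ok] = np.exp(intercept)
        sse[ok] = np.sum(resid**2, axis=1)
    return adc, s0, sse


# ---------------------------------------------------------------------------
# public scalar fitters
# ---------------------------------------------------------------------------

def fit_t1_ir(signals, tis, tr: float) -> dict:
    """Fit one magnitude IR series; returns t1 (ms), m0, residual, null_index.

    ``residual`` is the root-sum-of-squares misfit of the restored-polarity
    model.  Requires at least 3 inversion times.
    """
    signals = np.asarray(signals, dtype=float)
    tis = np.asarray(tis, dtype=float)
    if signals.ndim != 1 or signals.shape != tis.shape or len(tis) < 3:
        raise ValueError("need matching 1-D signals and >= 3 inversion times")
    t1, m0, sse, k = _fit_t1_image(signals[None, :], tis, tr)
    if not np.isfinite(t1[0]):
        raise RuntimeError("IR fit did not converge (flat or invalid series)")
    return {"t1": float(t1[0]), "m0": float(m0[0]),
            "residual": float(np.sqrt(sse[0])), "null_index": int(k[0])}


def fit_t2_cpmg(signals, tes) -> dict:
    """Fit one CPMG decay; returns t2 (ms), m0 and the residual norm."""
    signals = np.asarray(signals, dtype=float)
    tes = np.asarray(tes, dtype=float)
    if signals.ndim != 1 or signals.shape != tes.shape or len(tes) < 3:
        raise ValueError("need matching 1-D signals and >= 3 echoes")
    if np.ptp(signals) == 0 and signals.max() == 0:
        raise RuntimeError("all-zero series cannot be fitted")
    t2, m0, sse = _fit_t2_image(signals[None, :], tes)
    if not (np.isfinite(t2[0]) and m0[0] > 0):
        raise RuntimeError("CPMG fit did not converge (flat or all-noise series)")
    return {"t2": float(t2[0]), "m0": float(m0[0]),
            "residual": float(np.sqrt(sse[0]))}


def fit_adc_loglinear(signals, bvals) -> dict:
    """Log-linear ADC fit of one voxel; returns adc (10^-3 mm²/s) and s0."""
    signals = np.asarray(signals, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    if signals.ndim != 1 or signals.shape != bvals.shape or len(bvals) < 2:
        raise ValueError("need matching 1-D signals and >= 2 b-values")
    if np.any(signals <= 0):
        raise ValueError("non-positive signal; voxel cannot be log-fitted")
    adc, s0, sse = _fit_adc_image(signals[None, :], bvals)
    return {"adc": float(adc[0]), "s0": float(s0[0]),
            "residual": float(np.sqrt(sse[0]))}


# ---------------------------------------------------------------------------
# image-level mapping and ROI analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParametricMap:
    """A fitted parameter image with per-voxel fit error and validity mask."""

    kind: str  # "t1" | "t2" | "adc"
    values: np.ndarray  # ms or 10^-3 mm²/s; NaN outside mask
    fit_error: np.ndarray  # residual norm per voxel
    mask: np.ndarray  # bool; True where fitted successfully
    fov: float
    matrix: int

    @property
    def units(self) -> str:
        return "10^-3 mm^2/s" if self.kind == "adc" else "ms"


def compute_maps(series: ImageSeries, mask_threshold: float = MASK_THRESHOLD) -> ParametricMap:
    """Fit every above-threshold voxel of a series into a parametric map.

    The signal mask keeps voxels whose first-frame signal reaches
    ``mask_threshold`` times the series-wide maximum; fits that fail
    (non-positive amplitude, non-positive DWI signals) are dropped from
    the mask as well.
    """
    data = series.data
    n = series.matrix
    first = data[0]
    mask = first >= mask_threshold * float(data.max())
    Y = data[:, mask].T  # (nv, npts)
    values = np.full((n, n), np.nan)
    fit_err = np.full((n, n), np.nan)
    if isinstance(series.protocol, IrProtocol):
        kind = "t1"
        est, _, sse, _ = _fit_t1_image(Y, series.points,
                                       series.protocol.repetition_time)
    elif isinstance(series.protocol, CpmgProtocol):
        kind = "t2"
        est, amp, sse = _fit_t2_image(Y, series.points)
        est = np.where(amp > 0, est, np.nan)
    elif isinstance(series.protocol, DwiProtocol):
        kind = "adc"
        est, _, sse = _fit_adc_image(Y, series.points)
    else:
        raise TypeError(f"series/protocol mismatch: {type(series.protocol)!r}")
    vals = np.full(mask.sum(), np.nan)
    vals[:] = est
    values[mask] = vals
    fit_err[mask] = np.sqrt(sse)
    good = mask.copy()
    good[mask] = np.isfinite(vals)
    values[~good] = np.nan
    return ParametricMap(kind=kind, values=values, fit_error=fit_err,
                         mask=good, fov=series.fov, matrix=series.matrix)


def roi_mean(pmap: ParametricMap, center: tuple[float, float],
             radius: float) -> tuple[float, float]:
    """Mean and SD of a map over a circular ROI (mm coordinates).

    Only masked (successfully fitted) voxels whose centers fall inside the
    circle contribute; an empty ROI raises ``ValueError``.  The SD is the
    sample standard deviation (ddof=1), 0 for a single voxel.
    """
    if radius <= 0:
        raise ValueError("ROI radius must be positive")
    half = pmap.fov / 2.0
    if abs(center[0]) + radius > half or abs(center[1]) + radius > half:
        raise ValueError("ROI extends beyond the image")
    step = pmap.fov / pmap.matrix
    axis = (np.arange(pmap.matrix) + 0.5) * step - half
    x, y = np.meshgrid(axis, axis, indexing="xy")
    sel = ((x - center[0])**2 + (y - center[1])**2 <= radius**2) & pmap.mask
    if not sel.any():
        raise ValueError("ROI contains no fitted voxels")
    vals = pmap.values[sel]
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd


@dataclass(frozen=True)
class RoiReport:
    """Per-ROI summary of the three fitted parameters against a target."""

    name: str
    target: TissueTarget
    t1_mean: float
    t1_sd: float
    t2_mean: float
    t2_sd: float
    adc_mean: float
    adc_sd: float

    def deviations(self) -> dict[str, float]:
        """Percent deviation 100*|measured - target|/target per parameter."""
        return {
            "t1": 100.0 * abs(self.t1_mean - self.target.t1) / self.target.t1,
            "t2": 100.0 * abs(self.t2_mean - self.target.t2) / self.target.t2,
            "adc": 100.0 * abs(self.adc_mean - self.target.adc) / self.target.adc,
        }


@dataclass(frozen=True)
class ValidationReport:
    """Target-vs-measured table plus the worst deviation per parameter."""

    table: pd.DataFrame
    max_deviation: dict[str, float]


def validate_against_targets(reports) -> ValidationReport:
    """Build the target/measured/deviation table from ROI reports."""
    reports = list(reports)
    if not reports:
        raise ValueError("no ROI reports supplied")
    rows = []
    for r in reports:
        if not isinstance(r, RoiReport):
            raise ValueError("every ROI must be paired with its target (RoiReport)")
        dev = r.deviations()
        rows.append({
            "name": r.name,
            "t1_target_ms": r.target.t1, "t1_measured_ms": r.t1_mean,
            "t1_sd_ms": r.t1_sd, "t1_deviation_pct": dev["t1"],
            "t2_target_ms": r.target.t2, "t2_measured_ms": r.t2_mean,
            "t2_sd_ms": r.t2_sd, "t2_deviation_pct": dev["t2"],
            "adc_target": r.target.adc, "adc_measured": r.adc_mean,
            "adc_sd": r.adc_sd, "adc_deviation_pct": dev["adc"],
        })
    table = pd.DataFrame(rows)
    max_dev = {p: float(table[f"{p}_deviation_pct"].max()) for p in ("t1", "t2", "adc")}
    return ValidationReport(table=table, max_deviation=max_dev)
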