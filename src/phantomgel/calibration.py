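"""Estimate the forward-model coefficients from titration series.

Relaxivities are the slopes of ordinary least-squares regressions of the
relaxation rates (R1 = 1/T1, R2 = 1/T2, in s^-1) on the concentration of
the varied substance, with the other two ingredients held fixed.  The
ADC-vs-lecithin relationship is fitted as an unweighted biexponential in
natural response space by multi-start nonlinear least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .forward_models import (
    AdcModelParams,
    CalibrationSet,
    ConcentrationTriple,
    RelaxivityTable,
    SolventBaseline,
    adc_forward,
    r1_forward,
    r2_forward,
)

__all__ = [
    "DegenerateFitWarning",
    "TitrationSeries",
    "RelaxivityFit",
    "fit_relaxivity",
    "fit_adc_model",
    "build_calibration",
    "read_titration_csv",
    "write_titration_csv",
    "generate_titration_design",
    "simulate_titration_responses",
]

_SUBSTANCES = ("gd", "lecithin", "agarose")

#: Concentration grids of the characterization design: Gd-DTPA 0–0.2 mM,
#: agarose 0–4 % wt/vol, soy lecithin 0–5 % wt/vol.
DESIGN_GRIDS = {
    "gd": (0.0, 0.05, 0.1, 0.15, 0.2),
    "agarose": (0.0, 1.0, 2.0, 3.0, 4.0),
    "lecithin": (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0),
}


class DegenerateFitWarning(UserWarning):
    """The biexponential fit collapsed to (nearly) a single exponential."""


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: one substance varied, the other two held fixed.

    ``responses`` are measured R1 or R2 rates (s^-1) or ADC values
    (10^-3 mm^2/s) at the corresponding ``concentrations`` (mM for Gd,
    % wt/vol otherwise); ``response_type`` says which ("r1", "r2", "adc").
    """

    varied_substance: str
    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    response_type: str = "r1"
    background: ConcentrationTriple = ConcentrationTriple(0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.varied_substance not in _SUBSTANCES:
            raise ValueError(f"varied_substance must be one of {_SUBSTANCES}")
        if self.response_type not in ("r1", "r2", "adc"):
            raise ValueError("response_type must be 'r1', 'r2' or 'adc'")
        conc = tuple(float(c) for c in self.concentrations)
        resp = tuple(float(r) for r in self.responses)
        if len(conc) != len(resp):
            raise ValueError("concentrations and responses must have equal length")
        if len(conc) < 3:
            raise ValueError("a titration series needs at least 3 points")
        if any(c < 0 for c in conc):
            raise ValueError("concentrations must be non-negative")
        if any(b >= a for a, b in zip(conc[1:], conc[:-1])):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)


@dataclass(frozen=True)
class RelaxivityFit:
    """OLS estimate of one relaxivity: R = intercept + slope * C."""

    slope: float
    intercept: float
    slope_se: float
    r_squared: float

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared must be in [0, 1], got {self.r_squared}")
        if self.slope_se < 0:
            raise ValueError("slope_se must be non-negative")


def fit_relaxivity(series: TitrationSeries) -> RelaxivityFit:
    """Relaxivity as the OLS slope of rate on concentration.

    The intercept absorbs the solvent baseline plus the contributions of
    the fixed background ingredients.  Requires >= 3 distinct
    concentrations (enforced by :class:`TitrationSeries`).
    """
    if series.response_type not in ("r1", "r2"):
        raise ValueError("fit_relaxivity expects rate responses (r1 or r2, s^-1)")
    x = np.asarray(series.concentrations)
    y = np.asarray(series.responses)
    if np.ptp(x) == 0:
        raise ValueError("concentrations have zero variance")
    res = stats.linregress(x, y)
    return RelaxivityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0,
    )


def _biexp_residuals(theta: np.ndarray, c: np.ndarray, y: np.ndarray) -> np.ndarray:
    a1, k1, a2, k2 = theta
    return a1 * np.exp(-k1 * c) + a2 * np.exp(-k2 * c) - y


def fit_adc_model(concentrations, adcs, n_starts: int = 25,
                  degenerate_ratio: float = 1e-3) -> AdcModelParams:
    """Fit the biexponential ADC-vs-lecithin model by multi-start least squares.

    Unweighted fit in natural response space.  Starts pair decay constants
    from a log-spaced grid over [0.05, 10] (% wt/vol)^-1, with amplitudes
    initialized by linear least squares at the fixed decay constants (best
    ``n_starts`` pairs by that linear SSE are refined).  Components of the
    result are ordered so ``k_fast > k_slow``.  A fit whose fast amplitude
    is below ``degenerate_ratio`` times the slow amplitude, or whose decay
    constants nearly coincide (ill-conditioned, the two components are not
    separable), is flagged with :class:`DegenerateFitWarning`.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(adcs, dtype=float)
    if c.ndim != 1 or c.shape != y.shape:
        raise ValueError("concentrations and adcs must be equal-length 1-D sequences")
    if len(c) < 5:
        raise ValueError("need at least 5 points to constrain a biexponential")
    if np.any(y <= 0):
        raise ValueError("ADC responses must be positive")

    k_grid = np.geomspace(0.05, 10.0, 8)
    candidates = []
    for k1, k2 in product(k_grid, k_grid):
        if k1 <= k2:
            continue
        basis = np.column_stack([np.exp(-k1 * c), np.exp(-k2 * c)])
        amps, *_ = np.linalg.lstsq(basis, y, rcond=None)
        amps = np.clip(amps, 1e-8, None)
        sse = float(np.sum((basis @ amps - y) ** 2))
        candidates.append((sse, np.array([amps[0], k1, amps[1], k2])))
    candidates.sort(key=lambda t: t[0])

    lo = np.array([0.0, 1e-6, 0.0, 1e-6])
    hi = np.array([np.inf, 100.0, np.inf, 100.0])
    best = None
    for _, theta0 in candidates[:n_starts]:
        try:
            sol = least_squares(_biexp_residuals, theta0, args=(c, y),
                                bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:  # pragma: no cover - defensive
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    if best is None:
        raise RuntimeError("biexponential fit failed to converge from any start")
    sse, theta = best
    a1, k1, a2, k2 = theta
    # order components fast-first
    if k1 < k2:
        a1, k1, a2, k2 = a2, k2, a1, k1
    if a1 < degenerate_ratio * a2:
        warnings.warn(
            "fast component amplitude is negligible; the data are effectively "
            "single-exponential", DegenerateFitWarning, stacklevel=2)
    elif k2 > 0 and k1 / k2 < 1.05:
        warnings.warn(
            "decay constants nearly coincide; the two components are poorly "
            "conditioned", DegenerateFitWarning, stacklevel=2)
    floor = 1e-12
    return AdcModelParams(a_fast=max(a1, floor), k_fast=k1,
                          a_slow=max(a2, floor), k_slow=min(k2, k1 * (1 - 1e-12)))


def build_calibration(r1_gd: RelaxivityFit | None = None,
                      r2_gd: RelaxivityFit | None = None,
                      r1_lec: RelaxivityFit | None = None,
                      r2_lec: RelaxivityFit | None = None,
                      r2_agar: RelaxivityFit | None = None,
                      adc_params: AdcModelParams | None = None,
                      solvent: SolventBaseline | None = None) -> CalibrationSet:
    """Assemble a validated :class:`CalibrationSet` from fitted pieces.

    All five relaxivity fits, the ADC parameters and the solvent baseline
    are required (there is intentionally no slot for an agarose r1 — its
    longitudinal contribution is negligible in the composite gel).  A
    missing or negative piece raises ``ValueError`` naming the field.
    """
    fits = {"r1_gd": r1_gd, "r2_gd": r2_gd, "r1_lec": r1_lec,
            "r2_lec": r2_lec, "r2_agar": r2_agar}
    for name, fit in fits.items():
        if fit is None:
            raise ValueError(f"missing required relaxivity fit: {name}")
        if fit.slope < 0:
            raise ValueError(f"fitted relaxivity {name} is negative ({fit.slope:g})")
    if adc_params is None:
        raise ValueError("missing required field: adc_params")
    if solvent is None:
        raise ValueError("missing required field: solvent")
    table = RelaxivityTable(**{name: fit.slope for name, fit in fits.items()})
    return CalibrationSet(relaxivity=table, adc=adc_params, solvent=solvent)


# ---------------------------------------------------------------------------
# titration tables: CSV I/O and the synthetic characterization design
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["substance", "concentration", "response_type", "response",
                "bg_gd", "bg_lecithin", "bg_agarose"]


def write_titration_csv(series_list, path) -> None:
    """Write titration series to a delimited table (one row per point)."""
    rows = []
    for s in series_list:
        for c, r in zip(s.concentrations, s.responses):
            rows.append({
                "substance": s.varied_substance, "concentration": c,
                "response_type": s.response_type, "response": r,
                "bg_gd": s.background.c_gd, "bg_lecithin": s.background.c_lec,
                "bg_agarose": s.background.c_agar,
            })
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_titration_csv(path) -> list[TitrationSeries]:
    """Read titration series back from a CSV written by :func:`write_titration_csv`.

    Rows are grouped into one series per (substance, response_type,
    background) combination and sorted by concentration within each.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("substance", "concentration", "response_type", "response")
               if c not in df.columns]
    if missing:
        raise ValueError(f"titration table is missing columns: {missing}")
    for bg in ("bg_gd", "bg_lecithin", "bg_agarose"):
        if bg not in df.columns:
            df[bg] = 0.0
    out = []
    keys = ["substance", "response_type", "bg_gd", "bg_lecithin", "bg_agarose"]
    for (sub, rtype, g, l, a), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("concentration")
        out.append(TitrationSeries(
            varied_substance=sub,
            concentrations=tuple(grp["concentration"]),
            responses=tuple(grp["response"]),
            response_type=rtype,
            background=ConcentrationTriple(c_gd=g, c_lec=l, c_agar=a),
        ))
    return out


#: Fixed backgrounds used by the synthetic characterization design: each
#: substance is titrated over its full grid at these (other two) settings.
_DESIGN_BACKGROUNDS = {
    # varied: list of (c_gd, c_lec, c_agar) with the varied one ignored
    "lecithin": [(0.0, None, 0.0), (0.1, None, 2.0), (0.2, None, 4.0)],
    "agarose": [(0.0, 0.0, None), (0.1, 1.0, None), (0.2, 3.0, None)],
    "gd": [(None, 0.0, 0.0), (None, 2.0, 1.0)],
}


def generate_titration_design() -> pd.DataFrame:
    """The synthetic one-varied/others-fixed characterization design.

    Each substance is titrated over its full concentration grid (Gd-DTPA
    0–0.2 mM in 5 steps, agarose 0–4 % in 5 steps, lecithin 0–5 % in 7
    steps) at two or three fixed backgrounds of the other ingredients,
    giving 46 mixtures (7×3 + 5×3 + 5×2).  Returns a table with one row
    per mixture: the full composition (``c_gd, c_lecithin, c_agarose``)
    plus a ``substance`` tag naming the varied ingredient.
    """
    rows = []
    for substance, backgrounds in _DESIGN_BACKGROUNDS.items():
        for bg in backgrounds:
            g, l, a = bg
            for conc in DESIGN_GRIDS[substance]:
                rows.append({
                    "substance": substance,
                    "c_gd": conc if substance == "gd" else g,
                    "c_lecithin": conc if substance == "lecithin" else l,
                    "c_agarose": conc if substance == "agarose" else a,
                })
    return pd.DataFrame(rows)


_VARIED_COLUMN = {"gd": "c_gd", "lecithin": "c_lecithin", "agarose": "c_agarose"}


def simulate_titration_responses(design: pd.DataFrame, calib: CalibrationSet,
                                 noise_sigma: float = 0.0,
                                 seed: int | None = None) -> list[TitrationSeries]:
    """Generate measured R1/R2/ADC responses for a characterization design.

    Evaluates the forward models at every mixture of ``design`` and
    (optionally) adds iid Gaussian measurement noise of standard deviation
    ``noise_sigma`` (same units as each response).  Returns one
    :class:`TitrationSeries` per (substance, background, response kind),
    ready for :func:`fit_relaxivity` / :func:`fit_adc_model`.  ADC series
    are generated only for lecithin titrations (diffusion is insensitive
    to the other two ingredients in this model).
    """
    rng = np.random.default_rng(seed)
    series = []
    for substance, grp0 in design.groupby("substance", sort=False):
        varied = _VARIED_COLUMN[substance]
        fixed = [c for c in ("c_gd", "c_lecithin", "c_agarose") if c != varied]
        for (f1, f2), grp in grp0.groupby(fixed, sort=False):
            grp = grp.sort_values(varied)
            concs = tuple(grp[varied])
            triples = [
                ConcentrationTriple(c_gd=row.c_gd, c_lec=row.c_lecithin,
                                    c_agar=row.c_agarose)
                for row in grp.itertuples()
            ]
            bg_vals = dict(zip(fixed, (f1, f2)))
            bg_vals[varied] = 0.0
            background = ConcentrationTriple(
                c_gd=bg_vals["c_gd"], c_lec=bg_vals["c_lecithin"],
                c_agar=bg_vals["c_agarose"])
            kinds = ["r1", "r2"]
            if substance == "lecithin":
                kinds.append("adc")
            for kind in kinds:
                if kind == "r1":
                    vals = [r1_forward(t, calib.relaxivity, calib.solvent)
                            for t in triples]
                elif kind == "r2":
                    vals = [r2_forward(t, calib.relaxivity, calib.solvent)
                            for t in triples]
                else:
                    vals = [adc_forward(t.c_lec, calib.adc) for t in triples]
                vals = np.asarray(vals)
                if noise_sigma > 0:
                    vals = vals + rng.normal(0.0, noise_sigma, size=vals.shape)
                series.append(TitrationSeries(
                    varied_substance=substance, concentrations=concs,
                    responses=tuple(np.clip(vals, 1e-9, None)),
                    response_type=kind, background=background,
                ))
    return series
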