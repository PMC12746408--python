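"""Invert the forward models: from a tissue target to a gel recipe.

Because ADC depends only on lecithin, T1 only on lecithin and Gd-DTPA, and
T2 on all three ingredients, the inversion is triangular and proceeds in
three steps:

1. lecithin from the target ADC, by bisection of the strictly decreasing
   biexponential ADC model;
2. Gd-DTPA from the target T1, in closed form from the affine R1 model;
3. agarose from the target T2, in closed form from the affine R2 model.

A target is infeasible exactly when a closed-form numerator goes negative
(the target time is longer than the baseline already set by the previous
steps) or the ADC lies outside the reachable band.  The same closed forms
delimit the achievable (ADC, T1) region and the baseline T2 available for
agarose adjustment, which :func:`feasibility_grid` maps over a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .forward_models import (
    AdcModelParams,
    CalibrationSet,
    ConcentrationTriple,
    TissueTarget,
    adc_forward,
    predict_triple,
)
from .units import rate_from_time, time_from_rate

__all__ = [
    "InfeasibleTargetError",
    "RecipeResult",
    "FeasibilityGrid",
    "solve_lecithin",
    "solve_gd",
    "solve_agarose",
    "solve_recipe",
    "max_t1_at_adc",
    "baseline_t2",
    "feasibility_grid",
]

#: Default upper bisection bracket for the lecithin concentration, % wt/vol.
#: Calibration data extend to 5 %; solutions above that carry an
#: extrapolation warning (higher loads are physically possible but the gels
#: become hard to mix homogeneously).
DEFAULT_C_LEC_MAX = 10.0

#: ADC residual tolerance for the bisection, 10^-3 mm^2/s.
ADC_TOL = 1e-10

# Solved concentrations this close to zero are flagged "near-boundary":
# the target sits at the edge of the feasible region and small calibration
# errors may push the real recipe infeasible.
_NEAR_BOUNDARY = {"c_gd": 0.005, "c_agar": 0.02}


class InfeasibleTargetError(ValueError):
    """A target parameter cannot be reached with non-negative concentrations.

    Attributes
    ----------
    step : str
        Which inversion step failed: ``"adc"``, ``"t1"`` or ``"t2"``.
    reason : str
        Machine-readable reason, e.g. ``"infeasible-high"``.
    """

    def __init__(self, step: str, reason: str, message: str):
        super().__init__(message)
        self.step = step
        self.reason = reason


def solve_lecithin(target_adc: float, params: AdcModelParams,
                   c_max: float = DEFAULT_C_LEC_MAX) -> float:
    """Step 1: lecithin concentration (% wt/vol) for a target ADC.

    Bisection root of the biexponential ADC model, unique by strict
    monotonicity.  ``target_adc`` must lie in ``(adc(c_max), adc(0)]``;
    the water-limit ADC itself maps to concentration 0.
    """
    target_adc = float(target_adc)
    if target_adc <= 0:
        raise InfeasibleTargetError("adc", "non-positive", "target ADC must be positive")
    adc_water = adc_forward(0.0, params)
    if target_adc > adc_water:
        raise InfeasibleTargetError(
            "adc", "infeasible-high",
            f"target ADC {target_adc:g} exceeds the water-limit ADC {adc_water:g} "
            "(no lecithin load can raise ADC above pure water)",
        )
    if target_adc == adc_water:
        return 0.0
    adc_floor = adc_forward(c_max, params)
    if target_adc <= adc_floor:
        raise InfeasibleTargetError(
            "adc", "infeasible-low",
            f"target ADC {target_adc:g} is at or below ADC({c_max:g} % wt/vol) = "
            f"{adc_floor:g}; raise c_max to extrapolate further",
        )
    c = brentq(lambda x: adc_forward(x, params) - target_adc, 0.0, c_max,
               xtol=1e-13, rtol=8.9e-16)
    # brentq terminates on the bracket width; verify the ADC residual itself
    if abs(adc_forward(c, params) - target_adc) > ADC_TOL:
        raise RuntimeError("bisection failed to reach the ADC tolerance")
    return float(c)


def solve_gd(target_t1: float, c_lec: float, calib: CalibrationSet) -> float:
    """Step 2: Gd-DTPA concentration (mM) for a target T1 at a given lecithin load.

    Closed form ``c_gd = (R1(target) - R1w - r1_lec*c_lec) / r1_gd``.
    Raises :class:`InfeasibleTargetError` when the numerator is negative,
    i.e. the target T1 is longer than the baseline T1 already set by the
    lecithin needed for the ADC.
    """
    if target_t1 <= 0:
        raise InfeasibleTargetError("t1", "non-positive", "target T1 must be positive")
    relax, solvent = calib.relaxivity, calib.solvent
    numerator = rate_from_time(target_t1) - solvent.r1w - relax.r1_lec * c_lec
    if numerator < -1e-12:
        t1_max = time_from_rate(solvent.r1w + relax.r1_lec * c_lec)
        raise InfeasibleTargetError(
            "t1", "infeasible",
            f"target T1 = {target_t1:g} ms exceeds the maximum achievable "
            f"{t1_max:.1f} ms at lecithin load {c_lec:g} % wt/vol",
        )
    return max(numerator, 0.0) / relax.r1_gd


def solve_agarose(target_t2: float, c_lec: float, c_gd: float,
                  calib: CalibrationSet) -> float:
    """Step 3: agarose concentration (% wt/vol) for a target T2.

    Closed form ``c_agar = (R2(target) - R2w - r2_gd*c_gd - r2_lec*c_lec) /
    r2_agar``; infeasible when negative (target T2 longer than the baseline
    T2 left after steps 1 and 2).
    """
    if target_t2 <= 0:
        raise InfeasibleTargetError("t2", "non-positive", "target T2 must be positive")
    relax, solvent = calib.relaxivity, calib.solvent
    r2_base = solvent.r2w + relax.r2_gd * c_gd + relax.r2_lec * c_lec
    numerator = rate_from_time(target_t2) - r2_base
    if numerator < -1e-12:
        raise InfeasibleTargetError(
            "t2", "infeasible",
            f"target T2 = {target_t2:g} ms exceeds the baseline T2 "
            f"{time_from_rate(r2_base):.1f} ms at this lecithin/Gd load",
        )
    return max(numerator, 0.0) / relax.r2_agar


@dataclass(frozen=True)
class RecipeResult:
    """Outcome of the three-step inversion for one tissue target."""

    target: TissueTarget
    feasible: bool
    concentrations: ConcentrationTriple | None = None
    predicted: TissueTarget | None = None
    warnings: tuple[str, ...] = ()
    failed_step: str | None = None
    message: str = ""

    def to_dict(self) -> dict:
        d = {
            "target": {"t1_ms": self.target.t1, "t2_ms": self.target.t2,
                       "adc": self.target.adc},
            "feasible": self.feasible,
            "warnings": list(self.warnings),
        }
        if self.feasible:
            assert self.concentrations is not None and self.predicted is not None
            d["concentrations"] = {
                "gd_dtpa_mM": self.concentrations.c_gd,
                "lecithin_pct": self.concentrations.c_lec,
                "agarose_pct": self.concentrations.c_agar,
            }
            d["predicted"] = {"t1_ms": self.predicted.t1, "t2_ms": self.predicted.t2,
                              "adc": self.predicted.adc}
        else:
            d["failed_step"] = self.failed_step
            d["message"] = self.message
        return d


def solve_recipe(target: TissueTarget, calib: CalibrationSet,
                 c_lec_max: float = DEFAULT_C_LEC_MAX) -> RecipeResult:
    """Run the three-step procedure for one target.

    Never raises for an infeasible target; the failing step and reason are
    reported on the returned :class:`RecipeResult`.  Warnings flag
    extrapolation beyond the calibrated ranges and solutions at the edge of
    the feasible region.
    """
    try:
        c_lec = solve_lecithin(target.adc, calib.adc, c_max=c_lec_max)
        c_gd = solve_gd(target.t1, c_lec, calib)
        c_agar = solve_agarose(target.t2, c_lec, c_gd, calib)
    except InfeasibleTargetError as exc:
        return RecipeResult(target=target, feasible=False,
                            failed_step=exc.step, message=str(exc))
    conc = ConcentrationTriple(c_gd=c_gd, c_lec=c_lec, c_agar=c_agar)
    flags = list(conc.extrapolation_flags())
    for name, eps in _NEAR_BOUNDARY.items():
        if 0 <= getattr(conc, name) < eps:
            flags.append(f"near-boundary:{name}")
    predicted = predict_triple(conc, calib, warn_extrapolation=False)
    return RecipeResult(target=target, feasible=True, concentrations=conc,
                        predicted=predicted, warnings=tuple(flags))


def max_t1_at_adc(target_adc: float, calib: CalibrationSet,
                  c_lec_max: float = DEFAULT_C_LEC_MAX) -> float:
    """Longest achievable T1 (ms) at a given ADC: the zero-Gd boundary.

    The lecithin required for the ADC already shortens T1; without any
    Gd-DTPA, T1 = 1000 / (R1w + r1_lec * c_lec(ADC)).  Lower target ADC
    means more lecithin and hence a shorter T1 ceiling.
    """
    c_lec = solve_lecithin(target_adc, calib.adc, c_max=c_lec_max)
    return time_from_rate(calib.solvent.r1w + calib.relaxivity.r1_lec * c_lec)


def baseline_t2(target_adc: float, target_t1: float, calib: CalibrationSet,
                c_lec_max: float = DEFAULT_C_LEC_MAX) -> float:
    """Baseline T2 (ms) before agarose, at the step-1/step-2 solution.

    This is the T2 ceiling available for the final agarose adjustment; the
    (ADC, T1) pair must be feasible per :func:`max_t1_at_adc`.
    """
    c_lec = solve_lecithin(target_adc, calib.adc, c_max=c_lec_max)
    c_gd = solve_gd(target_t1, c_lec, calib)  # raises with the violated boundary
    relax, solvent = calib.relaxivity, calib.solvent
    return time_from_rate(solvent.r2w + relax.r2_gd * c_gd + relax.r2_lec * c_lec)


@dataclass(frozen=True)
class FeasibilityGrid:
    """Achievability map over an (ADC, T1) grid.

    ``achievable[i, j]`` and ``baseline_t2[i, j]`` correspond to
    ``t1_axis[i]`` and ``adc_axis[j]``; baseline T2 is NaN where the cell
    is not achievable.
    """

    adc_axis: np.ndarray
    t1_axis: np.ndarray
    achievable: np.ndarray
    baseline_t2: np.ndarray

    def __post_init__(self):
        if self.achievable.shape != (len(self.t1_axis), len(self.adc_axis)):
            raise ValueError("achievable matrix shape does not match axes")
        if self.baseline_t2.shape != self.achievable.shape:
            raise ValueError("baseline_t2 matrix shape does not match axes")

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with one row per (ADC, T1) cell."""
        aa, tt = np.meshgrid(self.adc_axis, self.t1_axis)
        return pd.DataFrame({
            "adc": aa.ravel(),
            "t1_ms": tt.ravel(),
            "achievable": self.achievable.ravel(),
            "baseline_t2_ms": self.baseline_t2.ravel(),
        })

    def min_baseline_t2(self) -> float:
        """Minimum baseline T2 (ms) over the achievable cells."""
        if not self.achievable.any():
            raise ValueError("no achievable cell in the grid")
        return float(np.nanmin(self.baseline_t2[self.achievable]))


def feasibility_grid(adc_range: tuple[float, float] = (0.8, 2.0),
                     t1_range: tuple[float, float] = (700.0, 2000.0),
                     resolution: tuple[int, int] = (121, 131),
                     calib: CalibrationSet | None = None,
                     c_lec_max: float = DEFAULT_C_LEC_MAX) -> FeasibilityGrid:
    """Map the achievable (ADC, T1) region and baseline T2 over a grid.

    Defaults cover ADC 0.8–2.0 (121 points) × T1 700–2000 ms (131 points),
    the ranges spanning almost all soft tissues.  A cell is achievable when
    its ADC is reachable by some lecithin load and its T1 does not exceed
    the zero-Gd ceiling at that load.
    """
    if calib is None:
        from .forward_models import default_calibration
        calib = default_calibration()
    n_adc, n_t1 = resolution
    if n_adc < 1 or n_t1 < 1:
        raise ValueError("resolution must be positive in both axes")
    if not (adc_range[0] < adc_range[1]) or not (t1_range[0] < t1_range[1]):
        raise ValueError("ranges must be non-empty with low < high")
    adc_axis = np.linspace(adc_range[0], adc_range[1], n_adc)
    t1_axis = np.linspace(t1_range[0], t1_range[1], n_t1)

    achievable = np.zeros((n_t1, n_adc), dtype=bool)
    base_t2 = np.full((n_t1, n_adc), np.nan)
    relax, solvent = calib.relaxivity, calib.solvent
    for j, adc in enumerate(adc_axis):
        try:
            c_lec = solve_lecithin(adc, calib.adc, c_max=c_lec_max)
        except InfeasibleTargetError:
            continue  # column entirely unreachable
        r1 = rate_from_time(np.asarray(t1_axis))
        numer = r1 - solvent.r1w - relax.r1_lec * c_lec
        ok = numer >= -1e-12
        c_gd = np.clip(numer, 0.0, None) / relax.r1_gd
        achievable[:, j] = ok
        r2_base = solvent.r2w + relax.r2_gd * c_gd + relax.r2_lec * c_lec
        base_t2[ok, j] = time_from_rate(r2_base[ok])
    return FeasibilityGrid(adc_axis=adc_axis, t1_axis=t1_axis,
                           achievable=achievable, baseline_t2=base_t2)
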