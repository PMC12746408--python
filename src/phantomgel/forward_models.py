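"""Forward models for hydrogel MRI test materials.

A composite hydrogel of Gd-DTPA (mM), soy lecithin (% wt/vol) and agarose
(% wt/vol) in water has, at 3 T and 20 °C, MR properties well described by

* a biexponential dependence of ADC on the lecithin concentration alone,
  ``ADC = a_fast * exp(-k_fast * C_lec) + a_slow * exp(-k_slow * C_lec)``,
  because lecithin vesicles restrict water mobility while Gd-DTPA and
  agarose leave diffusion essentially unchanged;
* affine relaxation-rate models in which each ingredient contributes its
  relaxivity times its concentration on top of the pure-water baseline:
  ``R1 = R1w + r1_gd*C_gd + r1_lec*C_lec`` (the longitudinal contribution
  of agarose is negligible in the composite gel) and
  ``R2 = R2w + r2_gd*C_gd + r2_lec*C_lec + r2_agar*C_agar``.

The dataclasses below carry the model coefficients with explicit units and
enforce their physical invariants; the functions evaluate the models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .units import rate_from_time, time_from_rate

__all__ = [
    "ExtrapolationWarning",
    "ConcentrationTriple",
    "AdcModelParams",
    "RelaxivityTable",
    "SolventBaseline",
    "TissueTarget",
    "CalibrationSet",
    "CALIBRATED_RANGES",
    "adc_forward",
    "r1_forward",
    "r2_forward",
    "predict_triple",
    "default_calibration",
]


class ExtrapolationWarning(UserWarning):
    """A concentration lies outside the range the model was calibrated on."""


#: Upper ends of the calibrated concentration ranges (lower end is 0 for all).
#: Beyond these the affine/biexponential models are extrapolations; ADC
#: accuracy in particular degrades at lecithin loads >= 3 % wt/vol.
CALIBRATED_RANGES = {"c_gd": 0.2, "c_lec": 5.0, "c_agar": 4.0}


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return value


@dataclass(frozen=True)
class ConcentrationTriple:
    """Ingredient concentrations of one gel.

    Attributes
    ----------
    c_gd : float
        Gd-DTPA concentration, mM.
    c_lec : float
        Soy lecithin concentration, % wt/vol.
    c_agar : float
        Agarose concentration, % wt/vol.
    """

    c_gd: float
    c_lec: float
    c_agar: float

    def __post_init__(self):
        for name in ("c_gd", "c_lec", "c_agar"):
            object.__setattr__(self, name, _require_finite_nonneg(name, getattr(self, name)))

    def extrapolation_flags(self) -> list[str]:
        """Names of components outside the calibrated concentration range."""
        return [
            f"extrapolation:{name}"
            for name, upper in CALIBRATED_RANGES.items()
            if getattr(self, name) > upper
        ]


@dataclass(frozen=True)
class AdcModelParams:
    """Coefficients of the biexponential ADC-vs-lecithin model.

    Amplitudes in 10^-3 mm^2/s, decay constants in (% wt/vol)^-1.
    Components are ordered so that ``k_fast > k_slow``.
    """

    a_fast: float
    k_fast: float
    a_slow: float
    k_slow: float

    def __post_init__(self):
        for name in ("a_fast", "k_fast", "a_slow", "k_slow"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
            object.__setattr__(self, name, v)
        if not self.k_fast > self.k_slow:
            raise ValueError(
                f"k_fast ({self.k_fast}) must exceed k_slow ({self.k_slow}); "
                "order the components before constructing AdcModelParams"
            )


@dataclass(frozen=True)
class RelaxivityTable:
    """Relaxivities of the three ingredients at 3 T, 20 °C.

    ``r1_gd``/``r2_gd`` in s^-1 mM^-1; ``r1_lec``/``r2_lec``/``r2_agar`` in
    s^-1 (% wt/vol)^-1.  There is deliberately no ``r1_agar``: in the
    composite gel no significant dependence of R1 on agarose concentration
    is observed, so the longitudinal contribution of agarose is treated as
    zero.
    """

    r1_gd: float
    r2_gd: float
    r1_lec: float
    r2_lec: float
    r2_agar: float

    def __post_init__(self):
        for name in ("r1_gd", "r2_gd", "r1_lec", "r2_lec", "r2_agar"):
            object.__setattr__(self, name, _require_finite_nonneg(name, getattr(self, name)))


@dataclass(frozen=True)
class SolventBaseline:
    """Relaxation rates of the pure-water solvent.

    ``r1w``/``r2w`` in s^-1, with the physical ordering R2w >= R1w > 0.
    ``temperature`` (°C) and ``field`` (T) are carried as provenance labels;
    the models contain no temperature or field dependence.
    """

    r1w: float
    r2w: float
    temperature: float = 20.0
    field: float = 3.0

    def __post_init__(self):
        r1w, r2w = float(self.r1w), float(self.r2w)
        if not (math.isfinite(r1w) and math.isfinite(r2w)):
            raise ValueError("solvent rates must be finite")
        if not (r2w >= r1w > 0):
            raise ValueError(f"require R2w >= R1w > 0, got R1w={r1w}, R2w={r2w}")
        object.__setattr__(self, "r1w", r1w)
        object.__setattr__(self, "r2w", r2w)

    @classmethod
    def from_times(cls, t1w_ms: float, t2w_ms: float, temperature: float = 20.0,
                   field: float = 3.0) -> "SolventBaseline":
        """Build from water T1/T2 in ms (e.g. T1w = 3000, T2w = 2000)."""
        return cls(rate_from_time(t1w_ms), rate_from_time(t2w_ms), temperature, field)

    @property
    def t1w(self) -> float:
        """Water T1 in ms."""
        return time_from_rate(self.r1w)

    @property
    def t2w(self) -> float:
        """Water T2 in ms."""
        return time_from_rate(self.r2w)


@dataclass(frozen=True)
class TissueTarget:
    """A desired (T1 ms, T2 ms, ADC 10^-3 mm^2/s) triple."""

    t1: float
    t2: float
    adc: float

    def __post_init__(self):
        t1, t2, adc = float(self.t1), float(self.t2), float(self.adc)
        if not all(map(math.isfinite, (t1, t2, adc))):
            raise ValueError("target values must be finite")
        if not t1 > t2 > 0:
            raise ValueError(f"require T1 > T2 > 0, got T1={t1}, T2={t2}")
        if adc <= 0:
            raise ValueError(f"ADC must be positive, got {adc}")
        object.__setattr__(self, "t1", t1)
        object.__setattr__(self, "t2", t2)
        object.__setattr__(self, "adc", adc)


@dataclass(frozen=True)
class CalibrationSet:
    """Everything needed to evaluate and invert the forward models."""

    relaxivity: RelaxivityTable
    adc: AdcModelParams
    solvent: SolventBaseline

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "units": {
                "r1_gd": "s^-1 mM^-1", "r2_gd": "s^-1 mM^-1",
                "r1_lec": "s^-1 (% wt/vol)^-1", "r2_lec": "s^-1 (% wt/vol)^-1",
                "r2_agar": "s^-1 (% wt/vol)^-1",
                "a_fast": "10^-3 mm^2/s", "a_slow": "10^-3 mm^2/s",
                "k_fast": "(% wt/vol)^-1", "k_slow": "(% wt/vol)^-1",
                "t1w_ms": "ms", "t2w_ms": "ms",
                "temperature": "degC", "field": "T",
            },
            "relaxivity": {k: getattr(self.relaxivity, k)
                           for k in ("r1_gd", "r2_gd", "r1_lec", "r2_lec", "r2_agar")},
            "adc_model": {k: getattr(self.adc, k)
                          for k in ("a_fast", "k_fast", "a_slow", "k_slow")},
            "solvent": {
                "t1w_ms": self.solvent.t1w,
                "t2w_ms": self.solvent.t2w,
                "temperature": self.solvent.temperature,
                "field": self.solvent.field,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationSet":
        try:
            relax = RelaxivityTable(**d["relaxivity"])
            adc = AdcModelParams(**d["adc_model"])
            sol = d["solvent"]
            solvent = SolventBaseline.from_times(
                sol["t1w_ms"], sol["t2w_ms"],
                sol.get("temperature", 20.0), sol.get("field", 3.0),
            )
        except KeyError as exc:
            raise ValueError(f"calibration config missing required field: {exc}") from exc
        return cls(relaxivity=relax, adc=adc, solvent=solvent)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CalibrationSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_calibration() -> CalibrationSet:
    """The shipped default calibration (3 T, 20 °C).

    Relaxivities and ADC coefficients from the reference characterization of
    the Gd-DTPA/agarose/soy-lecithin system; water baselines T1w = 3000 ms,
    T2w = 2000 ms (literature-typical for pure water near 20 °C at 3 T).
    """
    from importlib import resources

    with resources.as_file(
        resources.files("phantomgel").joinpath("data/default_calibration.yaml")
    ) as p:
        return CalibrationSet.from_yaml(p)


# ---------------------------------------------------------------------------
# forward evaluations
# ---------------------------------------------------------------------------

def adc_forward(c_lec, params: AdcModelParams):
    """ADC (10^-3 mm^2/s) of a gel with lecithin concentration ``c_lec``.

    Biexponential in the lecithin load; strictly decreasing.  Accepts
    scalars or arrays.  Raises ``ValueError`` for negative concentrations.
    """
    c = np.asarray(c_lec, dtype=float)
    if np.any(c < 0):
        raise ValueError("lecithin concentration must be non-negative")
    out = params.a_fast * np.exp(-params.k_fast * c) + params.a_slow * np.exp(-params.k_slow * c)
    return float(out) if out.ndim == 0 else out


def r1_forward(conc: ConcentrationTriple, relax: RelaxivityTable,
               solvent: SolventBaseline) -> float:
    """Longitudinal rate R1 (s^-1); agarose contributes nothing."""
    return solvent.r1w + relax.r1_gd * conc.c_gd + relax.r1_lec * conc.c_lec


def r2_forward(conc: ConcentrationTriple, relax: RelaxivityTable,
               solvent: SolventBaseline) -> float:
    """Transverse rate R2 (s^-1); all three ingredients contribute."""
    return (solvent.r2w + relax.r2_gd * conc.c_gd + relax.r2_lec * conc.c_lec
            + relax.r2_agar * conc.c_agar)


def predict_triple(conc: ConcentrationTriple, calib: CalibrationSet,
                   warn_extrapolation: bool = True) -> TissueTarget:
    """Predicted (T1, T2, ADC) of a gel with the given composition.

    Composes the three forward models and converts rates to times.  Emits
    an :class:`ExtrapolationWarning` when any concentration exceeds its
    calibrated range.
    """
    if warn_extrapolation:
        flags = conc.extrapolation_flags()
        if flags:
            warnings.warn(
                "concentrations outside the calibrated range: " + ", ".join(flags),
                ExtrapolationWarning,
                stacklevel=2,
            )
    r1 = r1_forward(conc, calib.relaxivity, calib.solvent)
    r2 = r2_forward(conc, calib.relaxivity, calib.solvent)
    return TissueTarget(
        t1=time_from_rate(r1),
        t2=time_from_rate(r2),
        adc=adc_forward(conc.c_lec, calib.adc),
    )
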