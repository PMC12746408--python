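"""Synthetic IR-TSE, CPMG and DWI acquisitions over a tube phantom.

The simulator renders magnitude image series with known voxel-wise ground
truth, emulating a 2-D acquisition of a phantom of gel-filled tubes in a
water-filled cylindrical housing: 128×128 matrix over a 200 mm FOV, nine
inversion times from 25 to 6400 ms (TR 10 s) for T1, 32 equally spaced
echoes from 10 to 320 ms for T2, and b = 0/50/500/1000 s/mm² for ADC.

Signal models:

* inversion recovery, magnitude with finite-TR recovery term:
  ``|1 - 2 exp(-TI/T1) + exp(-TR/T1)| * M0`` (echo-train decay during the
  short 9.9 ms readout is neglected);
* CPMG: ``M0 exp(-TE/T2)``;
* DWI: ``S0 exp(-b * ADC * 1e-3)`` with ADC in 10^-3 mm²/s and b in s/mm².

Noise is Rician — the magnitude of the true signal plus complex Gaussian
noise — which is what a scanner's magnitude reconstruction produces; the
fitting module must therefore handle the sign loss of inverted IR signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .forward_models import TissueTarget

__all__ = [
    "IrProtocol",
    "CpmgProtocol",
    "DwiProtocol",
    "Tube",
    "PhantomLayout",
    "ImageSeries",
    "ir_signal",
    "cpmg_signal",
    "dwi_signal",
    "add_rician_noise",
    "render_phantom",
    "sigma_for_snr",
    "default_layout",
    "save_series",
    "load_series",
]


def _strictly_increasing(values) -> bool:
    v = np.asarray(values)
    return bool(np.all(np.diff(v) > 0))


@dataclass(frozen=True)
class IrProtocol:
    """Inversion-recovery T1-mapping protocol.

    Default inversion times are nine log-spaced values from 25 to 6400 ms
    (successive doubling); TR = 10000 ms, TE = 9.9 ms.
    """

    inversion_times: tuple[float, ...] = tuple(float(t) for t in 25.0 * 2.0 ** np.arange(9))
    repetition_time: float = 10000.0
    echo_time: float = 9.9
    kind: str = field(default="ir", init=False)

    def __post_init__(self):
        tis = tuple(float(t) for t in self.inversion_times)
        if not _strictly_increasing(tis):
            raise ValueError("inversion times must be strictly increasing")
        if tis[0] <= 0 or tis[-1] >= self.repetition_time:
            raise ValueError("inversion times must be positive and below TR")
        object.__setattr__(self, "inversion_times", tis)

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.inversion_times)


@dataclass(frozen=True)
class CpmgProtocol:
    """Multi-echo CPMG T2-mapping protocol (default 32 echoes, 10–320 ms)."""

    echo_times: tuple[float, ...] = tuple(float(t) for t in np.linspace(10.0, 320.0, 32))
    repetition_time: float = 5000.0
    kind: str = field(default="cpmg", init=False)

    def __post_init__(self):
        tes = tuple(float(t) for t in self.echo_times)
        if not _strictly_increasing(tes) or tes[0] <= 0:
            raise ValueError("echo times must be positive and strictly increasing")
        object.__setattr__(self, "echo_times", tes)

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.echo_times)


@dataclass(frozen=True)
class DwiProtocol:
    """Diffusion-weighted protocol (default b = 0, 50, 500, 1000 s/mm²)."""

    b_values: tuple[float, ...] = (0.0, 50.0, 500.0, 1000.0)
    echo_time: float = 48.0
    kind: str = field(default="dwi", init=False)

    def __post_init__(self):
        bs = tuple(float(b) for b in self.b_values)
        if bs[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if not _strictly_increasing(bs):
            raise ValueError("b-values must be strictly increasing")
        object.__setattr__(self, "b_values", bs)

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.b_values)


Protocol = IrProtocol | CpmgProtocol | DwiProtocol


# ---------------------------------------------------------------------------
# analytic signal models
# ---------------------------------------------------------------------------

def ir_signal(t1, ti, tr, m0=1.0):
    """Magnitude IR signal ``m0 * |1 - 2 exp(-TI/T1) + exp(-TR/T1)|``."""
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    ti, tr = np.asarray(ti, dtype=float), float(tr)
    if np.any(ti <= 0) or tr <= 0:
        raise ValueError("TI and TR must be positive")
    out = np.asarray(m0) * np.abs(1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr / t1))
    return float(out) if out.ndim == 0 else out


def cpmg_signal(t2, te, m0=1.0):
    """CPMG echo magnitude ``m0 * exp(-TE/T2)``."""
    t2 = np.asarray(t2, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be positive")
    te = np.asarray(te, dtype=float)
    if np.any(te <= 0):
        raise ValueError("TE must be positive")
    out = np.asarray(m0) * np.exp(-te / t2)
    return float(out) if out.ndim == 0 else out


def dwi_signal(adc, b, s0=1.0):
    """DWI magnitude ``s0 * exp(-b * ADC * 1e-3)`` (ADC in 10^-3 mm²/s)."""
    adc = np.asarray(adc, dtype=float)
    if np.any(adc <= 0):
        raise ValueError("ADC must be positive")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    out = np.asarray(s0) * np.exp(-b * adc * 1e-3)
    return float(out) if out.ndim == 0 else out


def add_rician_noise(values, sigma: float, seed=None, rng=None):
    """Rician-corrupt magnitudes: ``sqrt((x + n1)^2 + n2^2)``.

    ``n1, n2`` are independent zero-mean Gaussians with standard deviation
    ``sigma`` (the per-channel complex noise level).  ``sigma = 0`` returns
    the input unchanged.  Pass either a ``seed`` or an existing Generator.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    values = np.asarray(values, dtype=float)
    if sigma == 0:
        return values.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=values.shape)
    n2 = rng.normal(0.0, sigma, size=values.shape)
    return np.hypot(values + n1, n2)


def sigma_for_snr(snr: float, s0: float = 1.0) -> float:
    """Per-channel noise sigma giving the requested SNR at signal level s0."""
    if snr <= 0:
        raise ValueError("SNR must be positive")
    return s0 / snr


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tube:
    """One gel-filled tube: circular cross-section with uniform truth."""

    center: tuple[float, float]  # mm, relative to FOV center
    radius: float  # mm
    truth: TissueTarget
    proton_density: float = 1.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("tube radius must be positive")
        if self.proton_density <= 0:
            raise ValueError("proton density must be positive")


@dataclass(frozen=True)
class PhantomLayout:
    """Tubes inside a water-filled cylindrical housing on a square FOV.

    Voxels are assigned to a tube when their center lies inside the tube
    circle; remaining voxels inside ``housing_radius`` are water with
    ``background`` truth (or empty when ``background`` is None).
    """

    tubes: tuple[Tube, ...]
    matrix: int = 128
    fov: float = 200.0
    background: TissueTarget | None = None
    housing_radius: float = 75.0

    def __post_init__(self):
        tubes = tuple(self.tubes)
        if self.matrix < 2 or self.fov <= 0:
            raise ValueError("matrix and FOV must be positive")
        half = self.fov / 2.0
        for t in tubes:
            if abs(t.center[0]) + t.radius > half or abs(t.center[1]) + t.radius > half:
                raise ValueError("tube extends beyond the FOV")
        for i, a in enumerate(tubes):
            for b in tubes[i + 1:]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise ValueError("tubes overlap")
        object.__setattr__(self, "tubes", tubes)

    def voxel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) voxel-center coordinates in mm, FOV-centered."""
        step = self.fov / self.matrix
        axis = (np.arange(self.matrix) + 0.5) * step - self.fov / 2.0
        return np.meshgrid(axis, axis, indexing="xy")

    def truth_maps(self) -> dict[str, np.ndarray]:
        """Voxel-wise ground truth: t1/t2/adc (NaN outside material), pd, label.

        ``label`` is -1 outside material, 0 for water background, 1..n for
        tubes in order.
        """
        x, y = self.voxel_coords()
        shape = x.shape
        t1 = np.full(shape, np.nan)
        t2 = np.full(shape, np.nan)
        adc = np.full(shape, np.nan)
        pd_map = np.zeros(shape)
        label = np.full(shape, -1, dtype=int)
        if self.background is not None:
            inside = x**2 + y**2 <= self.housing_radius**2
            t1[inside] = self.background.t1
            t2[inside] = self.background.t2
            adc[inside] = self.background.adc
            pd_map[inside] = 1.0
            label[inside] = 0
        for i, tube in enumerate(self.tubes, start=1):
            sel = (x - tube.center[0])**2 + (y - tube.center[1])**2 <= tube.radius**2
            t1[sel] = tube.truth.t1
            t2[sel] = tube.truth.t2
            adc[sel] = tube.truth.adc
            pd_map[sel] = tube.proton_density
            label[sel] = i
        return {"t1": t1, "t2": t2, "adc": adc, "pd": pd_map, "label": label}


def default_layout(targets: dict[str, TissueTarget],
                   matrix: int = 128, fov: float = 200.0,
                   background: TissueTarget | None = None,
                   tube_radius: float = 14.0,
                   ring_radius: float = 60.0,
                   housing_radius: float = 75.0) -> PhantomLayout:
    """Up to eight tubes evenly spaced on a ring inside the housing.

    By default five tubes of radius 14 mm on a 60 mm ring, mirroring the
    usual tube-in-housing arrangement; ``background`` defaults to empty
    (pass a water triple to fill the housing).
    """
    n = len(targets)
    if n == 0:
        raise ValueError("need at least one target")
    angles = np.pi / 2 - 2 * np.pi * np.arange(n) / n  # first tube at 12 o'clock
    tubes = tuple(
        Tube(center=(ring_radius * np.cos(a), ring_radius * np.sin(a)),
             radius=tube_radius, truth=target)
        for a, target in zip(angles, targets.values())
    )
    return PhantomLayout(tubes=tubes, matrix=matrix, fov=fov,
                         background=background, housing_radius=housing_radius)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSeries:
    """A stack of magnitude images over TI, TE or b, with ground truth."""

    kind: str  # "ir" | "cpmg" | "dwi"
    points: np.ndarray  # TI (ms), TE (ms) or b (s/mm²) per frame
    data: np.ndarray  # (n_points, matrix, matrix), non-negative magnitudes
    truth: dict[str, np.ndarray]
    protocol: Protocol
    noise_sigma: float
    seed: int | None
    fov: float
    matrix: int

    def __post_init__(self):
        if self.data.shape != (len(self.points), self.matrix, self.matrix):
            raise ValueError("data shape does not match points/matrix")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")


def render_phantom(layout: PhantomLayout, protocol: Protocol,
                   noise_sigma: float = 0.0, seed: int | None = None) -> ImageSeries:
    """Render a magnitude image series for one protocol over the layout.

    Noiseless voxels inside material equal the analytic signal exactly;
    with ``noise_sigma > 0`` every voxel (including empty background) is
    Rician-corrupted reproducibly under the given seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    truth = layout.truth_maps()
    pts = protocol.points
    n = layout.matrix
    data = np.zeros((len(pts), n, n))
    inside = truth["label"] >= 0
    pd_map = truth["pd"]
    if isinstance(protocol, IrProtocol):
        par = truth["t1"]
        for k, ti in enumerate(pts):
            data[k][inside] = ir_signal(par[inside], ti, protocol.repetition_time,
                                        pd_map[inside])
    elif isinstance(protocol, CpmgProtocol):
        par = truth["t2"]
        for k, te in enumerate(pts):
            data[k][inside] = cpmg_signal(par[inside], te, pd_map[inside])
    elif isinstance(protocol, DwiProtocol):
        par = truth["adc"]
        for k, b in enumerate(pts):
            data[k][inside] = dwi_signal(par[inside], b, pd_map[inside])
    else:  # pragma: no cover
        raise TypeError(f"unsupported protocol type {type(protocol)!r}")
    if noise_sigma > 0:
        data = add_rician_noise(data, noise_sigma, seed=seed)
    return ImageSeries(kind=protocol.kind, points=pts.copy(), data=data,
                       truth=truth, protocol=protocol, noise_sigma=noise_sigma,
                       seed=seed, fov=layout.fov, matrix=layout.matrix)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(fov: float, matrix: int) -> np.ndarray:
    step = fov / matrix
    aff = np.diag([step, step, 1.0, 1.0])
    aff[0, 3] = aff[1, 3] = -fov / 2.0 + step / 2.0
    return aff

def save_series(series: ImageSeries, prefix) -> None:
    """Write a series as ``<prefix>.nii.gz`` (4-D: x, y, 1, point) plus
    truth-map volumes and a JSON sidecar ``<prefix>.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.fov, series.matrix)
    vol = np.transpose(series.data, (2, 1, 0))[:, :, np.newaxis, :]
    nib.save(nib.Nifti1Image(vol.astype(np.float64), aff), str(prefix) + ".nii.gz")
    truth_stack = np.stack([series.truth[k] for k in ("t1", "t2", "adc", "pd")]
                           + [series.truth["label"].astype(float)])
    tvol = np.transpose(truth_stack, (2, 1, 0))[:, :, np.newaxis, :]
    nib.save(nib.Nifti1Image(tvol.astype(np.float64), aff),
             str(prefix) + "_truth.nii.gz")
    proto = series.protocol
    meta = {
        "kind": series.kind,
        "points": [float(p) for p in series.points],
        "noise_sigma": series.noise_sigma,
        "seed": series.seed,
        "fov_mm": series.fov,
        "matrix": series.matrix,
        "truth_volumes": ["t1", "t2", "adc", "pd", "label"],
        "protocol": {
            f: getattr(proto, f)
            for f in ("repetition_time", "echo_time")
            if hasattr(proto, f)
        },
    }
    Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=2))


def load_series(prefix) -> ImageSeries:
    """Read back a series written by :func:`save_series`."""
    prefix = Path(prefix)
    meta = json.loads(Path(str(prefix) + ".json").read_text())
    vol = np.asanyarray(nib.load(str(prefix) + ".nii.gz").dataobj)
    data = np.transpose(vol[:, :, 0, :], (2, 1, 0))
    tvol = np.asanyarray(nib.load(str(prefix) + "_truth.nii.gz").dataobj)
    tstack = np.transpose(tvol[:, :, 0, :], (2, 1, 0))
    truth = {k: tstack[i] for i, k in enumerate(meta["truth_volumes"])}
    truth["label"] = truth["label"].astype(int)
    pts = tuple(meta["points"])
    extra = meta.get("protocol", {})
    if meta["kind"] == "ir":
        proto = IrProtocol(inversion_times=pts, **extra)
    elif meta["kind"] == "cpmg":
        proto = CpmgProtocol(echo_times=pts, **extra)
    else:
        proto = DwiProtocol(b_values=pts, **{k: v for k, v in extra.items()
                                             if k == "echo_time"})
    return ImageSeries(kind=meta["kind"], points=np.asarray(pts), data=data,
                       truth=truth, protocol=proto,
                       noise_sigma=meta["noise_sigma"], seed=meta["seed"],
                       fov=meta["fov_mm"], matrix=meta["matrix"])
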