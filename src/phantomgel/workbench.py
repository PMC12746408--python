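"""End-to-end pipeline: solve recipes, simulate, map, validate.

`run_demo` chains the whole toolchain for a named set of tissue targets:
each target is inverted to a gel recipe, the resulting tubes are rendered
under the IR/CPMG/DWI protocols with Rician noise, parametric maps are
fitted, ROI statistics compared with the targets, and everything written
to an output directory (CSV tables, NIfTI maps, a JSON manifest and a
feasibility figure).  A single seed fans out deterministically to every
noisy stage, so a report is bit-reproducible from its config.

`stability_report` analyses longitudinal ROI measurements for drift with
a per-series linear trend and 95 % confidence interval; the shipped
fixture generator produces stationary synthetic series (truth constant
over 12 weeks, measurement noise only) for calibrating its false-alarm
behaviour.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .forward_models import CalibrationSet, TissueTarget, default_calibration
from .mapping import RoiReport, compute_maps, roi_mean, validate_against_targets
from .recipe_solver import RecipeResult, feasibility_grid, solve_recipe
from .simulator import (
    CpmgProtocol,
    DwiProtocol,
    IrProtocol,
    default_layout,
    render_phantom,
    save_series,
    sigma_for_snr,
)

__all__ = [
    "RunConfig",
    "tissue_targets",
    "run_demo",
    "make_stability_fixture",
    "stability_report",
]

log = logging.getLogger("phantomgel")


def tissue_targets(path=None) -> dict[str, TissueTarget]:
    """Named tissue targets, from the shipped file or a user YAML."""
    if path is None:
        from importlib import resources

        with resources.as_file(
            resources.files("phantomgel").joinpath("data/tissue_targets.yaml")
        ) as p:
            raw = yaml.safe_load(Path(p).read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    targets = {}
    for name, d in raw["targets"].items():
        if name in targets:
            raise ValueError(f"duplicate target name {name!r}")
        targets[name] = TissueTarget(t1=d["t1"], t2=d["t2"], adc=d["adc"])
    return targets


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one demo run."""

    out_dir: Path
    targets: dict[str, TissueTarget] = field(default_factory=tissue_targets)
    calibration: CalibrationSet = field(default_factory=default_calibration)
    snr: float | None = 50.0  # None or 0 -> noiseless
    seed: int = 0
    matrix: int = 128
    write_nifti: bool = True

    def __post_init__(self):
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("target names must be unique")
        if self.snr and self.snr > 0 and self.seed is None:
            raise ValueError("a seed is mandatory for noisy runs")


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds (one per noisy stage) from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32)]


def run_demo(config: RunConfig) -> dict:
    """Run the full solve → simulate → map → validate pipeline.

    Infeasible targets are reported and skipped; the pipeline continues
    with the feasible ones.  Returns the report manifest (also written to
    ``manifest.json``), with the deviation table in ``validation.csv``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    calib = config.calibration
    log.info("calibration: relaxivity=%s solvent T1w=%.0f ms T2w=%.0f ms",
             calib.relaxivity, calib.solvent.t1w, calib.solvent.t2w)

    recipes: dict[str, RecipeResult] = {
        name: solve_recipe(t, calib) for name, t in config.targets.items()
    }
    feasible = {n: r for n, r in recipes.items() if r.feasible}
    infeasible = {n: r for n, r in recipes.items() if not r.feasible}
    for name, r in infeasible.items():
        log.warning("target %s infeasible at step %s: %s", name, r.failed_step, r.message)

    recipe_rows = []
    for name, r in recipes.items():
        row = {"name": name, "feasible": r.feasible,
               "t1_target_ms": r.target.t1, "t2_target_ms": r.target.t2,
               "adc_target": r.target.adc}
        if r.feasible:
            row.update(gd_dtpa_mM=r.concentrations.c_gd,
                       lecithin_pct=r.concentrations.c_lec,
                       agarose_pct=r.concentrations.c_agar,
                       warnings=";".join(r.warnings))
        else:
            row.update(failed_step=r.failed_step, message=r.message)
        recipe_rows.append(row)
    pd.DataFrame(recipe_rows).to_csv(out / "recipes.csv", index=False)

    sigma = sigma_for_snr(config.snr) if (config.snr and config.snr > 0) else 0.0
    water = TissueTarget(t1=calib.solvent.t1w, t2=calib.solvent.t2w, adc=1.96)
    layout = default_layout({n: r.target for n, r in feasible.items()},
                            matrix=config.matrix, background=water)
    protocols = {"t1": IrProtocol(), "t2": CpmgProtocol(), "adc": DwiProtocol()}
    seeds = dict(zip(protocols, _stage_seeds(config.seed, len(protocols))))

    roi_stats: dict[str, dict[str, tuple[float, float]]] = {n: {} for n in feasible}
    for param, proto in protocols.items():
        series = render_phantom(layout, proto, noise_sigma=sigma, seed=seeds[param])
        pmap = compute_maps(series)
        if config.write_nifti:
            save_series(series, out / f"series_{param}")
            import nibabel as nib

            from .simulator import _affine

            nib.save(nib.Nifti1Image(pmap.values.T[:, :, None],
                                     _affine(pmap.fov, pmap.matrix)),
                     out / f"map_{param}.nii.gz")
        step = layout.fov / layout.matrix
        for tube, name in zip(layout.tubes, feasible):
            roi_stats[name][param] = roi_mean(pmap, tube.center, tube.radius - step)

    reports = [
        RoiReport(name=name, target=feasible[name].target,
                  t1_mean=s["t1"][0], t1_sd=s["t1"][1],
                  t2_mean=s["t2"][0], t2_sd=s["t2"][1],
                  adc_mean=s["adc"][0], adc_sd=s["adc"][1])
        for name, s in roi_stats.items()
    ]
    validation = validate_against_targets(reports)
    validation.table.to_csv(out / "validation.csv", index=False)

    grid = feasibility_grid(calib=calib)
    grid.to_dataframe().to_csv(out / "feasibility_grid.csv", index=False)
    _plot_feasibility(grid, config.targets, out / "feasibility.png")

    manifest = {
        "seed": config.seed,
        "snr": config.snr,
        "noise_sigma": sigma,
        "matrix": config.matrix,
        "solvent_baseline": {"t1w_ms": calib.solvent.t1w, "t2w_ms": calib.solvent.t2w},
        "relaxivity": calib.to_dict()["relaxivity"],
        "targets": {n: {"t1": t.t1, "t2": t.t2, "adc": t.adc}
                    for n, t in config.targets.items()},
        "infeasible": {n: {"step": r.failed_step, "message": r.message}
                       for n, r in infeasible.items()},
        "max_deviation_pct": validation.max_deviation,
        "outputs": ["recipes.csv", "validation.csv", "feasibility_grid.csv",
                    "feasibility.png", "manifest.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _plot_feasibility(grid, targets: dict[str, TissueTarget], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.2), constrained_layout=True)
    extent = (grid.adc_axis[0], grid.adc_axis[-1], grid.t1_axis[0], grid.t1_axis[-1])
    axes[0].imshow(grid.achievable, origin="lower", extent=extent, aspect="auto",
                   cmap="Greys", vmin=0, vmax=1.6)
    axes[0].set_title("achievable (ADC, T1) combinations")
    im = axes[1].imshow(grid.baseline_t2, origin="lower", extent=extent,
                        aspect="auto", cmap="viridis")
    fig.colorbar(im, ax=axes[1], label="baseline T2 (ms)")
    axes[1].set_title("baseline T2 before agarose")
    for ax in axes:
        for name, t in targets.items():
            if extent[0] <= t.adc <= extent[1] and extent[2] <= t.t1 <= extent[3]:
                ax.plot(t.adc, t.t1, "r.", ms=6)
                ax.annotate(name, (t.adc, t.t1), fontsize=7,
                            textcoords="offset points", xytext=(4, 2))
        ax.set_xlabel("ADC (10$^{-3}$ mm$^2$/s)")
        ax.set_ylabel("T1 (ms)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# temporal-stability fixture and trend analysis
# ---------------------------------------------------------------------------

def make_stability_fixture(targets: dict[str, TissueTarget] | None = None,
                           n_weeks: int = 12, noise_frac: float = 0.01,
                           drift_per_week: float = 0.0,
                           seed: int | None = None) -> pd.DataFrame:
    """Synthetic longitudinal ROI means over a storage period.

    The underlying truth is stationary (zero drift) unless
    ``drift_per_week`` (relative change per week) is set; each weekly
    value gets iid Gaussian measurement noise of relative SD
    ``noise_frac`` (1 % by default, the scanner-repeatability scale seen
    in water reference measurements).  Columns: week, name, parameter,
    value.
    """
    if targets is None:
        targets = tissue_targets()
    if n_weeks < 3:
        raise ValueError("need at least 3 time points")
    rng = np.random.default_rng(seed)
    weeks = np.arange(1, n_weeks + 1)
    rows = []
    for name, t in targets.items():
        for param, truth in (("t1", t.t1), ("t2", t.t2), ("adc", t.adc)):
            base = truth * (1.0 + drift_per_week * (weeks - 1))
            vals = base + rng.normal(0.0, noise_frac * truth, size=n_weeks)
            for w, v in zip(weeks, vals):
                rows.append({"week": int(w), "name": name,
                             "parameter": param, "value": float(v)})
    return pd.DataFrame(rows)


def stability_report(fixture: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-series linear drift estimate with confidence interval.

    For each (name, parameter) series the value is regressed on week;
    drift is flagged when the two-sided (1 - alpha) confidence interval of
    the slope excludes zero.  Requires >= 3 time points per series.
    """
    required = {"week", "name", "parameter", "value"}
    if not required.issubset(fixture.columns):
        raise ValueError(f"fixture must have columns {sorted(required)}")
    rows = []
    for (name, param), grp in fixture.groupby(["name", "parameter"], sort=False):
        if len(grp) < 3:
            raise ValueError(f"series {name}/{param} has fewer than 3 time points")
        res = stats.linregress(grp["week"], grp["value"])
        n = len(grp)
        if res.stderr == 0:
            lo = hi = res.slope
        else:
            tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
            lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
        rows.append({
            "name": name, "parameter": param,
            "slope_per_week": float(res.slope),
            "ci_low": float(lo), "ci_high": float(hi),
            "drift_flagged": bool(lo > 0 or hi < 0),
        })
    return pd.DataFrame(rows)
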