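"""Recovery of relaxivities and the biexponential ADC model from titrations."""

import numpy as np
import pytest

from phantomgel.calibration import (
    DegenerateFitWarning,
    RelaxivityFit,
    TitrationSeries,
    build_calibration,
    fit_adc_model,
    fit_relaxivity,
    generate_titration_design,
    read_titration_csv,
    simulate_titration_responses,
    write_titration_csv,
)
from phantomgel.forward_models import AdcModelParams, SolventBaseline, adc_forward

GD_CONCS = (0.0, 0.05, 0.1, 0.15, 0.2)
LEC_CONCS = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0])


def _ols_3pt(x, y):
    """Independent closed-form OLS oracle on the first three points."""
    x, y = np.asarray(x[:3]), np.asarray(y[:3])
    xb, yb = x.mean(), y.mean()
    slope = np.sum((x - xb) * (y - yb)) / np.sum((x - xb) ** 2)
    return slope, yb - slope * xb


class TestFitRelaxivity:
    def test_noiseless_gd_r1_recovered_exactly(self):
        rates = tuple(0.3333 + 3.78 * c for c in GD_CONCS)
        fit = fit_relaxivity(TitrationSeries("gd", GD_CONCS, rates, "r1"))
        assert fit.slope == pytest.approx(3.78, rel=1e-12)
        assert fit.intercept == pytest.approx(0.3333, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_ols_oracle(self):
        x = (0.0, 0.1, 0.2)
        y = (0.31, 0.75, 1.10)
        fit = fit_relaxivity(TitrationSeries("gd", x, y, "r1"))
        slope, intercept = _ols_3pt(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_flat_series_has_zero_slope(self):
        fit = fit_relaxivity(TitrationSeries("agarose", (0.0, 1.0, 2.0),
                                             (0.5, 0.5, 0.5), "r2"))
        assert fit.slope == 0.0

    def test_noisy_monte_carlo_slope_unbiased(self):
        """Mean slope over 200 noise realizations within 2 SE of the truth."""
        rng = np.random.default_rng(42)
        slopes, ses = [], []
        for _ in range(200):
            rates = 0.3333 + 3.78 * np.asarray(GD_CONCS) + rng.normal(0, 0.02, 5)
            fit = fit_relaxivity(TitrationSeries("gd", GD_CONCS, tuple(rates), "r1"))
            slopes.append(fit.slope)
            ses.append(fit.slope_se)
        assert abs(np.mean(slopes) - 3.78) < 2 * np.mean(ses)

    def test_slope_se_shrinks_with_replication(self):
        """Standard error scales ~1/sqrt(n) on replicated designs."""
        rng = np.random.default_rng(7)

        def mean_se(reps):
            out = []
            for _ in range(100):
                c = np.repeat(GD_CONCS, reps)
                # tiny jitter keeps concentrations strictly increasing per series
                c = np.sort(c + rng.uniform(0, 1e-6, c.size))
                y = 0.3333 + 3.78 * c + rng.normal(0, 0.02, c.size)
                out.append(fit_relaxivity(
                    TitrationSeries("gd", tuple(c), tuple(y), "r1")).slope_se)
            return np.mean(out)

        assert mean_se(4) == pytest.approx(mean_se(1) / 2.0, rel=0.15)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            TitrationSeries("gd", (0.0, 0.1), (0.3, 0.7), "r1")

    def test_adc_series_rejected(self):
        s = TitrationSeries("lecithin", (0.0, 1.0, 2.0), (1.9, 1.4, 1.2), "adc")
        with pytest.raises(ValueError):
            fit_relaxivity(s)


class TestFitAdcModel:
    def test_noiseless_recovery_at_study_concentrations(self, calib):
        y = adc_forward(LEC_CONCS, calib.adc)
        p = fit_adc_model(LEC_CONCS, y)
        for name, true in [("a_fast", 0.36), ("k_fast", 2.79),
                           ("a_slow", 1.60), ("k_slow", 0.13)]:
            assert getattr(p, name) == pytest.approx(true, rel=1e-4)

    def test_self_consistency_random_params(self):
        """Fitting data generated from any well-separated biexponential
        recovers its parameters (noiseless)."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            truth = AdcModelParams(
                a_fast=rng.uniform(0.1, 1.0), k_fast=rng.uniform(1.5, 6.0),
                a_slow=rng.uniform(0.8, 2.0), k_slow=rng.uniform(0.05, 0.3))
            assert truth.k_fast / truth.k_slow >= 5
            c = np.linspace(0, 5, 9)
            p = fit_adc_model(c, adc_forward(c, truth))
            for name in ("a_fast", "k_fast", "a_slow", "k_slow"):
                assert getattr(p, name) == pytest.approx(
                    getattr(truth, name), rel=1e-3)

    def test_single_exponential_flagged_and_rate_recovered(self):
        y = 1.6 * np.exp(-0.13 * LEC_CONCS)
        with pytest.warns(DegenerateFitWarning):
            p = fit_adc_model(LEC_CONCS, y)
        # the fitted curve must collapse onto the generating single exponential
        fitted = adc_forward(LEC_CONCS, p)
        np.testing.assert_allclose(fitted, y, rtol=1e-6)
        assert p.k_slow == pytest.approx(0.13, rel=1e-3)

    def test_noisy_recovery_within_15_percent(self, calib):
        """Median parameter error over 50 noise realizations (1 % multiplicative)
        stays within 15 % relative; the fast decay constant is the weakest,
        being pinned by only the two lowest concentrations."""
        rng = np.random.default_rng(11)
        errs = {n: [] for n in ("a_fast", "k_fast", "a_slow", "k_slow")}
        truth = dict(a_fast=0.36, k_fast=2.79, a_slow=1.60, k_slow=0.13)
        import warnings as _w
        for _ in range(50):
            y = adc_forward(LEC_CONCS, calib.adc) * (
                1 + rng.normal(0, 0.01, LEC_CONCS.size))
            with _w.catch_warnings():
                _w.simplefilter("ignore", DegenerateFitWarning)
                p = fit_adc_model(LEC_CONCS, y)
            for n in errs:
                errs[n].append(abs(getattr(p, n) - truth[n]) / truth[n])
        for n, e in errs.items():
            assert np.median(e) < 0.15, n

    def test_too_few_points_rejected(self, calib):
        c = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_adc_model(c, adc_forward(c, calib.adc))


class TestBuildCalibration:
    @staticmethod
    def _fits():
        mk = lambda s: RelaxivityFit(slope=s, intercept=0.4, slope_se=0.01, r_squared=1.0)  # noqa: E731
        return dict(r1_gd=mk(3.78), r2_gd=mk(4.24), r1_lec=mk(0.10),
                    r2_lec=mk(0.69), r2_agar=mk(6.62))

    def test_assembles_default_like_calibration(self, calib):
        cal = build_calibration(**self._fits(), adc_params=calib.adc,
                                solvent=SolventBaseline.from_times(3000, 2000))
        assert cal.relaxivity == calib.relaxivity

    def test_missing_field_named_in_error(self, calib):
        fits = self._fits()
        fits.pop("r2_agar")
        with pytest.raises(ValueError, match="r2_agar"):
            build_calibration(**fits, adc_params=calib.adc,
                              solvent=SolventBaseline.from_times(3000, 2000))

    def test_negative_relaxivity_rejected(self, calib):
        fits = self._fits()
        fits["r1_lec"] = RelaxivityFit(slope=-0.1, intercept=0.4,
                                       slope_se=0.01, r_squared=0.9)
        with pytest.raises(ValueError, match="r1_lec"):
            build_calibration(**fits, adc_params=calib.adc,
                              solvent=SolventBaseline.from_times(3000, 2000))


class TestTitrationDesign:
    def test_design_follows_stated_grids(self):
        d = generate_titration_design()
        assert len(d) == 46
        gd = d[d.substance == "gd"]
        assert sorted(gd.c_gd.unique()) == [0.0, 0.05, 0.1, 0.15, 0.2]
        lec = d[d.substance == "lecithin"]
        assert sorted(lec.c_lecithin.unique()) == [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0]
        agar = d[d.substance == "agarose"]
        assert sorted(agar.c_agarose.unique()) == [0.0, 1.0, 2.0, 3.0, 4.0]

    def test_round_trip_through_csv_and_full_recovery(self, calib, tmp_path):
        """Simulated noiseless titrations written to CSV, read back, and fitted
        reproduce every shipped calibration coefficient."""
        series = simulate_titration_responses(generate_titration_design(), calib)
        path = tmp_path / "titrations.csv"
        write_titration_csv(series, path)
        back = read_titration_csv(path)
        assert len(back) == len(series)

        fits = {}
        adc_params = None
        abbr = {"gd": "gd", "lecithin": "lec", "agarose": "agar"}
        for s in back:
            if s.response_type == "adc":
                if s.background == s.background.__class__(0, 0, 0):
                    adc_params = fit_adc_model(s.concentrations, s.responses)
            elif not (s.varied_substance == "agarose" and s.response_type == "r1"):
                fits.setdefault(f"{s.response_type}_{abbr[s.varied_substance]}",
                                fit_relaxivity(s))
        cal = build_calibration(**fits, adc_params=adc_params, solvent=calib.solvent)
        for name in ("r1_gd", "r2_gd", "r1_lec", "r2_lec", "r2_agar"):
            assert getattr(cal.relaxivity, name) == pytest.approx(
                getattr(calib.relaxivity, name), rel=1e-9)
        for name in ("a_fast", "k_fast", "a_slow", "k_slow"):
            assert getattr(cal.adc, name) == pytest.approx(
                getattr(calib.adc, name), rel=1e-3)
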