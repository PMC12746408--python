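# Methods

## The problem

Quantitative MRI methods (relaxometry, diffusion imaging) are validated on
test materials with known, stable properties. Most phantom gels control a
single parameter; real tissue pairs a characteristic T1, T2 *and* ADC in
the same voxel. `phantomgel` implements a recipe calculator and an
in-silico validation pipeline for hydrogels built from three compatible
modifiers at 3 T and 20 °C:

* **Gd-DTPA** (mM) — dominant T1 modifier,
* **agarose** (% wt/vol) — dominant T2 modifier,
* **soy lecithin** (% wt/vol) — ADC modifier (lecithin vesicles restrict
  water mobility).

## Forward models

ADC depends only on the lecithin load and is biexponential,

    ADC(C_lec) = a_fast · exp(−k_fast · C_lec) + a_slow · exp(−k_slow · C_lec),

with shipped coefficients (0.36, 2.79, 1.60, 0.13) in units of
10⁻³ mm²/s and (% wt/vol)⁻¹. Relaxation rates are affine in the
concentrations,

    R1 = R1w + r1,Gd·C_Gd + r1,lec·C_lec
    R2 = R2w + r2,Gd·C_Gd + r2,lec·C_lec + r2,agar·C_agar,

with shipped relaxivities r1,Gd = 3.78 s⁻¹ mM⁻¹, r2,Gd = 4.24 s⁻¹ mM⁻¹,
r1,lec = 0.10, r2,lec = 0.69 and r2,agar = 6.62 s⁻¹ (% wt/vol)⁻¹. There is
no agarose term in R1: in the composite gel the longitudinal rate shows no
significant dependence on agarose, so its contribution is treated as zero.
Note that two slightly different transverse relaxivities for agarose
circulate for this system (6.23 vs 6.62 s⁻¹ (% wt/vol)⁻¹, from text and
table of the same characterization); the shipped default uses the tabled
6.62 and the value is a plain YAML field for users who prefer the other.

**Water baselines.** The reference characterization does not state its
measured pure-water rates. The shipped defaults are T1w = 3000 ms and
T2w = 2000 ms, literature-typical for deionized water near 20 °C at 3 T.
Every feasibility number in this package depends on this choice and is
always reported together with it (the demo manifest records the baseline).
Users with measured baselines should edit the calibration file.

**Calibrated ranges.** The models were characterized over Gd-DTPA
0–0.2 mM, agarose 0–4 %, lecithin 0–5 % wt/vol. Concentrations beyond
these are allowed but tagged with an `ExtrapolationWarning` / a recipe
warning flag; ADC accuracy is known to degrade at lecithin ≥ 3 % wt/vol.

## Inverse solver

Because the dependency structure is triangular (ADC ← lecithin;
T1 ← lecithin, Gd; T2 ← all three), the recipe solver proceeds in three
steps: bisection of the strictly decreasing ADC model for the lecithin
concentration (bracket 0–10 % wt/vol, residual tolerance 10⁻¹⁰ in ADC
units), then closed forms for Gd-DTPA and agarose. A target is infeasible
exactly when a closed-form numerator is negative; infeasibility is always
attributed to the single step whose boundary is violated. Exact boundary
hits (a concentration of 0) are feasible; solved concentrations within
0.005 mM (Gd) or 0.02 % (agarose) of zero carry a `near-boundary` flag
since small calibration errors could push the physical recipe outside the
feasible set.

The same closed forms delimit the parameter space: `max_t1_at_adc` is the
zero-Gd T1 ceiling at the lecithin load required for an ADC, and
`baseline_t2` the T2 remaining before agarose addition. The default
feasibility grid is 121 × 131 cells over ADC 0.8–2.0 × T1 700–2000 ms
(0.01 / 10 ms steps), the ranges covering almost all soft tissues. With
the default water baselines the T1 ceiling at ADC = 0.9 is ≈ 1289 ms and
the minimum baseline T2 over the grid is ≈ 208 ms (at the low-ADC/low-T1
corner); gray matter (ADC 0.8–1.0, T1 1500–1850 ms) falls outside the
achievable region. Infeasible targets are only reported, not projected
onto the feasible set.

## Synthetic acquisition

The simulator emulates a 2-D acquisition of gel tubes in a water-filled
cylindrical housing: 128 × 128 matrix over a 200 mm FOV (1.5625 mm
voxels), five 14 mm-radius tubes on a 60 mm ring inside a 75 mm housing.
Protocols:

* **IR-TSE** (T1): nine inversion times, log-spaced 25–6400 ms
  (successive doubling — the exact spacing used in practice is a
  convention here, only the 25–6400 ms span and count are fixed),
  TR = 10 000 ms, TE = 9.9 ms. Signal
  `M0·|1 − 2e^(−TI/T1) + e^(−TR/T1)|`: the finite-TR recovery term is
  included; decay during the 9.9 ms readout is neglected (≲ 20 % scaling
  for the shortest T2 in scope, absorbed into M0, irrelevant to T1).
* **CPMG** (T2): 32 echoes, 10–320 ms equally spaced, TR = 5000 ms;
  `M0·e^(−TE/T2)`.
* **DWI** (ADC): b = 0, 50, 500, 1000 s/mm², TE = 48 ms;
  `S0·e^(−b·ADC·10⁻³)`.

Noise is Rician — `sqrt((x+n1)² + n2²)` with iid zero-mean Gaussians of
standard deviation σ — applied to every voxel. Magnitude (not complex)
data are simulated deliberately, so IR series lose polarity before the
null point exactly as scanner magnitude reconstructions do. `SNR n` means
σ = M0/n with M0 = 1.

What the simulator does **not** model: partial-volume averaging at tube
rims (a voxel belongs to a tube iff its center is inside the circle),
B0/B1 inhomogeneity, k-space/EPI artifacts, stimulated echoes in the CPMG
train, magnetization transfer, kurtosis, perfusion, temperature drift.
Passing the in-silico round trip therefore demonstrates the internal
consistency of recipe → signal → fit under ideal acquisition physics, not
agreement with wet-lab gel measurements.

## Parametric mapping

All fits exploit the separable structure `S = M0 · g(θ, t)`: for fixed θ
the optimal amplitude is a projection, so the sum of squares is profiled
to a 1-D function of θ, minimized by a 96-point log-grid bracket, 40
golden-section iterations, and up to six Gauss-Newton steps on the raw
residuals. (The Gauss-Newton polish exists because the profiled SSE
`‖y‖² − (y·g)²/‖g‖²` cancels catastrophically near the optimum; iterating
on residuals instead recovers noiseless parameters to machine precision.)
The search is vectorized over voxels, so whole 128 × 128 series fit in
about a second.

* **T1**: magnitude-IR polarity is restored exhaustively — for each
  candidate null index k ∈ {0..9} the first k samples are negated, the
  signed model fitted, and the minimum-SSE candidate kept (candidates
  whose profiled amplitude is non-positive are mirror solutions and are
  discarded). Search bounds 5–20 000 ms.
* **T2**: unweighted mono-exponential fit over all 32 echoes in natural
  response space; bounds 1–10 000 ms. No Rician bias correction is
  applied; consequently short-T2 voxels (tail decayed into the noise
  floor, e.g. T2 ≈ 42 ms at TE ≤ 320 ms and SNR 50, floor
  σ√(π/2) ≈ 0.025·M0) are overestimated by roughly 2–3 %. This is the
  dominant error of the whole in-silico pipeline and is visible in the
  demo's T2 deviations.
* **ADC**: ordinary least squares of ln(S) on b over all four b-values;
  voxels with any non-positive signal are flagged out.

Voxels whose first-frame signal is below 5 % of the series maximum are
masked out before fitting. ROI statistics use masked voxels whose centers
fall inside a circle; the demo shrinks each ROI by one voxel relative to
the tube radius to stay off the rim. ROI SD is the sample (ddof = 1)
standard deviation.

## Calibration fitting

Relaxivities are OLS slopes of rate on concentration
(`scipy.stats.linregress`; slope SE from residual variance). The
biexponential ADC model is fitted by multi-start nonlinear least squares:
decay-constant pairs from a log grid over 0.05–10 (% wt/vol)⁻¹, amplitudes
initialized by linear least squares at fixed constants, the best 25 starts
refined (`scipy.optimize.least_squares`, bounded non-negative), best SSE
wins, components ordered k_fast > k_slow. Fits are unweighted and in
natural response space. A collapse to a single exponential (negligible
fast amplitude or nearly coincident constants) raises
`DegenerateFitWarning` rather than failing — the fitted curve is still
valid even though the two components are not separable.

The synthetic characterization design titrates each substance over its
full grid (Gd 5 levels, agarose 5, lecithin 7) at two or three fixed
backgrounds of the other ingredients, yielding 46 design rows; published
counts for this kind of one-varied/others-fixed design vary between 46
and 47 depending on whether a repeated water blank is counted, and this
generator documents its own count rather than claiming either.

## Stability analysis

`make_stability_fixture` produces synthetic longitudinal ROI means over a
12-week storage period: stationary truth (or an injected relative drift
per week) plus 1 % relative Gaussian measurement noise, the repeatability
scale seen in water reference measurements. It is explicitly a synthetic
stand-in — real gels can dehydrate or restructure, and nothing here models
that. `stability_report` fits a per-series linear trend and flags drift
when the two-sided 95 % t-interval of the slope excludes zero. Because the
interval is exact under the fixture's Gaussian noise, the false-alarm rate
is 5 % by construction; the Monte-Carlo check in the test suite verifies
the empirical rate over 100 seeded stationary runs does not exceed that
nominal level, and a 1 %/week injected drift is detected with power ≈ 1.

## Numerical and design choices

* One helper (`phantomgel.units`) owns the ms ↔ s⁻¹ factor-of-1000; ADC is
  always expressed in 10⁻³ mm²/s.
* Bisection uses `scipy.optimize.brentq` with near-machine bracket
  tolerance, then verifies the ADC residual < 10⁻¹⁰.
* The demo fans one global seed out to per-protocol sub-seeds via
  `numpy.random.SeedSequence`, so reports are bit-reproducible.
* Demo problem sizes: the full five-tube 128 × 128 phantom with water
  background (~13 000 fitted voxels per protocol) runs the whole
  solve → simulate → map → validate chain in a few seconds.

## Known limitations

* No temperature or field-strength scaling: all coefficients are 3 T /
  20 °C values.
* The affine relaxation models ignore chemical interactions; physically,
  ADC variability grows at lecithin ≥ 3 % wt/vol and the solver's
  extrapolation warnings mark where trust should drop.
* T2 estimates carry the uncorrected Rician-floor bias described above.
* Feasibility boundaries inherit the uncertainty of the assumed water
  baselines.
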