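# Default calibration for the Gd-DTPA / agarose / soy-lecithin hydrogel system
# at 3 T and 20 degC.  Relaxivities and the biexponential ADC coefficients come
# from the reference titration characterization of this system; the pure-water
# baselines are literature-typical values for ~20 degC at 3 T and should be
# replaced by measured values where available.
units:
  r1_gd: s^-1 mM^-1
  r2_gd: s^-1 mM^-1
  r1_lec: s^-1 (% wt/vol)^-1
  r2_lec: s^-1 (% wt/vol)^-1
  r2_agar: s^-1 (% wt/vol)^-1
  a_fast: 10^-3 mm^2/s
  a_slow: 10^-3 mm^2/s
  k_fast: (% wt/vol)^-1
  k_slow: (% wt/vol)^-1
  t1w_ms: ms
  t2w_ms: ms
  temperature: degC
  field: T
relaxivity:
  r1_gd: 3.78
  r2_gd: 4.24
  r1_lec: 0.10
  r2_lec: 0.69
  r2_agar: 6.62
adc_model:
  a_fast: 0.36
  k_fast: 2.79
  a_slow: 1.60
  k_slow: 0.13
solvent:
  t1w_ms: 3000.0
  t2w_ms: 2000.0
  temperature: 20.0
  field: 3.0
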