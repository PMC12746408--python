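# Shipped tissue targets: (T1 ms, T2 ms, ADC 10^-3 mm^2/s) triples at 3 T,
# 20 degC, for the five reference tissues.  The liver ADC is the build target
# of 1.40; the frequently quoted in-vivo 1.45 is perfusion-influenced.
targets:
  pancreas:        {t1: 725,  t2: 43, adc: 0.98}
  white_matter:    {t1: 1084, t2: 69, adc: 0.84}
  fibroglandular:  {t1: 1444, t2: 54, adc: 1.75}
  liver:           {t1: 812,  t2: 42, adc: 1.40}
  prostate:        {t1: 1597, t2: 80, adc: 1.25}
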