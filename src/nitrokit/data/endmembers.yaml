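# Nitrate source endmembers for coastal East Antarctic lakes (permil).
# Atmospheric: annual-mean snow/atmosphere nitrate at the coastal station.
# Biological: nitrification-produced nitrate (published constant; the
# 1:2 O2:water mixing arithmetic gives -0.5 with the measured pools).
atmospheric:
  d18O: 92.0
  sigma_d18O: 0.0
  D17O: 32.0
  sigma_D17O: 0.0
biological:
  d18O: 0.6
  sigma_d18O: 0.0
  D17O: 0.0
  sigma_D17O: 0.0
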