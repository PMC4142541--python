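# Kinetic rate constants of the alpha1 subunit-containing GABA-A receptor.
# Units: binding rates (k_on, d1d2) in mM^-1 ms^-1; all others in ms^-1.
subtype: alpha1
rates:
  k_on: 20.0
  k_off: 6.0
  a1: 0.06
  b1: 0.03
  a2: 0.4
  b2: 10.0
  d1: 3.3e-4
  r1: 7.0e-4
  d2: 1.2
  r2: 6.0e-3
  d3: 15.0
  r3: 3.75
  d1d2: 15.0
  r1r2: 0.007
g_max_pS: 1323.25
e_rev_mV: -65.0
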