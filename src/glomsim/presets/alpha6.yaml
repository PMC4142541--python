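# Kinetic rate constants of the alpha6 subunit-containing GABA-A receptor.
# Units: binding rates (k_on, d1d2) in mM^-1 ms^-1; all others in ms^-1.
subtype: alpha6
rates:
  k_on: 54.8
  k_off: 0.31
  a1: 0.06
  b1: 0.03
  a2: 0.4
  b2: 10.0
  d1: 0.86
  r1: 0.04
  d2: 2.7
  r2: 0.43
  d3: 15.0
  r3: 7.41
  d1d2: 24.2
  r1r2: 0.09
g_max_pS: 491.58
e_rev_mV: -65.0
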