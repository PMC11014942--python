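# Energy conservation / carbon acquisition marker panel (user-extensible):
# aerobic respiration terminal oxidases, trace-gas oxidation (CO
# dehydrogenase CoxL, uptake [NiFe]-hydrogenase groups), and carbon
# fixation via the Calvin-Benson-Bassham and 3-hydroxypropionate cycles.
processes:
  aerobic_respiration:
    genes: [coxA, ccoN, cydA]
  co_oxidation:
    genes: [coxL]
  h2_oxidation:
    genes: [hyd_NiFe_1h, hyd_NiFe_1l, hyd_NiFe_2a]
  cbb_fixation:
    genes: [rbcL]
  hp_3_fixation:
    genes: [accC, pccB]
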