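# Default nitrogen-cycle marker panel. nirS/nirK sit under
# denitrification only; add them to nitrification for dual attribution
# (they also occur in nitrifier genomes).
processes:
  n2_fixation:
    genes: [nifH]
  nitrification:
    genes: [amoA, hao, nxrB]
  denitrification:
    genes: [napA, narG, nirS, nirK, norB, nosZ]
  dnra:
    genes: [nrfA]
  anr:
    genes: [nasA, nirA]
  anammox:
    genes: [hzo, hzs]
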