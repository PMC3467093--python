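# Beet armyworm (Spodoptera exigua) parameter set before iterative adjustment:
# cold/heat stress values taken directly from laboratory survival literature.
DV0 = 15.06
DV1 = 26
DV2 = 29
DV3 = 36
SM0 = 0.03
SM1 = 0.31
SM2 = 1.00
SM3 = 2.00
TTCS = 0.73    # degC, from survival times at 5 to -10 degC
THCS = 0.1699  # week^-1 (magnitude)
TTHS = 40      # degC
THHS = 0.0177  # week^-1 (magnitude)
SMDS = 0.02
HDS = 0.005
SMWS = 2.5
HWS = 0.002
PDD = 265.6
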