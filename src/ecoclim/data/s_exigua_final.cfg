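# Beet armyworm (Spodoptera exigua) parameter set after iterative adjustment
# against the known world distribution; used for the China projection.
DV0 = 15.06   # degC, minimum temperature for development
DV1 = 26     # degC, lower optimum for population growth
DV2 = 29     # degC, upper optimum
DV3 = 36     # degC, maximum temperature for growth
SM0 = 0.03   # lower soil-moisture threshold (fraction of capacity)
SM1 = 0.31   # lower moisture optimum
SM2 = 1.00   # upper moisture optimum
SM3 = 2.00   # upper moisture limit
TTCS = 3.2   # degC, cold-stress temperature threshold (iterated from 0.73)
THCS = 0.20  # week^-1, cold-stress accumulation rate (magnitude)
TTHS = 36    # degC, heat-stress temperature threshold (iterated from 40)
THHS = 0.0163  # week^-1, heat-stress accumulation rate (magnitude)
SMDS = 0.02  # dry-stress soil-moisture threshold
HDS = 0.005  # week^-1, dry-stress rate (magnitude)
SMWS = 2.5   # wet-stress soil-moisture threshold
HWS = 0.002  # week^-1, wet-stress rate (magnitude)
PDD = 265.6  # degC-days above DV0 to complete one generation
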