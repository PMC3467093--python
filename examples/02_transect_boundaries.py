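"""Latitudinal band structure along the synthetic south-to-north transect.

Runs the model at 45 stations from 18 to 40 degN and prints where the
perennial band ends (EI drops below 30) and where persistence ends
entirely (EI reaches 0), under both the literature-derived and the
iterated stress parameter sets. The iterated set raised the cold-stress
threshold TTCS from 0.73 to 3.2 degC, which pulls the persistence
boundary southward.
"""

import ecoclim as ec

transect = ec.generate_china_transect(45)
for name in ("s_exigua_initial", "s_exigua_final"):
    p = ec.load_fixture(name)
    results = ec.run_network(transect, p)
    perennial = [s.lat for s, r in zip(transect, results) if r.EI >= 30]
    persisting = [s.lat for s, r in zip(transect, results) if r.EI > 0]
    print(f"{name} (TTCS={p.TTCS} degC):")
    print(f"  perennial band up to {max(perennial):.1f}N" if perennial
          else "  no perennial band")
    print(f"  EI>0 (overwinter survival) up to {max(persisting):.1f}N")
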