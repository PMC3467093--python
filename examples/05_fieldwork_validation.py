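"""Model categories versus the 14 winter fieldwork sites.

Matches each fieldwork site (Sanya 18.14N ... Beijing 39.92N; observed
perennial / overwinter / none) to the nearest station of the synthetic
transect and prints the 3x3 confusion table. Strict agreement scores exact
category matches; lenient agreement also credits a perennial prediction at
an observed overwintering site.
"""

import ecoclim as ec
from ecoclim.validation import confusion, match_to_stations

params = ec.load_fixture("s_exigua_final")
transect = ec.generate_china_transect(45)
results = ec.run_network(transect, params)

sites = ec.fieldwork_sites()
matched = match_to_stations(sites, transect, results)
table, strict, lenient = confusion(matched)

print(matched[["site", "observed", "predicted", "EI", "match_km"]].to_string(index=False))
print("\nconfusion (rows observed, columns predicted):")
print(table)
print(f"\nstrict agreement {strict:.3f}, lenient agreement {lenient:.3f}")
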