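"""Station EI values to a gridded suitability surface.

Runs the model on a 45x5 synthetic station network, krigs the EI values
onto a half-degree grid, prints the median overwintering-band boundary
latitudes, and writes the surface as an ESRI ASCII grid plus dissolved
category polygons as GeoJSON (into ./example_output/).
"""

from pathlib import Path

import ecoclim as ec
from ecoclim.mapping import GridSpec, interpolate_ei, overwintering_band
from ecoclim.synthetic import china_transect_spec, generate_network

params = ec.load_fixture("s_exigua_final")
network = generate_network(45, 5, (18.0, 40.0), (108.0, 116.0),
                           china_transect_spec())
df = ec.results_to_frame(network, ec.run_network(network, params))

grid = GridSpec(lat_min=18, lat_max=40, lon_min=108, lon_max=116, cell_size=0.5)
raster = interpolate_ei(df, grid, method="kriging", cutoff_km=500.0)
band = overwintering_band(raster)
print(f"kriging variogram: {raster.method_params['variogram']}")
print(f"overwintering band: {band['south_boundary_lat']:.2f}N (south edge, "
      f"EI drops below 30) to {band['north_boundary_lat']:.2f}N (north edge, EI -> 0)")

out = Path("example_output")
out.mkdir(exist_ok=True)
ec.write_raster(raster, out / "ei.asc")
ec.write_categories_geojson(raster, out / "categories.geojson")
print(f"wrote {out/'ei.asc'}, {out/'ei_category.asc'}, {out/'categories.geojson'}")
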