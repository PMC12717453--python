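"""Island geometry and management networks.

Generates the synthetic 208 km² island stand-in, lays out the trap
lattice matched to the real network's 2353-trap density, and clips
pheromone-decoy grids at several spacings.  Writes the island as GeoJSON
and the trap layout as CSV next to this script.
"""

from pathlib import Path

from stoatsim import (make_synthetic_island, make_trap_network,
                      make_point_grid, save_island, write_points_csv)

out = Path(__file__).parent
island = make_synthetic_island(area_km2=208.0, elongation=2.5, seed=7)
print(f"island area: {island.area_km2:.1f} km^2, "
      f"bounding box {island.bounds[2]/1000:.1f} x "
      f"{island.bounds[3]/1000:.1f} km")

traps = make_trap_network(island, target_count=2353)
print(f"trap lattice: {len(traps)} traps at {traps.spacing:.0f} m spacing")

for spacing in (300, 500, 1000):
    decoys = make_point_grid(island, spacing)
    print(f"decoy grid at {spacing:4d} m: {len(decoys)} decoys")

save_island(island, out / "island.geojson")
write_points_csv(traps, out / "traps.csv")
print(f"\nwrote {out/'island.geojson'} and {out/'traps.csv'}")
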