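"""Nocturnal wind-trajectory projection and occupancy grids.

Projects 30 single-night, 12-hour dusk-start flights from a lower Rio Grande
valley source under two wind regimes — consistent (high von Mises kappa) and
near-isotropic (low kappa) — and contrasts footprint size and directionality.
"""

from fawkit import WindFieldSpec, directionality_stats, gen_wind_nights, nightly_ensemble

SOURCE = (26.09, -98.26)  # Hidalgo County, TX

for label, kappa in (("consistent wind (kappa=50)", 50.0),
                     ("variable wind   (kappa=0.5)", 0.5)):
    spec = WindFieldSpec(
        pattern="seasonal_mean", speed=8.0, bearing=0.0,
        directional_concentration=kappa,
        lat0=18.0, lat1=34.0, lon0=-106.0, lon1=-88.0, n_lat=33, n_lon=37,
        seed=3,
    )
    grid, trajectories = nightly_ensemble(SOURCE, gen_wind_nights(spec, 30))
    stats = directionality_stats([t.endpoint for t in trajectories], SOURCE)
    i, j = grid.cell_of(*SOURCE)
    print(f"{label}:")
    print(f"  cells entered: {(grid.frequency > 0).sum():3d}   "
          f"source-cell frequency: {grid.frequency[i, j]:.0f}%")
    print(f"  mean bearing {stats.mean_bearing_deg:6.1f} deg   "
          f"R = {stats.resultant_length:.2f}   "
          f"mean displacement {stats.mean_displacement_km:.0f} km")
# Consistent nightly winds give a narrow corridor (few cells, R near 1) —
# the directional early-spring regime; variable winds scatter the same
# displacement over many cells with R near 0 — localized dispersal.
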