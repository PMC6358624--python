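"""Spatially smoothed ancestry: place individuals at grandparental
centroids (80-km filter, 24-km display jitter), smooth copying vectors on a
3-km grid with an adaptive Gaussian kernel, and map an admixture gradient."""

import numpy as np

from coanpipe import (
    CopyingParams,
    coancestry_restricted,
    donor_basis_vectors,
    grid_profiles,
    place_individuals,
    simulate_structured_panel,
    smoothed_copying_grid,
)
from coanpipe.simdata import (
    DemeSpec, DemographicScenario, DonorSpec, GenomeSpec, PulseSpec,
    assign_geography,
)

scenario = DemographicScenario(
    demes=[DemeSpec("north", 16, drift=0.05, pool="bg", centroid=(0, 120),
                    dispersion_km=18),
           DemeSpec("south", 16, drift=0.05, pool="bg", centroid=(0, 0),
                    dispersion_km=18)],
    donors=[DonorSpec("near", 10, divergence=0.1, pool="bg"),
            DonorSpec("far", 10, divergence=0.7)],
    pulses=[PulseSpec("far", "south", 0.1, 20)],
    genome=GenomeSpec(4, 80, 320),
    seed=13,
)
panel, _ = simulate_structured_panel(scenario)
assign_geography(panel, scenario, seed=14)
roles = panel.metadata["role"]
study = panel.subset_by_ids(list(roles[roles == "deme"].index))
donors = panel.subset_by_ids(list(roles[roles == "donor"].index))
params = CopyingParams(switch_rate_per_cm=2.0)

placed = place_individuals(study.metadata, seed=15)
print(f"placed {sum(p.retained for p in placed)} of {len(placed)} individuals "
      f"(all four grandparents within 80 km of their centroid)")
_, Xg = coancestry_restricted(study, donors, params)
prop = Xg.to_frame().div(Xg.to_frame().sum(axis=1), axis=0)
grid = smoothed_copying_grid(placed, prop, cell_km=6.0, k_neighbours=12,
                             base_bandwidth_km=25.0)
prof = grid_profiles(grid, donor_basis_vectors(donors, params))
far = prof.values[:, :, list(prof.columns).index("far")]
row = np.nanmean(far, axis=1)
_, ys = prof.cell_centres()
ok = np.isfinite(row)
print("mean 'far' ancestry coefficient by latitude band (south -> north):")
for y, v in zip(ys[ok][::4], row[ok][::4]):
    print(f"  y = {y:6.1f} km   coefficient = {v:.3f}")
print("the simulated 0 -> 0.1 admixture step is recovered as a "
      "south-increasing gradient")
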