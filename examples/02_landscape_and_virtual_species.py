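"""Simulate a landscape and a virtual species with known truth.

The landscape is a stack of correlated smooth predictor surfaces plus a
DEM-like layer; the species' true occurrence probability is a logistic
function of hinge (piecewise-linear) effects, so the exact range is known
and everything downstream can be scored against it.
"""

import numpy as np

from marsflora import (VirtualSpeciesSpec, derive_terrain, make_landscape,
                       make_virtual_species, sample_presences)

stack = make_landscape(seed=3, n_rows=100, n_cols=100, n_predictors=3,
                       correlation=0.3)
print("layers:", stack.names, "grid:", stack.spec.shape)

terrain = derive_terrain(stack["dem"])
slope = terrain["slope"].values
print(f"terrain: slope median {np.nanmedian(slope):.1f} deg, "
      f"northness in [{np.nanmin(terrain['northness'].values):.2f}, "
      f"{np.nanmax(terrain['northness'].values):.2f}]")

species = VirtualSpeciesSpec(
    species_id="demo",
    effects={"env1": [(0.2, 1, 6.0)]},   # logit rises 6 per unit above 0.2
    intercept=-2.0,
    n_train=30,
    seed=7,
)
prob, true_range = make_virtual_species(species, stack)
print(f"true prevalence (mean probability): {prob.values.mean():.3f}")
print(f"true range (p >= 0.5): {int(np.nansum(true_range.values))} cells")

points = sample_presences(prob, n=30, seed=11)
print(f"sampled {len(points)} presence points; "
      f"mean true p at points {prob.sample_at(points['x'], points['y']).mean():.2f}")
# Presence points concentrate where the true probability is high -- the
# presence-only sampling the survey data emulates.
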