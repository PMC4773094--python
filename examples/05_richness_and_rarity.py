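"""Stack range maps into richness, group-richness and rarity surfaces.

Species richness is the cellwise count of overlapping ranges; range-size
rarity replaces the count with the sum of inverse range sizes, so narrowly
distributed species dominate; quintile classes split the non-zero cells into
five equal-count bands for mapping, and mask overlap asks what share of a
region of interest falls in the top classes.
"""

import warnings

import numpy as np

from marsflora import (area_above, mask_overlap_stats, quintile_classes,
                       rarity_weighted, richness_correlation, stack_richness)
from marsflora.experiments import fit_synthetic_community, _range_maps_for
from marsflora.grids import Raster

res = fit_synthetic_community(seed=6, n_species=20)
_, _, range_maps = _range_maps_for(res["model"], res["stack"], res["train"],
                                   methods=("sd_band",))
maps = [range_maps[sp]["sd_band"] for sp in res["model"].species_ids]

richness = stack_richness(maps)
flags = res["train"].group_flags()
ee = [sp for sp in res["model"].species_ids
      if flags.loc[sp, "endangered"] or flags.loc[sp, "endemic"]]
richness_ee = stack_richness(maps, species_filter=ee)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    rarity = rarity_weighted(maps)

print(f"max richness: {int(np.nanmax(richness.values))} of {len(maps)} species")
print(f"endangered/endemic subset: {len(ee)} species, "
      f"max {int(np.nanmax(richness_ee.values))}")
print(f"rarity map total: {np.nansum(rarity.values):.6f} "
      f"(= number of species, by construction)")
cell_km2 = 0.86
print(f"area with > half the species: "
      f"{area_above(richness, len(maps) / 2, cell_km2):.1f} km^2")
print(f"correlation richness vs rarity: "
      f"{richness_correlation(richness, rarity):.2f}")
print(f"correlation richness vs endangered/endemic richness: "
      f"{richness_correlation(richness, richness_ee):.2f}")

classes = quintile_classes(richness)
mask = Raster(richness.spec, (classes.values >= 4).astype(float))
print(f"share of a top-two-quintile mask in the top quintile: "
      f"{mask_overlap_stats(richness, mask, top_classes=1):.2f}")
# Moderate correlations between total richness and the endangered/endemic or
# rarity surfaces are the expected pattern: overall richness is driven by
# widespread species and is an imperfect surrogate for rare ones.
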