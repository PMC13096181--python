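"""Trait-space overlap between managed and wild species groups.

Draws bivariate-normal trait clouds (intertegular distance, tongue length)
with the managed group offset from the wild group, residualises on genus
principal components, and compares kernel-density hypervolumes: overlap
mass, group-unique masses and a permutation test of the overlap.
"""

from beebias.synth import GroupSpec, TraitSpec, gen_traits
from beebias.traits import (
    centroid_distance,
    kde2d,
    overlap_and_unique,
    permutation_null,
    residualize_on_genus_pcs,
)

traits, _ = gen_traits(TraitSpec(
    groups={
        "wild": GroupSpec(offset=(0.0, 0.0), n_species=400),
        "managed": GroupSpec(offset=(1.5, 1.0), n_species=80, managed=True),
    },
    seed=5,
))
coords = residualize_on_genus_pcs(traits)
pts = coords[["x", "y"]].to_numpy()
managed = traits["managed"].to_numpy(dtype=bool)

grid_all = kde2d(pts, grid_size=(120, 120))
extent = (grid_all.x[0], grid_all.x[-1], grid_all.y[0], grid_all.y[-1])
g_managed = kde2d(pts[managed], grid_size=(120, 120), extent=extent)
g_wild = kde2d(pts[~managed], grid_size=(120, 120), extent=extent)
res = overlap_and_unique(g_managed, g_wild, level=0.95)
print(f"n = {len(pts)} species ({managed.sum()} managed)")
print(f"overlap mass          = {res.overlap_mass:.3f}")
print(f"unique managed mass   = {res.unique_mass_a:.3f}")
print(f"unique wild mass      = {res.unique_mass_b:.3f}")
print(f"centroid distance     = {centroid_distance(pts[managed], pts[~managed]):.3f}")

null = permutation_null(
    lambda subset: overlap_and_unique(
        kde2d(subset, grid_size=(120, 120), extent=extent), g_wild
    ).overlap_mass,
    pts, int(managed.sum()), res.overlap_mass, n_perm=199, seed=6, tail="lower",
)
print(f"permutation null mean = {null.null_mean:.3f}, p = {null.p_value:.3f}")
# overlap well below the random-subset null (small p) means the managed
# group occupies a functionally distinct region of trait space rather than
# a representative sample of it.
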