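"""Quantify compositional heterogeneity: what fraction of particles carry an
extra bound factor?

Species A is a flexible chain; species B is the same chain with a compact
companion domain docked next to it.  The reference map mixes the two species
40/60.  Reweighting the concatenated ensemble against that map recovers the
species fractions from the posterior mass on each species' members.
"""

from cryoreweight import standard_reweight
from cryoreweight.synth import (
    add_companion_domain,
    make_compositional_ensemble,
    make_continuous_ensemble,
)

TRUE_B_FRACTION = 0.4

species_a = make_continuous_ensemble(M=30, seed=5, amplitude=4.0)
species_b = add_companion_domain(
    make_continuous_ensemble(M=30, seed=6, amplitude=4.0), seed=7
)
combined, ref, truth, noise = make_compositional_ensemble(
    species_a, species_b, TRUE_B_FRACTION,
    resolution=6.0, noise_fraction=0.01, seed=8,
)

result = standard_reweight(combined, ref, resolution=6.0, noise=noise)

b_mass = result.weights[species_a.n_members:].sum()
print(f"selected theta             : {result.theta:g}")
print(f"species-B fraction (truth) : {TRUE_B_FRACTION:.0%}")
print(f"species-B fraction (found) : {b_mass:.1%}")
# The posterior mass on species-B members reports how much of the map's
# density is explained by particles carrying the companion domain.
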