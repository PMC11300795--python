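"""Recover discrete state populations from a mixed synthetic map.

Builds a 100-member two-state hinged-polymer ensemble, mixes the open and
closed state maps 30/70 at 6 A resolution with 1% Gaussian noise, and runs
standard Bayesian reweighting.  The summed posterior weight of the open-state
members estimates the open population embedded in the map.
"""

import numpy as np

from cryoreweight import standard_reweight
from cryoreweight.synth import make_mixture_reference, make_two_state_ensemble

TRUTH = 0.3

ensemble = make_two_state_ensemble(M=100, seed=11)
ref, truth, noise = make_mixture_reference(
    ensemble, [TRUTH, 1.0 - TRUTH], resolution=6.0, noise_fraction=0.01, seed=12
)

result = standard_reweight(ensemble, ref, resolution=6.0, noise=noise)

is_open = np.array([s.label.startswith("open") for s in ensemble.structures])
recovered = result.weights[is_open].sum()

print(f"selected theta          : {result.theta:g}")
print(f"effective sample size   : {result.neff:.3f}")
print(f"posterior map CC        : {result.cc:.4f}")
print(f"open population (truth) : {TRUTH:.2f}")
print(f"open population (found) : {recovered:.3f}")
# The recovered population should sit within a few percent of the truth:
# the reweighting has shifted mass between the two states to match the map,
# while theta (chosen on the L-curve) keeps Neff high enough that no single
# member dominates.
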