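"""Draw a quenched binding-energy landscape and inspect its hopping rates.

A sliding protein sees each base pair as a site with a random binding free
energy; the roughness mu (k_BT) is the standard deviation of those
energies, and hops across a bond happen with probability
(1/2) min{1, exp(-beta dU)} per attempt time.
"""

import numpy as np

from dnaslide import estimate_roughness, generate_landscape, hopping_probabilities

land = generate_landscape(n_sites=100, mu=0.75, seed=11)
hop = hopping_probabilities(land, beta=1.0)

print(f"generated {land.n_sites} sites at nominal roughness mu = {land.mu_nominal} k_BT")
print(f"empirical roughness (population RMS): {estimate_roughness(land):.4f} k_BT")
print(f"energy range: [{land.energies.min():+.3f}, {land.energies.max():+.3f}] k_BT")
print(f"mean hop probability  <alpha> = {np.mean(hop.alpha_right[:-1]):.4f}")
print(f"mean sojourn (interior)       = {np.mean(hop.sojourn[1:-1]):.4f}")
# The sojourn probability is the chance to hop to neither neighbour in one
# attempt; dissociation can only fire through it, so a rough landscape is
# what exposes the protein to the reaction channel at all.
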