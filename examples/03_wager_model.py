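"""The post-decision wager: expected utility and noisy circle-size choices.

A circle of radius r centered on the saccade endpoint earns 120*exp(-0.4*r)
points if it contains the target (probability = Rayleigh CDF given the
trial's precision J).  The observer noisily maximizes expected utility:
response mass is a softmax of EU with temperature lam.
"""

import numpy as np

from vpalloc import RadiusGrid, expected_utility, points, softmax_radius_density
from vpalloc.wager import optimal_radius

rgrid = RadiusGrid()
print(f"points at r = 0      : {points(0.0):.0f}")
print(f"half-points radius   : {np.log(2) / 0.4:.3f} dva")

print("\n   J    optimal r   EU(r*)   mean chosen r (lam=5)")
for J in (0.3, 1.0, 3.0, 10.0):
    r_star = optimal_radius(J)
    eu = expected_utility(r_star, J)
    mass = softmax_radius_density(J, lam=5.0, rgrid=rgrid)
    print(f" {J:5.1f}    {r_star:5.2f}     {eu:6.1f}        {mass @ rgrid.values:5.2f}")

print("\nHigher precision -> smaller optimal circle and more points: the")
print("wager reads out the observer's trial-by-trial memory uncertainty.")
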