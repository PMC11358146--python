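"""Bootstrap mediation: attentional-state occupancy -> anhedonia -> blunting.

A planted standardized chain (a = 0.54, b = -0.62) is estimated by the
package's mediation model: a from regressing the mediator on the IV, b and
the direct effect c' from the joint regression of the DV, and a percentile
bootstrap for the indirect effect ab.
"""

import numpy as np

from musicstates import mediate

rng = np.random.default_rng(0)
n = 5000
occupancy = rng.normal(size=n)                                   # IV
masq = 0.54 * occupancy + np.sqrt(1 - 0.54**2) * rng.normal(size=n)   # mediator
std = -0.62 * masq + np.sqrt(1 - 0.62**2) * rng.normal(size=n)        # DV

res = mediate(occupancy, masq, std, n_boot=5000, seed=1)
print(f"a  = {res.a:+.3f} (p={res.p_a:.2g})")
print(f"b  = {res.b:+.3f} (p={res.p_b:.2g})")
print(f"ab = {res.ab:+.3f}, 95% bootstrap CI [{res.ci_ab[0]:+.3f}, {res.ci_ab[1]:+.3f}]")
print(f"c' = {res.c_prime:+.3f} (p={res.p_c_prime:.2g}), c = {res.c_total:+.3f}")
print("full mediation:", res.full_mediation)
# ab should sit near 0.54 * -0.62 = -0.335 with a CI excluding zero, while
# the direct effect c' is null: the textbook full-mediation pattern
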