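"""Find equilibria and nullclines for a saturating-benefit mutualism.

With symmetric unit parameters the interior equilibrium of the
partner-saturating model solves N^2 - N - 1 = 0: the golden ratio.
"""
import numpy as np

from mutualism import canonical_params, find_equilibria, nullclines

p = canonical_params("case_1_2", "SC")
eqs = find_equilibria("case_1_2", p)
print("equilibria (position, location, local type):")
for e in eqs:
    print(f"  {e.position_class:9s} {np.round(e.location, 6)}  {e.local_type}")
print("-> the interior node sits at the golden ratio (1.618..., 1.618...),")
print("   above the solo carrying capacity K = r/s = 1 of either species.")

ncs = nullclines("case_1_2", p, resolution=201)
for c in ncs.nontrivial(1):
    print("N1 nullcline geometry:", c.geometry,
          " <- benefits saturating in partner density bend it concave-up")
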