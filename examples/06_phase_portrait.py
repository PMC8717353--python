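"""Render a publication-style phase portrait.

Vector field (arrow angle = direction of density change, color = log
magnitude), nullclines, equilibria (filled black = stable, filled red =
unstable, hollow = saddle) and, for threshold regimes, a dashed separatrix.
"""
from mutualism import (canonical_params, find_equilibria, separatrix)
from mutualism.plotting import render_portrait

p = canonical_params("case_1_2", "HD SC & SC/E threshold")
eqs = find_equilibria("case_1_2", p)
saddles = [e for e in eqs if e.is_saddle]
seps = [separatrix("case_1_2", p, s) for s in saddles]
render_portrait("case_1_2", p, path="portrait_case_1_2.svg",
                equilibria=eqs, separatrices=seps, box=(0, 3))
print("wrote portrait_case_1_2.svg: an obligate saturating pair with its")
print("coexistence node, the saddle below it, and the dashed separatrix")
print("dividing recovery from collapse.")
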