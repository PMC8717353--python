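"""Browse the model registry and evaluate a model by hand.

Every registered model is a pair of ODEs dN_i/dt = f_i(N1, N2) with a
validated parameter schema; derivatives and Jacobians come from a single
symbolic definition.
"""
import numpy as np

from mutualism import get_model, jacobian, list_models, make_params, obligacy, rhs

print(f"{len(list_models())} registered models, e.g.:")
for mid in ["gause_witt_eq1", "holland_deangelis_eq13_bidir", "case_1_1_1"]:
    print(f"  {mid:32s} {get_model(mid).source}")

# a symmetric facultative pair with weak linear benefits
p = make_params("case_1_1_1", r1=1, r2=1, s1=1, s2=1, beta12=0.5, beta21=0.5)
print("\nrhs at (2, 2):", rhs("case_1_1_1", p, (2.0, 2.0)),
      " <- (2,2) is the coexistence equilibrium, both derivatives vanish")
print("Jacobian there:\n", jacobian("case_1_1_1", p, (2.0, 2.0)))
print("eigenvalues:", np.linalg.eigvals(jacobian("case_1_1_1", p, (2.0, 2.0))),
      " <- both negative: a locally stable node")

p_obl = p.replace(r1=-0.5)
print("\nobligacy with r1 = -0.5:", obligacy("case_1_1_1", p_obl),
      " <- species 1 cannot persist alone")
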