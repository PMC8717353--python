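# mutualism

Phase-plane analysis toolkit for two-species mutualism population models.

Mutualisms — pollination, seed dispersal, protection, resource exchange —
are modeled in theoretical ecology as coupled ODEs for two population
densities,

    dN1/dt = f1(N1, N2),    dN2/dt = f2(N1, N2),

where each species' per-capita growth combines an intrinsic rate *r*,
a benefit from the partner (linear `β·N_j`, or saturating, e.g. the
Holling type II form `β·N_j/(h+N_j)`), and intraspecific limitation
(`−s·N_i`, possibly with costs of the interaction). Across ninety years of
such models a small set of qualitative outcomes recurs: **stable
coexistence at high density** when benefits saturate, **unbounded growth**
when linear benefits exceed self-limitation (`β12·β21 > s1·s2`),
**extinction thresholds** when a partner is obligate (negative *r*), and
**Allee, overexploitation, and oscillatory regimes** when costs enter.
This package makes that synthesis runnable:

* a **registry of 28 canonical models** — the classical pairwise equations
  (Gause–Witt, Whittaker, Vandermeer–Boucher, Addicott, Wolin–Lawlor,
  Wright, Zhang, Neuhauser–Fargione, Graves, Thompson, Holland–DeAngelis,
  Fishman–Hadany, Kang, Martignoni, and pollination/seed-dispersal
  consumer–resource pairs) plus nine generic benefit/limitation cases and
  their mixed pairings — each defined symbolically with validated
  parameter schemas, analytic Jacobians, and obligacy determination;
* **phase-plane machinery**: nullclines with geometry summaries,
  equilibria with local stability types, basins of attraction, separatrix
  tracing, and oscillation detection;
* a **qualitative-outcome classifier** mapping any parameterized model to
  the outcome taxonomy (`SC`, `UC`, `E`, the threshold combinations, the
  high-density qualifier, multi-attractor), the threshold-type taxonomy
  (partner threshold / own-density Allee / overexploitation), mutualistic
  vs. parasitic coexistence, and critical interaction strengths;
* a committed **fixture registry** of parameterizations for every regime,
  with expected labels, serving as the regression surface.

Intended users: theoretical ecologists and students exploring mutualism
dynamics, and anyone needing reproducible phase-plane analyses of small
ODE systems with ecological event semantics.

## Worked example

```python
from mutualism import canonical_params, classify_dynamics, find_equilibria

p = canonical_params("case_1_2", "SC")          # saturating benefits, r=s=β=h=1
for e in find_equilibria("case_1_2", p):
    print(e.position_class, e.location, e.local_type)
```

```
origin   (0.0, 0.0)                               unstable_node
axis_1   (1.0, 0.0)                               saddle
axis_2   (0.0, 1.0)                               saddle
interior (1.6180339887498947, 1.618033988749895)  stable_node
```

Alone, each species equilibrates at its carrying capacity K = r/s = 1;
together they settle at the golden ratio φ ≈ 1.618 — the positive root of
N² − N − 1 = 0 that solves `r + β·N/(h+N) = s·N` — i.e. *higher density
than either achieves alone*, the signature of saturating-benefit
mutualism. The classifier packages the same analysis:

```python
rep = classify_dynamics("case_1_2", p)
print(rep.outcome_label, rep.coexistence_character, rep.oscillation)
# SC mutualistic none
```

The `examples/` directory walks through each capability (registry,
nullclines, basins and separatrices, outcome classification, threshold
taxonomy and sweeps, phase portraits); each script prints the numbers it
computes and what they mean.

## Command line

A thin CLI wraps the library for scripted runs:

```sh
mutualism list-models
mutualism analyze case_1_1_1 --fixture "UC/E threshold"
mutualism basins case_1_2 -p r1=-0.5 -p r2=-0.5 -p beta12=3 -p beta21=3
mutualism critical case_1_1_1 -p beta21=1.0 --symbol beta12 --bracket 0.5,2
mutualism portrait case_1_2 --fixture SC
```

Reports are JSON (stable key order, version-pinned), tables CSV, figures
SVG; a YAML config file drives identical runs via `mutualism.run`.

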