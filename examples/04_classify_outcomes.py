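"""Classify parameterized models into the qualitative-outcome taxonomy.

The classifier runs equilibria -> stability -> basins and synthesizes a
label: SC (stable coexistence), UC (unbounded growth), E (extinction), the
threshold combinations between them, and multi-attractor regimes.
"""
from mutualism import canonical_params, classify_dynamics

for mid, regime in [
    ("case_1_1_1", "SC"),
    ("case_1_1_1", "UC"),
    ("case_1_1_1", "UC/E threshold"),
    ("case_1_2", "HD SC & SC/E threshold"),
    ("holland_deangelis_eq13_bidir", "five_interior_equilibria"),
]:
    p = canonical_params(mid, regime)
    rep = classify_dynamics(mid, p)
    n_int = sum(e["class"] == "interior" for e in rep.evidence["equilibria"])
    print(f"{mid:30s} {regime:26s} -> {rep.outcome_label:24s} "
          f"(interior equilibria: {n_int}, coexistence: "
          f"{rep.coexistence_character}, oscillation: {rep.oscillation})")
print("-> the last line is the consumer-resource pair whose lobe-shaped")
print("   nullclines cross five times: three attractors, two saddles.")
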