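"""Qualitative-outcome classification of a parameterized mutualism model.

Maps (model, parameters) to the synthesis vocabulary used throughout the
package: stable coexistence ("SC"), unbounded growth ("UC"), extinction
("E"), the threshold combinations between them, the high-density ("HD")
qualifier, multi-attractor regimes, the threshold taxonomy (partner-density
threshold, own-density Allee effect, overexploitation), mutualistic versus
parasitic coexistence, and critical interaction strengths.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import models as M
from .dynamics import (
    DynamicsSettings,
    Equilibrium,
    default_box,
    find_equilibria,
    single_species_equilibrium,
)
from . import phase as PH
from .phase import PhaseSettings, basin_map

__all__ = [
    "OutcomeReport",
    "SweepResult",
    "ClassifySettings",
    "OUTCOME_LABELS",
    "classify_dynamics",
    "threshold_type",
    "coexistence_character",
    "critical_benefit_strength",
    "sweep",
]

OUTCOME_LABELS = (
    "SC", "UC", "E",
    "UC/E threshold", "SC/E threshold",
    "HD SC & SC/E threshold", "HD UC & UC/SC threshold",
    "HD UC & SC/E threshold",
    "multi-attractor", "unclassified",
)

THRESHOLD_TYPES = ("none", "partner_threshold", "own_density_allee", "overexploitation")


@dataclass(frozen=True)
class ClassifySettings:
    basin_grid_n: int = 61
    t_max: float = 400.0
    probe_n: int = 12
    dynamics: DynamicsSettings = field(default_factory=DynamicsSettings)
    phase: PhaseSettings = field(default_factory=PhaseSettings)


@dataclass(frozen=True)
class OutcomeReport:
    model_id: str
    outcome_label: str
    threshold_type: str
    coexistence_character: str    # mutualistic | parasitic | n/a
    oscillation: str              # none | damped | sustained
    low_confidence: bool
    evidence: dict

    def summary(self) -> dict:
        return {
            "model": self.model_id,
            "outcome_label": self.outcome_label,
            "threshold_type": self.threshold_type,
            "coexistence_character": self.coexistence_character,
            "oscillation": self.oscillation,
            "low_confidence": self.low_confidence,
        }


@dataclass(frozen=True)
class SweepResult:
    symbol: str
    values: tuple[float, ...]
    reports: tuple[OutcomeReport, ...]
    change_brackets: tuple[tuple[float, float], ...]


def _interior_attractors(eqs, attractors):
    pts = [e for e in eqs if e.position_class == "interior" and e.is_attractor]
    cycles = [a for a in attractors if a["type"] == "cycle"]
    return pts, cycles


def classify_dynamics(model, params, box=None,
                      settings: ClassifySettings | None = None) -> OutcomeReport:
    """Full qualitative classification.

    Pipeline: equilibria -> local stability -> basin map -> label synthesis
    from which basins are present (interior attractor / extinction /
    unbounded), with the high-density qualifier attached when the
    coexistence attractor exceeds both single-species equilibria.
    """
    spec = M.get_model(model)
    st = settings or ClassifySettings()
    if box is None:
        box = default_box(spec, params)
    L = float(box[1])
    eqs = find_equilibria(spec, params, box=(0.0, L), settings=st.dynamics)
    bm = basin_map(spec, params, box=(0.0, L), grid_n=st.basin_grid_n,
                   t_max=st.t_max, settings=st.phase, equilibria=eqs)

    # label synthesis uses strictly interior initial conditions when the
    # axes are invariant: orbits started with a species absent answer a
    # different (single-species) question
    if all(M.axis_invariant(spec, params)):
        interior_labels = bm.labels[1:, 1:].ravel().astype(str)
        uniq, cnt = np.unique(interior_labels, return_counts=True)
        counts = dict(zip(uniq.tolist(), cnt.tolist()))
    else:
        counts = bm.counts
    n_cells = sum(counts.values())
    n_horizon = counts.get("horizon", 0)
    n_domain = counts.get("domain", 0)
    has_unbounded = counts.get("unbounded", 0) > 0
    has_extinct = any(k.startswith("extinct") for k in counts)
    point_attr, cycles = _interior_attractors(eqs, bm.attractors)
    ia = len(point_attr) + len(cycles)
    saddles = [e for e in eqs if e.is_saddle]

    k_alone = (single_species_equilibrium(spec, params, 1),
               single_species_equilibrium(spec, params, 2))

    def _hd(e: Equilibrium) -> bool:
        return e.location[0] > k_alone[0] and e.location[1] > k_alone[1]

    if ia >= 2:
        label = "multi-attractor"
    elif ia == 1:
        if has_unbounded and has_extinct:
            label = "HD UC & SC/E threshold"
        elif has_unbounded:
            label = "HD UC & UC/SC threshold"
        elif has_extinct:
            hd = _hd(point_attr[0]) if point_attr else False
            label = "HD SC & SC/E threshold" if hd else "SC/E threshold"
        else:
            label = "SC"
    else:
        if has_unbounded and has_extinct:
            label = "UC/E threshold"
        elif has_unbounded:
            label = "UC"
        elif has_extinct:
            label = "E"
        else:
            label = "unclassified"

    if cycles:
        osc = "sustained"
    elif any(abs(e.eigenvalues[0].imag) > 0 or abs(e.eigenvalues[1].imag) > 0
             for e in point_attr):
        osc = "damped"
    else:
        osc = "none"

    coex = "n/a"
    if point_attr:
        coex = coexistence_character(spec, params, point_attr[0],
                                     k_alone=k_alone)

    low_conf = (n_horizon + n_domain) > 0.1 * n_cells

    report = OutcomeReport(
        model_id=spec.id,
        outcome_label=label,
        threshold_type="none",
        coexistence_character=coex,
        oscillation=osc,
        low_confidence=bool(low_conf),
        evidence={
            "equilibria": [
                {"location": list(e.location), "type": e.local_type,
                 "class": e.position_class,
                 "eigenvalues": [[v.real, v.imag] for v in e.eigenvalues]}
                for e in eqs
            ],
            "basin_counts": counts,
            "attractors": [dict(a) for a in bm.attractors],
            "single_species_equilibria": list(k_alone),
            "box": [0.0, L],
            "grid_n": st.basin_grid_n,
            "t_max": st.t_max,
            "n_saddles": len(saddles),
        },
    )
    tt, fired = _threshold_probe(spec, params, report, (0.0, L), st)
    ev = dict(report.evidence)
    ev["threshold_probes"] = fired
    return OutcomeReport(**{**asdict_shallow(report), "threshold_type": tt,
                            "evidence": ev})


def asdict_shallow(r: OutcomeReport) -> dict:
    return {
        "model_id": r.model_id,
        "outcome_label": r.outcome_label,
        "threshold_type": r.threshold_type,
        "coexistence_character": r.coexistence_character,
        "oscillation": r.oscillation,
        "low_confidence": r.low_confidence,
        "evidence": r.evidence,
    }


# ---------------------------------------------------------------------------
# Threshold taxonomy
# ---------------------------------------------------------------------------

def _probe_outcomes(spec, params, starts, L, st: ClassifySettings):
    """Terminal fate for each probe initial condition: collapse / persist."""
    comp = M._compiled(spec.id)
    vals = M._vals(spec, params)

    def fvec(n1, n2):
        return comp.rhs(n1, n2, *vals)

    pts = np.asarray(starts, float)
    ok = M.valid_mask(spec, params, pts[:, 0], pts[:, 1])
    out = [("invalid", ()) for _ in range(len(pts))]
    if ok.any():
        y, t, status, em = PH._batch_integrate(fvec, pts[ok], 2 * st.t_max, L,
                                               st.phase)
        eps = st.phase.eps_ext_rel * L
        rows = np.nonzero(ok)[0]
        for r, (yk, sk, ek) in zip(rows, zip(y, status, em)):
            if sk == PH.EXTINCT:
                dead = tuple(i + 1 for i in range(2) if ek[i] or yk[i] < 10 * eps)
                out[r] = ("collapse", dead)
            elif sk == PH.CONVERGED:
                low = tuple(i + 1 for i in range(2) if yk[i] < 10 * eps)
                out[r] = ("collapse", low) if low else ("persist", ())
            elif sk == PH.UNBOUNDED:
                out[r] = ("unbounded", ())
            elif sk == PH.DOMAIN:
                out[r] = ("invalid", ())
            else:
                out[r] = ("undetermined", ())
    return out


def _critical_split(values, outcomes, require_species: int | None = None):
    """Classify a 1-D fate series: collapse below / above a critical value.

    A probe counts as collapse only if the required species (when given)
    is among those going extinct.
    """
    usable = [(v, f, dead) for v, (f, dead) in zip(values, outcomes)
              if f in ("collapse", "persist", "unbounded")]
    if len(usable) < 3:
        return None
    fs = []
    for _, f, dead in usable:
        hit = f == "collapse" and (require_species is None or require_species in dead)
        fs.append("collapse" if hit else "persist")
    if "collapse" not in fs or "persist" not in fs:
        return None
    switches = [k for k in range(1, len(fs)) if fs[k] != fs[k - 1]]
    if len(switches) != 1:
        return None
    return "collapse_below" if fs[0] == "collapse" else "collapse_above"


def _threshold_probe(spec, params, report, box, st: ClassifySettings):
    """Operational probes for the threshold taxonomy.

    partner_threshold: with the focal species anchored at high density,
    collapse occurs when the partner starts below a critical density.
    overexploitation: collapse instead occurs when the partner (consumer)
    starts *above* a critical density.  own_density_allee: with the partner
    anchored near its zero-growth level, the focal species collapses below
    a critical density of its own.  Precedence among co-firing probes:
    overexploitation > own_density_allee > partner_threshold.
    """
    L = box[1]
    fired: list[str] = []
    n_sad = report.evidence.get("n_saddles", 0)
    n_basin_labels = len([k for k in report.evidence["basin_counts"]
                          if k not in ("horizon", "domain")])
    if n_sad == 0 or n_basin_labels < 2:
        return "none", fired

    grid = np.linspace(0.02 * L, 0.8 * L, st.probe_n)
    anchor = 0.8 * L
    for focal in (1, 2):
        starts = ([(anchor, v) for v in grid] if focal == 1
                  else [(v, anchor) for v in grid])
        fates = _probe_outcomes(spec, params, starts, L, st)
        split = _critical_split(grid, fates, require_species=focal)
        if split == "collapse_below":
            fired.append(f"partner_threshold(N{focal} anchored high)")
        if _critical_split(grid, fates) == "collapse_above":
            fired.append(f"overexploitation(N{focal} anchored high)")

    # Allee probe: anchor partner near its own zero-growth density
    attr = [a for a in report.evidence["attractors"] if a["type"] == "equilibrium"]
    for focal in (1, 2):
        partner = 3 - focal
        if attr:
            anchor_p = attr[0]["location"][partner - 1]
        else:
            kp = report.evidence["single_species_equilibria"][partner - 1]
            anchor_p = kp if kp > 0 else 0.3 * L
        if anchor_p <= 0:
            continue
        starts = ([(v, anchor_p) for v in grid] if focal == 1
                  else [(anchor_p, v) for v in grid])
        fates = _probe_outcomes(spec, params, starts, L, st)
        if _critical_split(grid, fates, require_species=focal) == "collapse_below":
            fired.append(f"own_density_allee(N{focal})")

    if any(f.startswith("overexploitation") for f in fired):
        return "overexploitation", fired
    if any(f.startswith("own_density_allee") for f in fired):
        return "own_density_allee", fired
    if any(f.startswith("partner_threshold") for f in fired):
        return "partner_threshold", fired
    return "none", fired


def threshold_type(model, params, report: OutcomeReport,
                   settings: ClassifySettings | None = None) -> str:
    """Threshold taxonomy label for a classified system (see module docs)."""
    spec = M.get_model(model)
    st = settings or ClassifySettings()
    box = tuple(report.evidence["box"])
    label, _ = _threshold_probe(spec, params, report, box, st)
    return label


# ---------------------------------------------------------------------------
# Coexistence character
# ---------------------------------------------------------------------------

def coexistence_character(model, params, attractor: Equilibrium,
                          k_alone=None) -> str:
    """"mutualistic" vs "parasitic" coexistence at an interior attractor.

    Mutualistic iff both species sit above their single-species equilibria,
    or increasing either species from equilibrium would permit growth of its
    partner (both off-diagonal Jacobian entries positive); else parasitic.
    """
    spec = M.get_model(model)
    if attractor.position_class != "interior":
        raise ValueError("coexistence character is defined for interior attractors")
    if k_alone is None:
        k_alone = (single_species_equilibrium(spec, params, 1),
                   single_species_equilibrium(spec, params, 2))
    n1, n2 = attractor.location
    if n1 > k_alone[0] and n2 > k_alone[1]:
        return "mutualistic"
    jac = M.jacobian(spec, params, attractor.location, check=False)
    if jac[0, 1] > 0 and jac[1, 0] > 0:
        return "mutualistic"
    return "parasitic"


# ---------------------------------------------------------------------------
# Critical interaction strength
# ---------------------------------------------------------------------------

def _has_interior_attractor(spec, params, base_L, settings) -> bool:
    """Feasibility predicate with an expanding search box.

    Near the feasibility/unboundedness boundary of linear-benefit models the
    interior equilibrium recedes to infinity, so the box is grown until the
    equilibrium set stabilizes.
    """
    L = base_L
    for _ in range(7):
        eqs = find_equilibria(spec, params, box=(0.0, L), settings=settings)
        if any(e.position_class == "interior" and e.is_attractor for e in eqs):
            return True
        # nothing interior at all and nothing near the far edge: stop growing
        near_edge = any(max(e.location) > 0.8 * L for e in eqs)
        if not near_edge and L > 100 * base_L:
            return False
        L *= 10
        if L > 1e8 * base_L:
            break
    return False


def critical_benefit_strength(model, base_params, benefit_symbol: str,
                              bracket, iters: int = 40,
                              settings: DynamicsSettings | None = None) -> float:
    """Bisect the benefit coefficient for the feasibility boundary.

    Finds the value of ``benefit_symbol`` separating parameter regions with
    and without a feasible interior attractor — the smallest benefit
    sustaining coexistence with an obligate partner, or, for linear
    facultative models, the stability/unboundedness boundary.
    """
    spec = M.get_model(model)
    st = settings or DynamicsSettings()
    lo, hi = float(bracket[0]), float(bracket[1])
    base_L = default_box(spec, base_params)[1]

    def feasible(v):
        p = base_params.replace(**{benefit_symbol: v})
        return _has_interior_attractor(spec, p, base_L, st)

    flo, fhi = feasible(lo), feasible(hi)
    if flo == fhi:
        raise ValueError(
            f"bracket endpoints give identical feasibility ({flo}); "
            "bisection needs a sign change")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if feasible(mid) == flo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

def sweep(model, base_params, symbol: str, values,
          settings: ClassifySettings | None = None) -> SweepResult:
    """Classify along a parameter grid and report label-change brackets."""
    spec = M.get_model(model)
    st = settings or ClassifySettings()
    values = tuple(float(v) for v in values)
    reports = []
    for v in values:
        p = base_params.replace(**{symbol: v})
        reports.append(classify_dynamics(spec, p, settings=st))
    brackets = []
    for k in range(1, len(reports)):
        if reports[k].outcome_label != reports[k - 1].outcome_label:
            brackets.append((values[k - 1], values[k]))
    return SweepResult(symbol=symbol, values=values, reports=tuple(reports),
                       change_brackets=tuple(brackets))
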