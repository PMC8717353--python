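"""The model library: classical pairwise-mutualism equations and generic cases.

Each entry defines the pair of right-hand sides symbolically.  The classical
models follow the notation of their original citations (subscripts flattened
to ASCII, e.g. ``alpha12``); printed typography was normalized back to the
algebraic structure each derivation states.  The generic cases parameterize
how benefits from the partner enter a logistic-style backbone:

* Case 1.x — benefits add to per-capita growth; self-limitation ``s_i N_i^theta_i``.
* Case 2.x — benefits saturate with recipient (and possibly partner) density.
* Case 3.x — benefits relax intraspecific density dependence itself.

Mixed pairs (species 1 of one case form, species 2 of another) are registered
under ``case_<row>_vs_<partner>`` ids; they realize the pairings used when
tabulating qualitative outcomes against a linear or a saturating partner.
"""
from __future__ import annotations

import sympy as sp

from .models import (
    ModelSpec,
    N1,
    N2,
    ParameterDescriptor,
    register,
)

_inf = float("inf")


def P(symbol, description, default, lo=0.0, hi=_inf, loi=False, hii=False):
    return ParameterDescriptor(symbol, description, default, lo, hi, loi, hii)


def S(name):
    return sp.Symbol(name, real=True)


# ---------------------------------------------------------------------------
# Table of classical models
# ---------------------------------------------------------------------------

def _gause_witt():
    r1, r2, K1, K2, a12, a21 = map(S, ["r1", "r2", "K1", "K2", "alpha12", "alpha21"])
    f1 = r1 * N1 * (K1 + a12 * N2 - N1) / K1
    f2 = r2 * N2 * (K2 + a21 * N1 - N2) / K2
    register(ModelSpec(
        id="gause_witt_eq1",
        source="Gause & Witt (1935), Eq. 1",
        exprs=(f1, f2),
        schema=(
            P("r1", "intrinsic growth rate of species 1", 1.0),
            P("r2", "intrinsic growth rate of species 2", 1.0),
            P("K1", "carrying capacity of species 1 alone", 1.0),
            P("K2", "carrying capacity of species 2 alone", 1.0),
            P("alpha12", "benefit to 1 per unit partner density", 0.4),
            P("alpha21", "benefit to 2 per unit partner density", 0.4),
        ),
        notes="Lotka-Volterra mutualism; facultative only.",
    ))


def _whittaker():
    r1, r2, K1, K2, a12, a21 = map(S, ["r1", "r2", "K1", "K2", "alpha12", "alpha21"])
    f1 = r1 * N1 * (K1 + a12 * N2 - N1) / (K1 + a12 * N2)
    f2 = r2 * N2 * (K2 + a21 * N1 - N2) / K2
    register(ModelSpec(
        id="whittaker_eq2",
        source="Whittaker (1975), Eq. 2",
        exprs=(f1, f2),
        schema=(
            P("r1", "symbiont intrinsic growth rate", 1.0),
            P("r2", "host intrinsic growth rate", 1.0),
            P("K1", "symbiont capacity alone (0 = obligate)", 0.5, lo=0.0, loi=True),
            P("K2", "host capacity alone", 1.0),
            P("alpha12", "host benefit raising symbiont capacity", 1.0),
            P("alpha21", "symbiont benefit to host (negative = parasitism)", 0.5,
              lo=-_inf),
        ),
        notes="Symbiont (N1) - host (N2); benefit enters the symbiont's "
              "equilibrium density term.",
        validity=lambda p, n1, n2: (p["K1"] + p["alpha12"] * n2 > 0) | (n1 == 0),
        validity_text="symbiont density-limitation denominator K1 + alpha12*N2",
    ))

    r1, r2, K2, a12, a, D = map(S, ["r1", "r2", "K2", "alpha12", "a", "D"])
    f1 = r1 * N1 * (a12 * N2 - N1) / (a12 * N2)
    f2 = r2 * N2 * (K2 + a * D * N1 / (D + N1) - N2) / K2
    register(ModelSpec(
        id="whittaker_eq3",
        source="Whittaker (1975), Eq. 3",
        exprs=(f1, f2),
        schema=(
            P("r1", "symbiont intrinsic growth rate", 1.0),
            P("r2", "host intrinsic growth rate", 1.0),
            P("K2", "host capacity alone", 1.0),
            P("alpha12", "host benefit setting symbiont capacity", 1.0),
            P("a", "maximum proportional host benefit", 1.0),
            P("D", "half-saturation symbiont density for host benefit", 1.0),
        ),
        notes="Obligate symbiont; host benefit saturates with symbiont density.",
        validity=lambda p, n1, n2: (p["alpha12"] * n2 > 0) | (n1 == 0),
        validity_text="symbiont capacity alpha12*N2 must be positive",
    ))


def _vandermeer_boucher():
    r1, r2, a11, a22, a12, a21 = map(
        S, ["r1", "r2", "alpha11", "alpha22", "alpha12", "alpha21"])
    f1 = N1 * (r1 + a12 * N2 - a11 * N1)
    f2 = N2 * (r2 + a21 * N1 - a22 * N2)
    register(ModelSpec(
        id="vandermeer_boucher_eq1",
        source="Vandermeer & Boucher (1978), Eq. 1",
        exprs=(f1, f2),
        schema=(
            P("r1", "intrinsic growth rate of species 1 (<=0: obligate)", 1.0,
              lo=-_inf),
            P("r2", "intrinsic growth rate of species 2 (<=0: obligate)", 1.0,
              lo=-_inf),
            P("alpha11", "self-limitation of species 1", 1.0),
            P("alpha22", "self-limitation of species 2", 1.0),
            P("alpha12", "benefit to 1 from 2", 0.5),
            P("alpha21", "benefit to 2 from 1", 0.5),
        ),
        notes="Obligacy continuum: obligate when K_i = r_i/alpha_ii <= 0.",
    ))


def _addicott():
    r1, r2, K1, K2, a12, a21 = map(S, ["r1", "r2", "K1", "K2", "alpha12", "alpha21"])
    f1 = r1 * N1 * (K1 - N1) / K1 * (1 + a12 * N2 / K1)
    f2 = r2 * N2 * (K2 - N2) / K2 * (1 + a21 * N1 / K2)
    register(ModelSpec(
        id="addicott_eq4",
        source="Addicott (1981), Eq. 4",
        exprs=(f1, f2),
        schema=(
            P("r1", "aphid intrinsic growth rate", 1.0),
            P("r2", "ant intrinsic growth rate", 1.0),
            P("K1", "aphid carrying capacity", 1.0),
            P("K2", "ant carrying capacity", 1.0),
            P("alpha12", "growth-rate benefit to aphids", 0.5),
            P("alpha21", "growth-rate benefit to ants", 0.5),
        ),
        notes="Benefit acts on per-capita growth rate only; equilibrium "
              "density unchanged (vertical/horizontal nullclines).",
    ))


def _wolin_lawlor():
    r1, r2, b, m, d = map(S, ["r1", "r2", "b", "m", "d"])
    f1 = N1 * (r1 - b * N1 / (1 + m * N2) - d * N1)
    f2 = N2 * (r2 - b * N2 / (1 + m * N1) - d * N2)
    register(ModelSpec(
        id="wolin_lawlor_eq5",
        source="Wolin & Lawlor (1984), Eq. 5",
        exprs=(f1, f2),
        schema=(
            P("r1", "intrinsic growth rate of species 1", 1.0),
            P("r2", "intrinsic growth rate of species 2", 1.0),
            P("b", "density-dependent birth limitation", 0.5),
            P("m", "partner relief of birth limitation", 1.0),
            P("d", "density-dependent death rate", 0.5),
        ),
        notes="Facultative only; partner reduces birth limitation toward 0.",
    ))

    f1 = N1 * (r1 - (b - m * N2 + d) * N1)
    f2 = N2 * (r2 - (b - m * N1 + d) * N2)
    register(ModelSpec(
        id="wolin_lawlor_eq6",
        source="Wolin & Lawlor (1984), Eq. 6",
        exprs=(f1, f2),
        schema=(
            P("r1", "intrinsic growth rate of species 1", 1.0),
            P("r2", "intrinsic growth rate of species 2", 1.0),
            P("b", "density-dependent birth limitation", 0.5),
            P("m", "linear partner relief of birth limitation", 0.3),
            P("d", "density-dependent death rate", 0.5),
        ),
        notes="Partner reduces birth limitation without limit; unbounded "
              "growth possible at high partner density.",
    ))


def _wright():
    r1, r2, c1, c2 = map(S, ["r1", "r2", "c1", "c2"])
    b12, b21, a12, a21, h12, h21 = map(
        S, ["b12", "b21", "a12", "a21", "h12", "h21"])
    f1 = N1 * (r1 - c1 * N1 + b12 * a12 * N2 / (1 + a12 * h12 * N2))
    f2 = N2 * (r2 - c2 * N2 + b21 * a21 * N1 / (1 + a21 * h21 * N1))
    register(ModelSpec(
        id="wright_eq7",
        source="Wright (1989), Eq. 7",
        exprs=(f1, f2),
        schema=(
            P("r1", "intrinsic growth rate of species 1 (<=0: obligate)", 1.0,
              lo=-_inf),
            P("r2", "intrinsic growth rate of species 2 (<=0: obligate)", 1.0,
              lo=-_inf),
            P("c1", "self-limitation of species 1", 1.0),
            P("c2", "self-limitation of species 2", 1.0),
            P("b12", "benefit per interaction to species 1", 1.0),
            P("b21", "benefit per interaction to species 2", 1.0),
            P("a12", "encounter rate of 1 with 2", 1.0),
            P("a21", "encounter rate of 2 with 1", 1.0),
            P("h12", "handling time of 1 on 2", 0.5),
            P("h21", "handling time of 2 on 1", 0.5),
        ),
        notes="Holling type II benefit in partner density.",
    ))


def _zhang():
    R1, R2, c1, c2, a1, a2, b1, b2 = map(
        S, ["R1", "R2", "c1", "c2", "a1", "a2", "b1", "b2"])
    f1 = R1 * N1 * (c1 - N1 - a1 * (N2 - b1) ** 2)
    f2 = R2 * N2 * (c2 - N2 - a2 * (N1 - b2) ** 2)
    register(ModelSpec(
        id="zhang_eq8",
        source="Zhang (2003), Eq. 8",
        exprs=(f1, f2),
        schema=(
            P("R1", "rate constant of species 1", 1.0),
            P("R2", "rate constant of species 2", 1.0),
            P("c1", "density scale of species 1", 1.0),
            P("c2", "density scale of species 2", 1.0),
            P("a1", "curvature of interaction effect on 1", 0.5),
            P("a2", "curvature of interaction effect on 2", 0.5),
            P("b1", "partner density maximizing benefit to 1", 1.0, lo=-_inf),
            P("b2", "partner density maximizing benefit to 2", 1.0, lo=-_inf),
        ),
        notes="Phenomenological parabolic nullclines: mutualistic at low, "
              "competitive at high partner density.",
    ))


def _neuhauser_fargione():
    r1, r2, K1, K2, g12, a21, a = map(
        S, ["r1", "r2", "K1", "K2", "gamma12", "alpha21", "a"])
    f1 = N1 * (r1 * (K1 + g12 * N2 - N1) / (K1 + g12 * N2) - a * N2)
    f2 = r2 * N2 * (K2 + a21 * N1 - N2) / K2
    register(ModelSpec(
        id="neuhauser_fargione_eq9",
        source="Neuhauser & Fargione (2004), Eq. 9",
        exprs=(f1, f2),
        schema=(
            P("r1", "plant intrinsic growth rate", 1.0),
            P("r2", "mycorrhizal intrinsic growth rate", 1.0),
            P("K1", "plant carrying capacity", 1.0),
            P("K2", "fungal carrying capacity", 1.0),
            P("gamma12", "fungal benefit raising plant equilibrium", 1.0),
            P("alpha21", "plant benefit to fungus", 0.5),
            P("a", "linear exploitation cost on the plant", 0.2),
        ),
        notes="Plant (N1) - mycorrhizae (N2); benefit plus linear cost.",
    ))


def _graves():
    r10, r11, r20, r21, k1, k2, a1, a2 = map(
        S, ["r10", "r11", "r20", "r21", "k1", "k2", "a1", "a2"])
    f1 = N1 * (r10 + (r11 - r10) * (1 - sp.exp(-k1 * N2)) - a1 * N1)
    f2 = N2 * (r20 + (r21 - r20) * (1 - sp.exp(-k2 * N1)) - a2 * N2)
    register(ModelSpec(
        id="graves_eq10",
        source="Graves et al. (2006), Eq. 10",
        exprs=(f1, f2),
        schema=(
            P("r10", "growth rate of 1 without partner (<=0: obligate)", -0.3,
              lo=-_inf),
            P("r11", "growth rate of 1 at saturating partner density", 1.0,
              lo=-_inf),
            P("r20", "growth rate of 2 without partner (<=0: obligate)", -0.3,
              lo=-_inf),
            P("r21", "growth rate of 2 at saturating partner density", 1.0,
              lo=-_inf),
            P("k1", "benefit accrual rate for 1", 2.0),
            P("k2", "benefit accrual rate for 2", 2.0),
            P("a1", "self-limitation of species 1", 1.0),
            P("a2", "self-limitation of species 2", 1.0),
        ),
        notes="Lichen symbiosis; exponential saturation of growth rate.",
    ))


def _thompson():
    rho1, rho2, b1, b2, I1, I2, S1, S2, c1, c2 = map(
        S, ["rho1", "rho2", "b1", "b2", "I1", "I2", "S1", "S2", "c1", "c2"])
    d1min, d1max, d2min, d2max = map(S, ["d1min", "d1max", "d2min", "d2max"])
    f1 = (rho1 * b1 * N1 + I1) * (1 - N1 / S1) \
        - (d1min + (d1max - d1min) / (1 + c1 * N2)) * N1
    f2 = (rho2 * b2 * N2 + I2) * (1 - N2 / (S2 + N1)) \
        - (d2min + (d2max - d2min) / (1 + c2 * N1)) * N2
    register(ModelSpec(
        id="thompson_eq11_12",
        source="Thompson et al. (2006), Eqs. 11-12",
        exprs=(f1, f2),
        schema=(
            P("rho1", "local recruitment fraction, species 1", 1.0, hi=1.0, hii=True),
            P("rho2", "local recruitment fraction, species 2", 1.0, hi=1.0, hii=True),
            P("b1", "birth rate of species 1", 1.0),
            P("b2", "birth rate of species 2", 1.0),
            P("I1", "immigration into species 1", 0.0, loi=True),
            P("I2", "immigration into species 2", 0.0, loi=True),
            P("S1", "site limit for species 1", 2.0),
            P("S2", "baseline site limit for species 2", 1.0),
            P("c1", "partner-driven mortality relief, species 1", 1.0),
            P("c2", "partner-driven mortality relief, species 2", 1.0),
            P("d1min", "minimum death rate, species 1", 0.2),
            P("d1max", "death rate without partner, species 1", 0.8),
            P("d2min", "minimum death rate, species 2", 0.2),
            P("d2max", "death rate without partner, species 2", 0.8),
        ),
        notes="Hermit crab (N1) - anemone (N2); partner provides habitat to "
              "N2 and reduces mortality.  Closed system when I_i = 0, "
              "rho_i = 1 (the default); the axes are only invariant then.",
    ))


def _holland_deangelis():
    r1, r2, c1, c2, a12, a21, h1, h2 = map(
        S, ["r1", "r2", "c1", "c2", "a12", "a21", "h1", "h2"])
    q1, q2, b12, b21, e1, e2, s1, s2 = map(
        S, ["q1", "q2", "beta12", "beta21", "e1", "e2", "s1", "s2"])
    f1 = N1 * (r1 + c1 * a12 * N2 / (h2 + N2)
               - q1 * b12 * N2 / (e1 + N1) - s1 * N1)
    f2 = N2 * (r2 + c2 * a21 * N1 / (h1 + N1)
               - q2 * b21 * N1 / (e2 + N2) - s2 * N2)
    common = (
        P("r1", "intrinsic growth rate of species 1", 1.0, lo=-_inf),
        P("r2", "intrinsic growth rate of species 2", 1.0, lo=-_inf),
        P("c1", "benefit conversion for species 1", 1.0),
        P("c2", "benefit conversion for species 2", 1.0),
        P("a12", "consumption rate of 1 on 2's resources", 1.0),
        P("a21", "consumption rate of 2 on 1's resources", 1.0),
        P("h1", "half-saturation of consumption on 1", 0.5),
        P("h2", "half-saturation of consumption on 2", 0.5),
        P("q1", "cost conversion for species 1", 1.0),
        P("q2", "cost conversion for species 2", 1.0),
        P("beta12", "extraction pressure of 2 on 1", 0.5),
        P("beta21", "extraction pressure of 1 on 2", 0.5),
        P("e1", "cost half-saturation in own density, species 1", 0.5),
        P("e2", "cost half-saturation in own density, species 2", 0.5),
        P("s1", "self-limitation of species 1", 0.3),
        P("s2", "self-limitation of species 2", 0.3),
    )
    register(ModelSpec(
        id="holland_deangelis_eq13_bidir",
        source="Holland & DeAngelis (2010), Eq. 13 (bidirectional)",
        exprs=(f1, f2),
        schema=common,
        notes="Bidirectional consumer-resource mutualism: each species has a "
              "saturating benefit and a saturating cost functional response.",
        functional_responses=(
            {"species": 1, "kind": "benefit", "form": "saturating", "interspecific": True},
            {"species": 1, "kind": "cost", "form": "saturating", "interspecific": True},
            {"species": 2, "kind": "benefit", "form": "saturating", "interspecific": True},
            {"species": 2, "kind": "cost", "form": "saturating", "interspecific": True},
        ),
    ))

    f1u = N1 * (r1 + c1 * a12 * N2 / (h2 + N2)
                - q1 * b12 * N2 / (e1 + N1) - s1 * N1)
    f2u = N2 * (r2 + c2 * a21 * N1 / (h1 + N1) - s2 * N2)
    register(ModelSpec(
        id="holland_deangelis_eq13_7_unidir",
        source="Holland & DeAngelis (2010), Eq. 13.7 (unidirectional)",
        exprs=(f1u, f2u),
        schema=tuple(d for d in common
                     if d.symbol not in {"q2", "beta21", "e2"}),
        notes="Unidirectional consumer-resource mutualism, e.g. plant (N1) - "
              "pollinator (N2): only the resource species pays a variable cost.",
        functional_responses=(
            {"species": 1, "kind": "benefit", "form": "saturating", "interspecific": True},
            {"species": 1, "kind": "cost", "form": "saturating", "interspecific": True},
            {"species": 2, "kind": "benefit", "form": "saturating", "interspecific": True},
        ),
    ))


def _fishman_hadany():
    eta, mu, alpha, beta, b, c, d = map(
        S, ["eta", "mu", "alpha", "beta", "b", "c", "d"])
    denom = 1 + alpha * N1 + alpha * beta * N2
    f1 = N1 * (eta * alpha * N2 / denom - b - c * N1)
    f2 = N2 * (mu * alpha * N1 / denom - d)
    register(ModelSpec(
        id="fishman_hadany_eq14_15",
        source="Fishman & Hadany (2010), Eqs. 14-15",
        exprs=(f1, f2),
        schema=(
            P("eta", "plant benefit per pollinator visit", 2.0),
            P("mu", "pollinator benefit per visit", 2.0),
            P("alpha", "visit encounter rate", 1.0),
            P("beta", "pollinator interference coefficient", 0.5),
            P("b", "plant baseline mortality", 0.3),
            P("c", "plant self-limitation", 0.2),
            P("d", "pollinator mortality", 0.3),
        ),
        notes="Plant (N1) - pollinator (N2); both species obligate.",
    ))


def _kang():
    rf, rc, r, a, b, d1, d2 = map(S, ["rf", "rc", "r", "a", "b", "d1", "d2"])
    f1 = N1 * (rf * a * N2 ** 2 / (b + a * N2 ** 2) - rc * N2 - d1 * N1)
    f2 = N2 * (r * a * N1 - d2 * N2)
    register(ModelSpec(
        id="kang_eq16",
        source="Kang et al. (2011), Eq. 16",
        exprs=(f1, f2),
        schema=(
            P("rf", "maximum fungal growth from ant tending", 2.0),
            P("rc", "fungal consumption cost per ant", 0.1),
            P("r", "ant growth per unit fungal garden", 1.0),
            P("a", "division-of-labor scaling", 1.0),
            P("b", "half-saturation of colony workforce", 0.5),
            P("d1", "fungal self-limitation", 0.5),
            P("d2", "ant self-limitation", 1.0),
        ),
        notes="Fungal garden (N1) - leaf-cutter ants (N2); both obligate.",
    ))


def _martignoni():
    rp, qhp, qcp, qhm, qcm, alpha, beta, d, mup, mum = map(
        S, ["rp", "qhp", "qcp", "qhm", "qcm", "alpha", "beta", "d", "mup", "mum"])
    f1 = N1 * (rp + qhp * alpha * N2 / (d + N1) - qcp * beta * N2 - mup * N1)
    f2 = N2 * (qcm * beta * N1 - qhm * alpha * N1 / (d + N1) - mum * N2)
    register(ModelSpec(
        id="martignoni_eq17_18",
        source="Martignoni et al. (2020), Eqs. 17-18",
        exprs=(f1, f2),
        schema=(
            P("rp", "plant intrinsic growth rate", 0.5),
            P("qhp", "plant gain per unit phosphorus delivered", 1.0),
            P("qcp", "plant carbon cost per unit fungus", 0.2),
            P("qhm", "fungal phosphorus delivery cost", 0.2),
            P("qcm", "fungal gain per unit carbon received", 1.0),
            P("alpha", "phosphorus exchange rate", 1.0),
            P("beta", "carbon exchange rate", 1.0),
            P("d", "half-saturation plant density for exchange", 1.0),
            P("mup", "plant self-limitation", 1.0),
            P("mum", "fungal self-limitation", 1.0),
        ),
        notes="Plant (N1) - mycorrhizae (N2); fungus obligate.",
    ))


def _hale():
    bP, bA, f, g, phi, eps, a, h = map(
        S, ["bP", "bA", "f", "g", "phi", "epsilon", "a", "h"])
    sP, sA, dP, dA = map(S, ["sP", "sA", "dP", "dA"])
    pollinator = N2 * (bA + eps * a * N1 / (1 + a * h * N1) - sA * N2 - dA)
    fresp = a * N2 * N1 / (1 + a * h * N1 + a * N2 * N1)
    f1 = N1 * (bP * g * (f + phi * fresp) - sP * N1 - dP)
    register(ModelSpec(
        id="hale_eq19_7_pollination",
        source="Hale et al. (2021), Eqs. 19 & 7 (pollination)",
        exprs=(f1, pollinator),
        schema=(
            P("bP", "plant birth rate", 1.0),
            P("bA", "pollinator baseline birth rate", 0.5, lo=-_inf),
            P("f", "fraction of ovules self-fertilized", 0.1),
            P("g", "germination/recruitment probability", 1.0),
            P("phi", "fertilization efficiency of visits", 1.0),
            P("epsilon", "pollinator gain per visit", 1.0),
            P("a", "visitation encounter rate", 1.0),
            P("h", "handling time per flower", 0.5),
            P("sP", "plant self-limitation", 0.5),
            P("sA", "pollinator self-limitation", 0.5),
            P("dP", "plant death rate", 0.3),
            P("dA", "pollinator death rate", 0.3),
        ),
        notes="Plant (N1) - pollinator (N2).  Plant benefit scales with total "
              "visitation, vanishing at low plant density (emergent Allee "
              "effect); plant obligate when bP*f*g - dP <= 0.",
    ))

    sigma = S("sigma")
    f1d = N1 * (bP * f * g
                - (sP - sigma * a * N2 / (1 + a * h * N1 + a * N2 * N1)) * N1
                - dP)
    register(ModelSpec(
        id="hale_eq20_7_dispersal",
        source="Hale et al. (2021), Eqs. 20 & 7 (seed dispersal)",
        exprs=(f1d, pollinator),
        schema=(
            P("bP", "plant birth rate", 1.0),
            P("bA", "disperser baseline birth rate", 0.5, lo=-_inf),
            P("f", "fraction of seeds recruiting unassisted", 1.0),
            P("g", "germination/recruitment probability", 1.0),
            P("sigma", "dispersal relief of density-dependent seed mortality", 0.5),
            P("epsilon", "disperser gain per visit", 1.0),
            P("a", "visitation encounter rate", 1.0),
            P("h", "handling time per fruit", 0.5),
            P("sP", "plant self-limitation (Janzen-Connell)", 0.5),
            P("sA", "disperser self-limitation", 0.5),
            P("dP", "plant death rate", 0.3),
            P("dA", "disperser death rate", 0.3),
        ),
        notes="Plant (N1) - seed disperser (N2).  Dispersal relaxes the "
              "plant's density-dependent seed mortality (bounded relief); "
              "plant facultative, disperser obligate when bA - dA <= 0.",
    ))


# ---------------------------------------------------------------------------
# Generic cases (the synthesis table)
# ---------------------------------------------------------------------------

GENERIC_CASES = ("1_1_1", "1_1_2", "1_1_3", "1_2", "2_1", "2_2", "3_1", "3_2", "3_3")

_CASE_TEXT = {
    "1_1_1": "linear benefit to per-capita growth; power-law self-limitation",
    "1_1_2": "linear benefit; decelerating self-limitation (0 < theta < 1)",
    "1_1_3": "linear benefit; accelerating self-limitation (theta > 1)",
    "1_2": "benefit saturating in partner density; linear self-limitation",
    "2_1": "benefit saturating in recipient density",
    "2_2": "benefit saturating in recipient and partner density",
    "3_1": "benefit raises carrying capacity linearly",
    "3_2": "benefit reduces self-limitation linearly",
    "3_3": "benefit reduces self-limitation, saturating in both densities",
}


def _case_species(case: str, i: int):
    """Symbolic rhs and schema for species ``i`` following one generic form."""
    j = 3 - i
    Ni = N1 if i == 1 else N2
    Nj = N2 if i == 1 else N1
    ij = f"{i}{j}"
    r = S(f"r{i}")
    descs = [P(f"r{i}", f"intrinsic growth rate of species {i} (<=0: obligate)",
               1.0, lo=-_inf)]
    if case in ("1_1_1", "1_1_2", "1_1_3"):
        b, s, th = S(f"beta{ij}"), S(f"s{i}"), S(f"theta{i}")
        expr = Ni * (r + b * Nj - s * Ni ** th)
        th_default, th_lo, th_hi = {
            "1_1_1": (1.0, 0.0, _inf),
            "1_1_2": (0.5, 0.0, 1.0),
            "1_1_3": (2.0, 1.0, _inf),
        }[case]
        descs += [
            P(f"beta{ij}", f"linear benefit to {i} per unit partner density", 0.5),
            P(f"s{i}", f"self-limitation coefficient of species {i}", 1.0),
            P(f"theta{i}", f"self-limitation exponent of species {i}",
              th_default, lo=th_lo, hi=th_hi),
        ]
    elif case == "1_2":
        b, s, h = S(f"beta{ij}"), S(f"s{i}"), S(f"h{ij}")
        expr = Ni * (r + b * Nj / (h + Nj) - s * Ni)
        descs += [
            P(f"beta{ij}", f"maximum benefit rate to species {i}", 1.0),
            P(f"s{i}", f"self-limitation coefficient of species {i}", 1.0),
            P(f"h{ij}", "half-saturation partner density", 1.0),
        ]
    elif case == "2_1":
        b, s, h = S(f"beta{ij}"), S(f"s{i}"), S(f"h{ij}")
        expr = Ni * (r + b * Nj / (h + Ni) - s * Ni)
        descs += [
            P(f"beta{ij}", f"benefit rate to species {i}", 1.0),
            P(f"s{i}", f"self-limitation coefficient of species {i}", 1.0),
            P(f"h{ij}", "half-saturation recipient density", 1.0),
        ]
    elif case == "2_2":
        b, s, h = S(f"beta{ij}"), S(f"s{i}"), S(f"h{ij}")
        expr = Ni * (r + b * Nj / (h + Ni + Nj) - s * Ni)
        descs += [
            P(f"beta{ij}", f"benefit rate to species {i}", 1.0),
            P(f"s{i}", f"self-limitation coefficient of species {i}", 1.0),
            P(f"h{ij}", "half-saturation total density", 1.0),
        ]
    elif case == "3_1":
        K = S(f"K{i}")
        expr = r * Ni * (1 - Ni / (K + Nj))
        descs = [
            P(f"r{i}", f"intrinsic growth rate of species {i}", 1.0),
            P(f"K{i}", f"carrying capacity of species {i} alone "
                       "(<=0: obligate, historical convention)", 1.0, lo=-_inf),
        ]
    elif case == "3_2":
        b, s = S(f"beta{ij}"), S(f"s{i}")
        expr = Ni * (r - (s - b * Nj) * Ni)
        descs += [
            P(f"beta{ij}", f"linear relief of self-limitation of {i}", 0.25),
            P(f"s{i}", f"self-limitation coefficient of species {i}", 1.0),
        ]
    elif case == "3_3":
        b, s, h = S(f"beta{ij}"), S(f"s{i}"), S(f"h{ij}")
        expr = Ni * (r - (s - b * Nj / (h + Ni + Nj)) * Ni)
        descs += [
            P(f"beta{ij}", f"saturating relief of self-limitation of {i}", 0.5),
            P(f"s{i}", f"self-limitation coefficient of species {i}", 1.0),
            P(f"h{ij}", "half-saturation total density", 1.0),
        ]
    else:  # pragma: no cover
        raise ValueError(case)
    return expr, tuple(descs), case == "3_1"


def _register_generic(case1: str, case2: str, model_id: str) -> None:
    e1, d1, k1conv = _case_species(case1, 1)
    e2, d2, k2conv = _case_species(case2, 2)
    validity = None
    vtext = ""
    if k1conv or k2conv:
        def validity(p, n1, n2, _c1=k1conv, _c2=k2conv):
            ok = (n1 >= 0) & (n2 >= 0)
            if _c1:
                ok = ok & ((p["K1"] + n2 > 0) | (n1 == 0))
            if _c2:
                ok = ok & ((p["K2"] + n1 > 0) | (n2 == 0))
            return ok
        vtext = "carrying-capacity denominator K_i + N_j must stay positive"

    def _oblig(values, _c1=k1conv, _c2=k2conv):
        out = {}
        if _c1:
            out[1] = "facultative" if values["K1"] > 0 else "obligate"
        if _c2:
            out[2] = "facultative" if values["K2"] > 0 else "obligate"
        return out

    label = (f"Case {case1.replace('_', '.')}"
             if case1 == case2 else
             f"Case {case1.replace('_', '.')} (N1) vs Case {case2.replace('_', '.')} (N2)")
    register(ModelSpec(
        id=model_id,
        source=f"Generic synthesis model, {label}",
        exprs=(e1, e2),
        schema=d1 + d2,
        notes=f"N1: {_CASE_TEXT[case1]}; N2: {_CASE_TEXT[case2]}.",
        validity=validity,
        validity_text=vtext,
        obligacy_override=_oblig if (k1conv or k2conv) else None,
    ))


def _register_generics():
    for case in GENERIC_CASES:
        _register_generic(case, case, f"case_{case}")
    # mixed pairs used to tabulate outcomes against a linear (1.1.1) or a
    # saturating (1.2) partner
    for case in GENERIC_CASES:
        for partner in ("1_1_1", "1_2"):
            if partner != case:
                _register_generic(case, partner, f"case_{case}_vs_{partner}")


for _fn in (
    _gause_witt, _whittaker, _vandermeer_boucher, _addicott, _wolin_lawlor,
    _wright, _zhang, _neuhauser_fargione, _graves, _thompson,
    _holland_deangelis, _fishman_hadany, _kang, _martignoni, _hale,
    _register_generics,
):
    _fn()

#: The 28 canonical registry keys (classical equations + symmetric cases).
CANONICAL_IDS = (
    "gause_witt_eq1", "whittaker_eq2", "whittaker_eq3",
    "vandermeer_boucher_eq1", "addicott_eq4", "wolin_lawlor_eq5",
    "wolin_lawlor_eq6", "wright_eq7", "zhang_eq8", "neuhauser_fargione_eq9",
    "graves_eq10", "thompson_eq11_12", "holland_deangelis_eq13_bidir",
    "holland_deangelis_eq13_7_unidir", "fishman_hadany_eq14_15", "kang_eq16",
    "martignoni_eq17_18", "hale_eq19_7_pollination", "hale_eq20_7_dispersal",
    "case_1_1_1", "case_1_1_2", "case_1_1_3", "case_1_2", "case_2_1",
    "case_2_2", "case_3_1", "case_3_2", "case_3_3",
)
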