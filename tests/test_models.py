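"""Model registry: lookup, schemas, rhs/Jacobian consistency, obligacy."""
import numpy as np
import pytest

from mutualism import models as M
from mutualism.library import CANONICAL_IDS


PHI = (1 + np.sqrt(5)) / 2


def test_all_canonical_ids_resolve():
    for mid in CANONICAL_IDS:
        spec = M.get_model(mid)
        assert spec.id == mid
    assert len(CANONICAL_IDS) == 28


def test_unknown_id_error_lists_registry():
    with pytest.raises(KeyError) as exc:
        M.get_model("nonexistent")
    msg = str(exc.value)
    assert "nonexistent" in msg
    assert "case_1_1_1" in msg and "zhang_eq8" in msg


def test_rhs_schema_consistency_on_defaults(all_model_ids):
    """Every model evaluates finitely at a generic interior state."""
    for mid in all_model_ids:
        p = M.make_params(mid)
        f = M.rhs(mid, p, (0.7, 1.3), check=False)
        assert np.all(np.isfinite(f)), mid


@pytest.mark.parametrize("state,expected", [
    ((0.0, 0.0), (0.0, 0.0)),
    ((2.0, 2.0), (0.0, 0.0)),
])
def test_linear_case_rhs_closed_form(weak_facultative_linear, state, expected):
    f = M.rhs("case_1_1_1", weak_facultative_linear, state)
    assert f == pytest.approx(expected, abs=1e-12)


def test_saturating_case_golden_ratio_equilibrium(golden_ratio_saturating):
    """r + N/(1+N) = N has the golden ratio as its positive root."""
    f = M.rhs("case_1_2", golden_ratio_saturating, (PHI, PHI))
    assert np.max(np.abs(f)) < 1e-12


def test_linear_case_jacobian_closed_form(weak_facultative_linear):
    j = M.jacobian("case_1_1_1", weak_facultative_linear, (2.0, 2.0))
    assert j == pytest.approx(np.array([[-2.0, 1.0], [1.0, -2.0]]))


def test_jacobian_origin_diagonal_is_percapita_growth(weak_facultative_linear):
    j = M.jacobian("case_1_1_1", weak_facultative_linear, (0.0, 0.0))
    assert j == pytest.approx(np.diag([1.0, 1.0]))


def test_analytic_vs_numeric_jacobian_all_models(all_model_ids, rng):
    """Symbolically derived Jacobians match central differences to 1e-5."""
    for mid in all_model_ids:
        p = M.make_params(mid)
        for _ in range(100):
            state = rng.uniform(0.05, 3.0, size=2)
            if not np.all(M.valid_mask(mid, p, state[0], state[1])):
                continue
            ja = M.jacobian(mid, p, state, check=False)
            jf = M.jacobian_fd(mid, p, state)
            scale = np.max(np.abs(ja)) + 1.0
            assert np.max(np.abs(ja - jf)) / scale < 1e-5, (mid, state)


def test_axis_invariance_structural(all_model_ids, rng):
    """rhs_i vanishes identically on N_i = 0 for axis-invariant models."""
    for mid in all_model_ids:
        p = M.make_params(mid)
        inv = M.axis_invariant(mid, p)
        for i, flag in enumerate(inv):
            if not flag:
                continue
            for _ in range(100):
                other = rng.uniform(0.0, 5.0)
                state = (0.0, other) if i == 0 else (other, 0.0)
                if not np.all(M.valid_mask(mid, p, state[0], state[1])):
                    continue
                f = M.rhs(mid, p, state, check=False)
                assert f[i] == pytest.approx(0.0, abs=1e-12), (mid, i, other)


def test_thompson_axes_not_invariant_with_immigration():
    p = M.make_params("thompson_eq11_12", I1=0.2, I2=0.2)
    assert M.axis_invariant("thompson_eq11_12", p) == (False, False)
    p0 = M.make_params("thompson_eq11_12")  # closed system defaults
    assert M.axis_invariant("thompson_eq11_12", p0) == (True, True)


def test_symmetric_models_equivariant_under_species_swap(rng):
    symmetric = ["gause_witt_eq1", "vandermeer_boucher_eq1", "addicott_eq4",
                 "wolin_lawlor_eq5", "wright_eq7", "zhang_eq8",
                 "holland_deangelis_eq13_bidir", "case_1_1_1", "case_1_2",
                 "case_2_1", "case_2_2", "case_3_1", "case_3_2", "case_3_3"]
    for mid in symmetric:
        p = M.make_params(mid)
        # defaults are symmetric by construction
        for _ in range(20):
            a, b = rng.uniform(0.1, 3.0, size=2)
            f = M.rhs(mid, p, (a, b), check=False)
            g = M.rhs(mid, p, (b, a), check=False)
            assert f[0] == pytest.approx(g[1], rel=1e-12), mid
            assert f[1] == pytest.approx(g[0], rel=1e-12), mid


def test_parameter_validation_rejects_out_of_range():
    with pytest.raises(M.ParameterError):
        M.make_params("case_1_2", beta12=-1.0)
    with pytest.raises(M.ParameterError):
        M.make_params("case_1_1_1", s1=0.0)  # strictly positive
    with pytest.raises(M.ParameterError):
        M.make_params("case_1_1_1", bogus=1.0)
    # sign-unconstrained parameters accept negatives (obligacy, Zhang's b_i)
    M.make_params("case_1_1_1", r1=-0.5)
    M.make_params("zhang_eq8", b1=-2.0)


@pytest.mark.parametrize("mid,kw,expected", [
    ("case_1_2", {"r1": -0.5}, {1: "obligate", 2: "facultative"}),
    ("case_1_1_1", {}, {1: "facultative", 2: "facultative"}),
    ("case_3_1", {"K1": 0.0}, {1: "obligate", 2: "facultative"}),
    ("whittaker_eq2", {"K1": 0.0}, {1: "obligate", 2: "facultative"}),
    ("whittaker_eq3", {}, {1: "obligate", 2: "facultative"}),
    ("fishman_hadany_eq14_15", {}, {1: "obligate", 2: "obligate"}),
    ("kang_eq16", {}, {1: "obligate", 2: "obligate"}),
    ("martignoni_eq17_18", {}, {1: "facultative", 2: "obligate"}),
    ("vandermeer_boucher_eq1", {"r1": -0.1}, {1: "obligate", 2: "facultative"}),
    ("graves_eq10", {"r10": -0.3, "r20": 0.2},
     {1: "obligate", 2: "facultative"}),
])
def test_obligacy_rule(mid, kw, expected):
    """Obligate iff per-capita growth is non-positive alone at low density
    (carrying-capacity convention for the historical Case 3.1 form)."""
    p = M.make_params(mid, **kw)
    assert M.obligacy(mid, p) == expected


def test_hale_pollination_obligacy_matches_birth_death_balance():
    # plant per-capita growth at the origin is bP*f*g - dP
    p = M.make_params("hale_eq19_7_pollination", bP=1.0, f=0.1, g=1.0, dP=0.3)
    assert M.obligacy("hale_eq19_7_pollination", p)[1] == "obligate"
    p2 = M.make_params("hale_eq19_7_pollination", bP=1.0, f=0.5, g=1.0, dP=0.3)
    assert M.obligacy("hale_eq19_7_pollination", p2)[1] == "facultative"


def test_domain_error_for_singular_carrying_capacity():
    p = M.make_params("case_3_1", K1=-1.0)
    with pytest.raises(M.DomainError):
        M.rhs("case_3_1", p, (0.5, 0.5))  # K1 + N2 = -0.5 <= 0
    f = M.rhs("case_3_1", p, (0.5, 2.0))  # valid: K1 + N2 = 1
    assert np.all(np.isfinite(f))


def test_registry_manifest_covers_all_models(all_model_ids):
    man = M.registry_manifest()
    assert {row["id"] for row in man} == set(all_model_ids)
    row = next(r for r in man if r["id"] == "zhang_eq8")
    b1 = next(d for d in row["parameters"] if d["symbol"] == "b1")
    assert "-inf" in b1["range"]


def test_functional_response_metadata_eq13():
    """The bidirectional consumer-resource pair carries four saturating
    interspecific functional responses (two benefits, two costs)."""
    spec = M.get_model("holland_deangelis_eq13_bidir")
    sat = [t for t in spec.functional_responses
           if t["form"] == "saturating" and t["interspecific"]]
    assert len(sat) == 4
    spec_u = M.get_model("holland_deangelis_eq13_7_unidir")
    sat_u = [t for t in spec_u.functional_responses
             if t["form"] == "saturating" and t["interspecific"]]
    assert len(sat_u) == 3
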