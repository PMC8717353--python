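"""Equilibrium finding, stability typing, nullcline geometry."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutualism import models as M
from mutualism import dynamics as D


PHI = (1 + np.sqrt(5)) / 2


def _by_class(eqs, cls):
    return [e for e in eqs if e.position_class == cls]


class TestFindEquilibria:
    def test_weak_facultative_linear_full_set(self, weak_facultative_linear):
        eqs = D.find_equilibria("case_1_1_1", weak_facultative_linear, box=(0, 10))
        assert len(eqs) == 4
        origin, = _by_class(eqs, "origin")
        assert origin.local_type == "unstable_node"
        a1, = _by_class(eqs, "axis_1")
        a2, = _by_class(eqs, "axis_2")
        assert a1.location == pytest.approx((1.0, 0.0), abs=1e-8)
        assert a1.local_type == "saddle" and a2.local_type == "saddle"
        inner, = _by_class(eqs, "interior")
        assert inner.location == pytest.approx((2.0, 2.0), abs=1e-8)
        assert inner.local_type == "stable_node"

    def test_obligate_strong_linear(self, obligate_strong_linear):
        eqs = D.find_equilibria("case_1_1_1", obligate_strong_linear, box=(0, 10))
        origin, = _by_class(eqs, "origin")
        assert origin.local_type == "stable_node"
        assert not _by_class(eqs, "axis_1") and not _by_class(eqs, "axis_2")
        inner, = _by_class(eqs, "interior")
        assert inner.location == pytest.approx((0.5, 0.5), abs=1e-8)
        assert inner.local_type == "saddle"
        assert sorted(v.real for v in inner.eigenvalues) == pytest.approx([-1.5, 0.5])

    def test_golden_ratio_interior(self, golden_ratio_saturating):
        eqs = D.find_equilibria("case_1_2", golden_ratio_saturating)
        inner, = _by_class(eqs, "interior")
        assert inner.location == pytest.approx((PHI, PHI), abs=1e-9)
        assert inner.local_type == "stable_node"

    def test_whittaker_host_symbiont_golden_ratio(self):
        """Symmetric obligate-symbiont parameterization lands on the same
        root of N^2 - N - 1 by coincidence of algebra — a useful cross-model
        closed-form anchor."""
        p = M.make_params("whittaker_eq3")
        eqs = D.find_equilibria("whittaker_eq3", p)
        inner = _by_class(eqs, "interior")
        assert any(e.location == pytest.approx((PHI, PHI), abs=1e-8) for e in inner)

    def test_completeness_under_resolution_doubling(self, rng):
        for mid, kw in [
            ("case_1_1_1", dict(beta12=0.5, beta21=0.5)),
            ("case_1_2", dict(r1=-0.5, r2=-0.5, beta12=3, beta21=3)),
            ("holland_deangelis_eq13_bidir",
             dict(r1=0.15, r2=0.15, a12=1.6, a21=1.6, h1=0.2, h2=0.2,
                  beta12=0.65, beta21=0.65, e1=0.45, e2=0.45, s1=0.5, s2=0.5)),
        ]:
            p = M.make_params(mid, **kw)
            lo = D.find_equilibria(mid, p, settings=D.DynamicsSettings(grid_n=64))
            hi = D.find_equilibria(mid, p, settings=D.DynamicsSettings(grid_n=128))
            assert len(lo) == len(hi), mid
            for a, b in zip(lo, hi):
                assert np.hypot(*(np.subtract(a.location, b.location))) < 1e-4 * 10

    def test_closed_form_linear_interior(self, rng):
        """Case 1.1.1 interior equilibrium equals the 2x2 linear solve."""
        for _ in range(25):
            r1, r2 = rng.uniform(0.2, 1.5, 2)
            b12, b21 = rng.uniform(0.1, 0.9, 2)
            s1 = s2 = 1.0
            p = M.make_params("case_1_1_1", r1=r1, r2=r2, beta12=b12, beta21=b21)
            expect = np.linalg.solve([[s1, -b12], [-b21, s2]], [r1, r2])
            if np.any(expect <= 0):
                continue
            eqs = D.find_equilibria("case_1_1_1", p, box=(0, 10 * expect.max()))
            inner = _by_class(eqs, "interior")
            assert len(inner) == 1
            assert np.allclose(inner[0].location, expect, rtol=1e-8)

    def test_empty_box_rejected(self, weak_facultative_linear):
        with pytest.raises(ValueError):
            D.find_equilibria("case_1_1_1", weak_facultative_linear, box=(0, 0))


class TestClassifyEigenvalues:
    @pytest.mark.parametrize("eig,expected", [
        ((-1.0, -3.0), "stable_node"),
        ((1j, -1j), "nonhyperbolic"),
        ((0.5, -1.5), "saddle"),
        ((-0.5 + 2j, -0.5 - 2j), "stable_spiral"),
        ((0.5 + 2j, 0.5 - 2j), "unstable_spiral"),
        ((0.4, 2.0), "unstable_node"),
        ((1e-9, -1.0), "nonhyperbolic"),
    ])
    def test_mapping(self, eig, expected):
        assert D.classify_equilibrium(eig) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            D.classify_equilibrium((np.nan, 1.0))

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=4))
    def test_matches_matrix_eigen_signs(self, entries):
        """The label always agrees with the sign structure of the
        eigenvalues of the matrix it came from."""
        jac = np.array(entries).reshape(2, 2)
        eig = np.linalg.eigvals(jac)
        label = D.classify_equilibrium(eig)
        re = np.sort(eig.real)
        scale = max(1.0, np.max(np.abs(eig)))
        if np.any(np.abs(eig.real) < 1e-6 * scale):
            assert label == "nonhyperbolic"
        elif re[0] < 0 < re[1]:
            assert label == "saddle"
        elif re[1] < 0:
            assert label.startswith("stable")
        else:
            assert label.startswith("unstable")


class TestNullclines:
    def test_linear_case_increasing_linear(self, weak_facultative_linear):
        ncs = D.nullclines("case_1_1_1", weak_facultative_linear, box=(0, 10),
                           resolution=201)
        curves = ncs.nontrivial(1)
        assert len(curves) == 1
        assert curves[0].geometry == ("increasing", "linear")

    def test_saturating_case_concave_up(self, golden_ratio_saturating):
        ncs = D.nullclines("case_1_2", golden_ratio_saturating, box=(0, 10),
                           resolution=201)
        geo = ncs.nontrivial(1)[0].geometry
        assert geo == ("increasing", "concave_up")

    def test_decelerating_self_limitation_concave_down(self):
        p = M.make_params("case_1_1_2_vs_1_1_1", r1=0.5, beta12=1.0)
        ncs = D.nullclines("case_1_1_2_vs_1_1_1", p, box=(0, 10), resolution=201)
        geo = ncs.nontrivial(1)[0].geometry
        assert geo == ("increasing", "concave_down")

    def test_consumer_resource_lobe(self):
        p = M.make_params(
            "holland_deangelis_eq13_bidir",
            r1=0.15, r2=0.15, a12=1.6, a21=1.6, h1=0.2, h2=0.2,
            beta12=0.65, beta21=0.65, e1=0.45, e2=0.45, s1=0.5, s2=0.5)
        ncs = D.nullclines("holland_deangelis_eq13_bidir", p, resolution=301)
        geoms = [c.geometry for c in ncs.nontrivial(1) + ncs.nontrivial(2)]
        assert any(g[1] == "lobe" for g in geoms)

    def test_crossings_match_equilibria(self, golden_ratio_saturating):
        """Every crossing of an N1-curve and an N2-curve sits at a reported
        equilibrium (within the dedupe radius)."""
        box = (0.0, 10.0)
        ncs = D.nullclines("case_1_2", golden_ratio_saturating, box=box,
                           resolution=301)
        eqs = D.find_equilibria("case_1_2", golden_ratio_saturating, box=box)
        locs = np.array([e.location for e in eqs])
        for c1 in ncs.nontrivial(1):
            for c2 in ncs.nontrivial(2):
                for q in c1.points[::5]:
                    d = np.hypot(*(c2.points - q).T).min()
                    if d < 0.02:  # near a crossing
                        dmin = np.hypot(*(locs - q).T).min()
                        assert dmin < 0.1

    def test_resolution_floor(self, weak_facultative_linear):
        with pytest.raises(ValueError):
            D.nullclines("case_1_1_1", weak_facultative_linear, resolution=20)


class TestSingleSpeciesEquilibrium:
    @pytest.mark.parametrize("mid,kw,species,expected", [
        ("case_1_1_1", {}, 1, 1.0),
        ("case_1_2", {"r1": -0.5}, 1, 0.0),
        ("case_3_1", {"K1": 2.0}, 1, 2.0),
        ("gause_witt_eq1", {"K2": 1.7}, 2, 1.7),
    ])
    def test_carrying_capacity(self, mid, kw, species, expected):
        p = M.make_params(mid, **kw)
        assert D.single_species_equilibrium(mid, p, species) == pytest.approx(
            expected, abs=1e-7)


def test_flow_sign_agrees_with_nullcline_side(weak_facultative_linear):
    """Sign pattern of d(N1)/dt on a dense grid matches which side of the
    N1-nullcline each point lies on (oracle equivalence)."""
    p = weak_facultative_linear
    xs = np.linspace(0.01, 10, 200)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    G = M.per_capita("case_1_1_1", p, (X, Y))
    # nullcline: N2 = (s1*N1 - r1)/beta12 = 2*N1 - 2
    above = Y > 2 * X - 2
    assert np.all((G[0] > 0) == above)
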