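"""Trajectories, basins of attraction, separatrices, oscillations."""
import numpy as np
import pytest

from mutualism import models as M
from mutualism import dynamics as D
from mutualism import phase as P


class TestIntegrate:
    def test_weak_facultative_converges_to_interior(self, weak_facultative_linear):
        tr = P.integrate("case_1_1_1", weak_facultative_linear, (0.1, 0.1),
                         box=(0, 10))
        assert tr.terminal_event == "converged"
        assert tr.attractor == pytest.approx((2.0, 2.0), abs=1e-3)

    def test_obligate_below_saddle_goes_extinct(self, obligate_strong_linear):
        tr = P.integrate("case_1_1_1", obligate_strong_linear, (0.2, 0.2),
                         box=(0, 10))
        assert tr.terminal_event == "extinct"
        assert len(tr.extinct_species) >= 1

    def test_strong_facultative_unbounded(self):
        p = M.make_params("case_1_1_1", beta12=2.0, beta21=2.0)
        tr = P.integrate("case_1_1_1", p, (1.0, 1.0), box=(0, 10))
        assert tr.terminal_event == "unbounded"

    def test_states_nonnegative_and_series_ends_at_event(self, obligate_strong_linear):
        tr = P.integrate("case_1_1_1", obligate_strong_linear, (0.2, 0.2),
                         box=(0, 10))
        assert np.all(tr.y >= 0)
        assert tr.t[-1] == pytest.approx(tr.event_time)


class TestBasinMap:
    def test_weak_facultative_single_interior_basin(self, weak_facultative_linear):
        bm = P.basin_map("case_1_1_1", weak_facultative_linear, box=(0, 10),
                         grid_n=21)
        interior = bm.labels[1:, 1:].ravel()
        labs = set(map(str, interior))
        assert len(labs) == 1 and next(iter(labs)).startswith("eq:")

    def test_obligate_strong_extinct_and_unbounded(self, obligate_strong_linear):
        # box tight enough that the near-origin extinction basin spans
        # several grid cells
        bm = P.basin_map("case_1_1_1", obligate_strong_linear, box=(0, 5),
                         grid_n=21)
        labs = set(map(str, bm.labels[1:, 1:].ravel()))
        assert "unbounded" in labs
        assert any(l.startswith("extinct") for l in labs)
        assert not any(l.startswith("eq:") and
                       bm.equilibria[int(l.split(":")[1])].is_attractor
                       for l in labs)

    def test_obligate_feasible_two_basins(self):
        p = M.make_params("case_1_2", r1=-0.5, r2=-0.5, beta12=3, beta21=3)
        bm = P.basin_map("case_1_2", p, box=(0, 5), grid_n=21)
        labs = set(map(str, bm.labels[1:, 1:].ravel()))
        attractor_labels = {
            l for l in labs if l.startswith("eq:")
            and bm.equilibria[int(l.split(":")[1])].is_attractor}
        extinct_labels = {l for l in labs if l.startswith("extinct")}
        assert len(attractor_labels) == 1 and extinct_labels

    def test_same_orbit_shares_label(self, weak_facultative_linear):
        """Two initial conditions on one computed orbit get the same label."""
        tr = P.integrate("case_1_1_1", weak_facultative_linear, (0.3, 4.0),
                         box=(0, 10))
        mid = tr.y[:, len(tr.t) // 3]
        bm = P.basin_map("case_1_1_1", weak_facultative_linear, box=(0, 10),
                         grid_n=21)
        xs = bm.x0_grid[0]

        def label_at(pt):
            i = int(np.argmin(np.abs(xs - pt[0])))
            j = int(np.argmin(np.abs(xs - pt[1])))
            return str(bm.labels[i, j])

        assert label_at((0.3, 4.0)) == label_at(mid)

    def test_grid_floor(self, weak_facultative_linear):
        with pytest.raises(ValueError):
            P.basin_map("case_1_1_1", weak_facultative_linear, grid_n=5)

    def test_time_horizon_robustness(self, obligate_strong_linear):
        bm1 = P.basin_map("case_1_1_1", obligate_strong_linear, box=(0, 10),
                          grid_n=21, t_max=400)
        bm2 = P.basin_map("case_1_1_1", obligate_strong_linear, box=(0, 10),
                          grid_n=21, t_max=800)
        a, b = bm1.labels.ravel(), bm2.labels.ravel()
        mism = [(x, y) for x, y in zip(a, b) if x != y and "horizon" not in (x, y)]
        assert not mism


class TestSeparatrix:
    def test_branch_direction_along_stable_eigenvector(self, obligate_strong_linear):
        eqs = D.find_equilibria("case_1_1_1", obligate_strong_linear, box=(0, 10))
        saddle = next(e for e in eqs if e.is_saddle)
        sep = P.separatrix("case_1_1_1", obligate_strong_linear, saddle,
                           box=(0, 10))
        # stable eigenvector of [[-0.5, 1], [1, -0.5]] is (1, -1)
        v0 = sep.branches[0][0] - np.asarray(saddle.location)
        v0 /= np.linalg.norm(v0)
        assert abs(abs(v0 @ [1, -1] / np.sqrt(2)) - 1) < 1e-6
        assert all(t in ("box_exit", "origin", "horizon") for t in sep.truncation)

    def test_sides_fall_in_different_basins(self, obligate_strong_linear):
        eqs = D.find_equilibria("case_1_1_1", obligate_strong_linear, box=(0, 10))
        saddle = next(e for e in eqs if e.is_saddle)
        sep = P.separatrix("case_1_1_1", obligate_strong_linear, saddle,
                           box=(0, 10))
        bm = P.basin_map("case_1_1_1", obligate_strong_linear, box=(0, 10),
                         grid_n=41)
        frac = P.separatrix_consistency(sep, bm)
        assert frac >= 0.95

    def test_non_saddle_rejected(self, weak_facultative_linear):
        eqs = D.find_equilibria("case_1_1_1", weak_facultative_linear, box=(0, 10))
        node = next(e for e in eqs if e.local_type == "stable_node")
        with pytest.raises(ValueError):
            P.separatrix("case_1_1_1", weak_facultative_linear, node)


class TestOscillation:
    def test_cost_model_spiral_is_damped(self):
        p = M.make_params("neuhauser_fargione_eq9", r1=1.0, r2=0.25,
                          gamma12=2.0, alpha21=0.75, a=0.35)
        rep = P.detect_oscillation("neuhauser_fargione_eq9", p, (0.3, 0.3))
        assert rep["kind"] == "damped"

    def test_saturating_node_does_not_oscillate(self, golden_ratio_saturating):
        rep = P.detect_oscillation("case_1_2", golden_ratio_saturating,
                                   (0.5, 3.0))
        assert rep["kind"] == "none"

    def test_terminal_events_reported_as_none(self):
        p = M.make_params("case_1_1_1", r1=-0.5, r2=-0.5, beta12=0.5, beta21=0.5)
        rep = P.detect_oscillation("case_1_1_1", p, (0.3, 0.3), box=(0, 10))
        assert rep["kind"] == "none"
        assert rep["terminal"] == "extinct"


class TestBoundednessProperties:
    @pytest.mark.parametrize("mid", ["case_1_2", "case_2_1", "case_2_2"])
    def test_saturating_facultative_pairs_never_unbounded(self, mid):
        """Per-capita growth is bounded by r + beta - s*N, so facultative
        saturating pairs cannot grow without bound from any start."""
        p = M.make_params(mid, r1=1.0, r2=1.0, beta12=3.0, beta21=3.0)
        L = D.default_box(mid, p)[1]
        bm = P.basin_map(mid, p, box=(0, 5 * L), grid_n=21, t_max=300)
        assert "unbounded" not in bm.counts

    def test_saturating_partner_bounds_power_law_focal(self):
        """A Case-1.2 partner is self-bounded, so even a decelerating
        (theta < 1) focal species cannot grow without bound — whatever the
        benefit coefficients."""
        p = M.make_params("case_1_1_2_vs_1_2", r1=1.0, beta12=3.0, theta1=0.5,
                          r2=1.0, beta21=4.0)
        L = D.default_box("case_1_1_2_vs_1_2", p)[1]
        bm = P.basin_map("case_1_1_2_vs_1_2", p, box=(0, 5 * L), grid_n=21,
                         t_max=300)
        assert "unbounded" not in bm.counts

    def test_linear_dichotomy_on_benefit_grid(self):
        """Case 1.1.1 facultative symmetric: unbounded orbits occur iff
        beta12*beta21 > s1*s2."""
        for beta in (0.7, 0.9, 1.1, 1.4):
            p = M.make_params("case_1_1_1", beta12=beta, beta21=beta)
            bm = P.basin_map("case_1_1_1", p, box=(0, 10), grid_n=15,
                             t_max=300)
            has_unbounded = "unbounded" in bm.counts
            assert has_unbounded == (beta * beta > 1.0), beta


def test_stability_flow_agreement(weak_facultative_linear, obligate_strong_linear):
    """Orbits launched just off a stable equilibrium return; off an unstable
    one they leave its neighborhood."""
    for params, mid in [(weak_facultative_linear, "case_1_1_1"),
                        (obligate_strong_linear, "case_1_1_1")]:
        eqs = D.find_equilibria(mid, params, box=(0, 10))
        for e in eqs:
            if e.position_class == "origin" and not e.is_attractor:
                continue  # off-origin perturbations leave the axes anyway
            x0 = np.maximum(np.asarray(e.location) + 1e-3 * 10 / np.sqrt(2), 0)
            tr = P.integrate(mid, params, x0, box=(0, 10), t_max=300)
            d_end = np.hypot(*(tr.final_state - np.asarray(e.location)))
            if e.is_attractor:
                assert d_end < 1e-2
            else:
                assert d_end > 1e-1 or tr.terminal_event in ("extinct", "unbounded")
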