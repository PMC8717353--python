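"""Qualitative-outcome classification, thresholds, sweeps."""
import numpy as np
import pytest

from mutualism import models as M
from mutualism import classify as C
from mutualism import fixtures as FX
from mutualism.dynamics import find_equilibria, single_species_equilibrium

PHI = (1 + np.sqrt(5)) / 2

FAST = C.ClassifySettings(basin_grid_n=41)


class TestClassifyDynamics:
    @pytest.mark.parametrize("regime,expected", [
        ("SC", "SC"),
        ("UC", "UC"),
        ("UC/E threshold", "UC/E threshold"),
        ("E", "E"),
    ])
    def test_linear_regimes(self, regime, expected):
        p = FX.canonical_params("case_1_1_1", regime)
        rep = C.classify_dynamics("case_1_1_1", p, settings=FAST)
        assert rep.outcome_label == expected

    def test_obligate_saturating_high_density_threshold(self):
        p = FX.canonical_params("case_1_2", "HD SC & SC/E threshold")
        rep = C.classify_dynamics("case_1_2", p, settings=FAST)
        assert rep.outcome_label == "HD SC & SC/E threshold"
        # a coexistence attractor sits above both solo densities (0 here)
        att = [a for a in rep.evidence["attractors"] if a["type"] == "equilibrium"]
        assert any(a["location"][0] > 0 and a["location"][1] > 0 for a in att)

    def test_sc_invariant_no_unbounded_cells(self):
        p = FX.canonical_params("case_1_1_1", "SC")
        rep = C.classify_dynamics("case_1_1_1", p, settings=FAST)
        assert "unbounded" not in rep.evidence["basin_counts"]

    def test_label_stable_under_resolution_and_horizon_doubling(self):
        p = FX.canonical_params("case_1_2", "HD SC & SC/E threshold")
        a = C.classify_dynamics("case_1_2", p, settings=C.ClassifySettings(
            basin_grid_n=31, t_max=300))
        b = C.classify_dynamics("case_1_2", p, settings=C.ClassifySettings(
            basin_grid_n=62, t_max=600))
        assert a.outcome_label == b.outcome_label


class TestThresholdTaxonomy:
    def test_partner_threshold_saturating_obligate(self):
        # default grid: the extinction sliver is thinner than coarse spacing
        p = FX.canonical_params("case_1_2", "partner_threshold")
        rep = C.classify_dynamics("case_1_2", p)
        assert rep.threshold_type == "partner_threshold"

    def test_overexploitation_unidirectional_consumer_resource(self):
        p = FX.canonical_params("holland_deangelis_eq13_7_unidir",
                                "overexploitation")
        rep = C.classify_dynamics("holland_deangelis_eq13_7_unidir", p,
                                  settings=FAST)
        assert rep.threshold_type == "overexploitation"

    def test_allee_obligate_pollination(self):
        p = FX.canonical_params("hale_eq19_7_pollination", "allee")
        rep = C.classify_dynamics("hale_eq19_7_pollination", p, settings=FAST)
        assert rep.threshold_type == "own_density_allee"

    def test_no_threshold_without_saddle_split(self):
        p = FX.canonical_params("case_1_1_1", "SC")
        rep = C.classify_dynamics("case_1_1_1", p, settings=FAST)
        assert rep.threshold_type == "none"


class TestCoexistenceCharacter:
    def test_golden_ratio_exceeds_solo_density(self, golden_ratio_saturating):
        eqs = find_equilibria("case_1_2", golden_ratio_saturating)
        att = next(e for e in eqs if e.position_class == "interior")
        assert att.location[0] == pytest.approx(PHI, abs=1e-8)
        # solo carrying capacity is r/s = 1 < phi
        assert C.coexistence_character("case_1_2", golden_ratio_saturating,
                                       att) == "mutualistic"

    def test_costly_partner_can_be_parasitic(self):
        p = FX.canonical_params("neuhauser_fargione_eq9", "parasitic")
        eqs = find_equilibria("neuhauser_fargione_eq9", p)
        att = next(e for e in eqs
                   if e.position_class == "interior" and e.is_attractor)
        assert att.location[0] < single_species_equilibrium(
            "neuhauser_fargione_eq9", p, 1)
        assert C.coexistence_character("neuhauser_fargione_eq9", p,
                                       att) == "parasitic"

    def test_axis_attractor_rejected(self, weak_facultative_linear):
        eqs = find_equilibria("case_1_1_1", weak_facultative_linear, box=(0, 10))
        axis = next(e for e in eqs if e.position_class == "axis_1")
        with pytest.raises(ValueError):
            C.coexistence_character("case_1_1_1", weak_facultative_linear, axis)


class TestCriticalBenefitStrength:
    def test_linear_boundary_matches_closed_form(self):
        """Symmetric facultative pair: feasibility flips where the product
        of benefits equals the product of self-limitations (beta^2 = 1)."""
        base = M.make_params("case_1_1_1", beta12=1.0, beta21=1.0)
        # sweep beta12 holding beta21 = 1: boundary at beta12 = 1
        val = C.critical_benefit_strength("case_1_1_1", base, "beta12",
                                          (0.1, 3.0))
        assert val == pytest.approx(1.0, rel=1e-3)

    def test_obligate_needs_benefit_above_mortality(self):
        base = M.make_params("case_1_2", r1=-0.5)
        val = C.critical_benefit_strength("case_1_2", base, "beta12",
                                          (0.4, 3.0))
        # the saturating benefit must exceed |r1| at saturation
        assert val > 0.5

    def test_bracketing_error(self):
        base = M.make_params("case_1_2", r1=-0.5)
        with pytest.raises(ValueError):
            C.critical_benefit_strength("case_1_2", base, "beta12", (0.1, 0.2))


class TestSweep:
    def test_obligacy_continuum_passes_to_coexistence(self):
        base = M.make_params("case_1_1_1", beta12=0.5, beta21=0.5)
        res = C.sweep("case_1_1_1", base, "r1", [-1.0, -0.5, 0.2, 1.0],
                      settings=C.ClassifySettings(basin_grid_n=21))
        labels = [r.outcome_label for r in res.reports]
        assert labels[0] in ("E", "SC/E threshold")
        assert labels[-1] == "SC"
        assert res.change_brackets  # at least one transition detected

    def test_facultative_saturating_sweep_always_sc(self):
        base = M.make_params("case_1_2")
        res = C.sweep("case_1_2", base, "beta12", [0.3, 1.0, 3.0, 6.0],
                      settings=C.ClassifySettings(basin_grid_n=21))
        assert all(r.outcome_label == "SC" for r in res.reports)

    def test_empty_sweep(self):
        base = M.make_params("case_1_2")
        res = C.sweep("case_1_2", base, "beta12", [])
        assert res.reports == () and res.change_brackets == ()


class TestFixtureRegistry:
    def test_canonical_params_round_trip(self):
        p = FX.canonical_params("case_1_1_1", "SC")
        assert p.provenance == "fixture"
        assert p["beta12"] == 0.5

    def test_unknown_regime_lists_covered(self):
        with pytest.raises(KeyError) as exc:
            FX.canonical_params("case_1_1_1", "no_such_regime")
        assert "SC" in str(exc.value)

    def test_registry_covers_canonical_examples(self):
        for key in [("case_1_1_1", "SC"), ("case_1_1_1", "UC/E threshold"),
                    ("holland_deangelis_eq13_bidir", "five_interior_equilibria")]:
            assert key in FX.FIXTURES
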