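import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grdimer.binding import fit_hill, fit_one_site
from grdimer.equilibrium import (
    DnaAffinityParams,
    EquilibriumParams,
    SpeciesState,
    calibrate_presets,
    dimer_fraction,
    predicted_dose_response,
    promoter_occupancy,
    solve_equilibrium,
    specific_binding_curve,
)
from grdimer.presets import CALIBRATED_WT_PARAMS

kd_strategy = st.floats(1e-3, 1e6)


@settings(derandomize=True, max_examples=200)
@given(kd_strategy, kd_strategy, kd_strategy, kd_strategy)
def test_detailed_balance_always_holds(kdA, kdC, kdD1, kdD2):
    """The two routes around the thermodynamic cycle have equal net Kd."""
    p = EquilibriumParams(kdA, kdC, kdD1, kdD2)
    assert p.kdA**2 * p.kdB / (p.kdC * p.kdD1 * p.kdD2) == pytest.approx(
        1.0, rel=1e-9
    )


def test_kdB_is_derived_not_settable():
    p = EquilibriumParams(10.0, 100.0, 20.0, 5.0)
    with pytest.raises(Exception):
        p.kdB = 1.0  # frozen dataclass


def _bisect_mass_balance(p: EquilibriumParams, r: float, l: float) -> float:
    """Independent oracle: bisection on the monomer mass-balance residual."""
    b = 1.0 + l / p.kdA
    a = (2.0 / p.kdC) * (1.0 + l / p.kdD1 + l * l / (p.kdD1 * p.kdD2))

    def residual(m):
        return m * b + a * m * m - r

    lo, hi = 0.0, r
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestSolveEquilibrium:
    def test_dimerization_off_limit(self):
        p = EquilibriumParams(10.0, 1e12, 20.0, 5.0)
        s = solve_equilibrium(p, 100.0, 0.0)
        assert s.m == pytest.approx(100.0, rel=1e-9)
        assert s.d == pytest.approx(0.0, abs=1e-6)

    def test_quadratic_worked_example(self):
        # m + 2 m^2/100 = 300 has positive root m = 100 -> d = 100,
        # dimer mole fraction 2/3
        p = EquilibriumParams(10.0, 100.0, 20.0, 5.0)
        s = solve_equilibrium(p, 300.0, 0.0)
        assert s.m == pytest.approx(100.0, rel=1e-10)
        assert s.d == pytest.approx(100.0, rel=1e-10)
        assert dimer_fraction(p, 300.0, 0.0) == pytest.approx(2.0 / 3.0, rel=1e-10)

    def test_no_ligand_no_liganded_species(self):
        p = EquilibriumParams(3.0, 7.0, 11.0, 0.3)
        s = solve_equilibrium(p, 50.0, 0.0)
        assert s.ml == 0.0 and s.dl == 0.0 and s.dl2 == 0.0

    def test_zero_receptor_returns_zero_state(self):
        p = EquilibriumParams(3.0, 7.0, 11.0, 0.3)
        s = solve_equilibrium(p, 0.0, 5.0)
        assert s.m == s.ml == s.d == s.dl == s.dl2 == 0.0

    def test_negative_inputs_rejected(self):
        p = EquilibriumParams(3.0, 7.0, 11.0, 0.3)
        with pytest.raises(ValueError):
            solve_equilibrium(p, -1.0, 0.0)
        with pytest.raises(ValueError):
            solve_equilibrium(p, 1.0, -2.0)

    def test_closed_form_matches_bisection_oracle(self):
        """Stable quadratic root vs bisection over a random parameter grid."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = EquilibriumParams(*(10.0 ** rng.uniform(-2, 4, size=4)))
            r = 10.0 ** rng.uniform(-2, 3)
            l = 10.0 ** rng.uniform(-3, 4)
            s = solve_equilibrium(p, r, l)
            m_oracle = _bisect_mass_balance(p, r, l)
            assert s.m == pytest.approx(m_oracle, rel=1e-8, abs=1e-30)
            assert s.mass_balance_residual() < 1e-10

    def test_pairwise_equilibrium_relations(self):
        p = EquilibriumParams(3.0, 7.0, 11.0, 0.3)
        s = solve_equilibrium(p, 40.0, 2.5)
        assert s.m**2 / s.d == pytest.approx(p.kdC, rel=1e-8)
        assert s.m * s.l_free / s.ml == pytest.approx(p.kdA, rel=1e-8)
        assert s.d * s.l_free / s.dl == pytest.approx(p.kdD1, rel=1e-8)
        assert s.dl * s.l_free / s.dl2 == pytest.approx(p.kdD2, rel=1e-8)
        assert s.ml**2 / s.dl2 == pytest.approx(p.kdB, rel=1e-8)


class TestBindingCurve:
    def test_zero_ligand_zero_bound(self):
        p = EquilibriumParams(3.0, 7.0, 11.0, 0.3)
        curve = specific_binding_curve(p, 50.0, [0.0, 1.0, 10.0])
        assert curve[0, 1] == 0.0

    def test_single_site_limit_is_hyperbola(self):
        # with dimerization off, bound = r*l/(kdA+l); midpoint at l = kdA
        p = EquilibriumParams(16.8, 1e14, 20.0, 5.0)
        curve = specific_binding_curve(p, 100.0, [16.8])
        assert curve[0, 1] == pytest.approx(50.0, rel=1e-6)

    def test_monotone_and_saturating(self):
        p = CALIBRATED_WT_PARAMS
        l = np.geomspace(1e-3, 1e6, 50)
        curve = specific_binding_curve(p, 92.27, l)
        assert np.all(np.diff(curve[:, 1]) >= -1e-9)
        assert np.all(curve[:, 1] <= 92.27 * (1 + 1e-9))
        assert curve[-1, 1] == pytest.approx(92.27, rel=1e-3)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            specific_binding_curve(CALIBRATED_WT_PARAMS, 10.0, [])

    def test_cooperative_curve_has_hill_above_one(self):
        p = EquilibriumParams(100.0, 30.0, 80.0, 0.8)  # kdD2/kdD1 << 1/4
        l = np.geomspace(0.01, 1e4, 50)
        curve = specific_binding_curve(p, 500.0, l)
        hill = fit_hill(np.log10(curve[:, 0]), curve[:, 1])
        assert hill.hill_slope > 1.1


class TestDimerFraction:
    def test_zero_receptor(self):
        assert dimer_fraction(CALIBRATED_WT_PARAMS, 0.0, 0.0) == 0.0

    def test_dilution_limit(self):
        assert dimer_fraction(CALIBRATED_WT_PARAMS, 1e-9, 0.0) < 1e-6

    def test_strictly_increasing_in_receptor_pool(self):
        rs = np.geomspace(0.1, 1000.0, 20)
        fr = [dimer_fraction(CALIBRATED_WT_PARAMS, r, 0.0) for r in rs]
        assert np.all(np.diff(fr) > 0)

    def test_ligand_induced_dimerization(self):
        # kdB < kdC: saturating ligand pulls the pool toward dimers
        p = CALIBRATED_WT_PARAMS
        assert p.kdB < p.kdC
        assert dimer_fraction(p, 20.0, 1e5) > dimer_fraction(p, 20.0, 0.0)


class TestPromoterOccupancy:
    def test_all_zero_species(self):
        s = SpeciesState(0, 0, 0, 0, 0, 0, 0)
        occ, act = promoter_occupancy(CALIBRATED_WT_PARAMS, DnaAffinityParams(), s)
        assert all(v == 0 for v in occ.values()) and act == 0.0

    def test_half_saturation_of_unliganded_dimer(self):
        dna = DnaAffinityParams()
        s = SpeciesState(0, 0, dna.kd_dna_dimer_unliganded, 0, 0, 0,
                         2 * dna.kd_dna_dimer_unliganded)
        occ, _ = promoter_occupancy(CALIBRATED_WT_PARAMS, dna, s)
        assert occ["dimer_unliganded"] == pytest.approx(0.5)

    def test_liganded_dimer_wins_at_equal_concentrations(self):
        s = SpeciesState(1.0, 1.0, 1.0, 1.0, 0.0, 1.0, 7.0)
        occ, _ = promoter_occupancy(CALIBRATED_WT_PARAMS, DnaAffinityParams(), s)
        assert occ["dimer_liganded"] >= max(
            occ["monomer"], occ["monomer_liganded"], occ["dimer_unliganded"]
        )

    def test_occupancies_sum_below_one(self):
        s = SpeciesState(10, 10, 10, 10, 10, 5, 70)
        occ, _ = promoter_occupancy(CALIBRATED_WT_PARAMS, DnaAffinityParams(), s)
        assert 0 < sum(occ.values()) <= 1.0

    def test_affinity_hierarchy_of_defaults(self):
        dna = DnaAffinityParams()
        assert (dna.kd_dna_dimer_liganded < dna.kd_dna_dimer_unliganded
                <= dna.kd_dna_monomer_liganded < dna.kd_dna_monomer)


class TestPredictedDoseResponse:
    def test_basal_priming_grows_with_receptor_pool(self):
        dna = DnaAffinityParams()
        lo = predicted_dose_response(CALIBRATED_WT_PARAMS, dna, 21.78, [0.0])
        hi = predicted_dose_response(CALIBRATED_WT_PARAMS, dna, 92.27, [0.0])
        assert 0 < lo[0, 1] < hi[0, 1]

    def test_activity_nondecreasing_in_ligand(self):
        dna = DnaAffinityParams()
        l = np.concatenate([[0.0], np.geomspace(1e-3, 1e4, 30)])
        act = predicted_dose_response(CALIBRATED_WT_PARAMS, dna, 92.27, l)[:, 1]
        assert np.all(np.diff(act) >= -1e-12)

    def test_potency_increases_with_receptor_pool(self):
        # half-maximal ligand concentration of the activity curve drops as
        # the receptor pool (hence preformed-dimer priming) rises
        dna = DnaAffinityParams()
        l = np.geomspace(1e-4, 1e5, 200)

        def half_point(r):
            act = predicted_dose_response(CALIBRATED_WT_PARAMS, dna, r, l)[:, 1]
            target = act[0] + 0.5 * (act[-1] - act[0])
            return l[np.searchsorted(act, target)]

        assert half_point(92.27) < half_point(21.78)


class TestCalibration:
    def test_self_consistency_on_model_generated_targets(self):
        from grdimer.equilibrium import _default_r_totals, _observables

        true = EquilibriumParams(120.0, 40.0, 80.0, 1.0)
        r_totals = _default_r_totals()
        targets = _observables(true, r_totals)
        res = calibrate_presets(targets=targets, r_totals=r_totals,
                                x0=(100.0, 30.0, 60.0, 2.0))
        # the nested Hill/one-site fits inside the objective put a numerical
        # floor around 1e-5 on the achievable residual
        assert res.max_abs_log_residual < 1e-4
        assert res.feasible

    def test_default_calibration_reproduces_frozen_presets(self):
        res = calibrate_presets()
        frozen = CALIBRATED_WT_PARAMS
        for name in ("kdA", "kdC", "kdD1", "kdD2"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(frozen, name), rel=1e-4
            )
        assert res.achieved["apparent_kd_high"] == pytest.approx(16.8, rel=0.01)
        assert 1.5 <= res.achieved["hill_slope_high"] <= 2.0
        assert res.feasible

    def test_impaired_dimerization_flattens_hill_slope(self):
        # at the two expression levels the mutant was studied at, its
        # binding curve loses the cooperativity the wild type shows
        from grdimer.presets import GRDIM_IMPAIRMENT

        p = CALIBRATED_WT_PARAMS.with_impaired_dimerization(GRDIM_IMPAIRMENT)
        l = np.geomspace(0.5, 150.0, 20)
        for r in (21.78, 49.6):
            curve = specific_binding_curve(p, r, l)
            hill = fit_hill(np.log10(curve[:, 0]), curve[:, 1])
            wt_curve = specific_binding_curve(CALIBRATED_WT_PARAMS, r, l)
            wt_hill = fit_hill(np.log10(wt_curve[:, 0]), wt_curve[:, 1])
            assert hill.hill_slope == pytest.approx(1.0, abs=0.15)
            assert hill.hill_slope < wt_hill.hill_slope


def test_hill_slope_nondecreasing_in_receptor_pool():
    """Cooperativity emerges monotonically as the pool grows."""
    p = CALIBRATED_WT_PARAMS
    l = np.geomspace(0.05, 2000.0, 40)
    slopes = []
    for r in np.geomspace(0.5, 500.0, 8):
        curve = specific_binding_curve(p, r, l)
        slopes.append(fit_hill(np.log10(curve[:, 0]), curve[:, 1]).hill_slope)
    assert np.all(np.diff(slopes) > -0.01)


def test_dilution_limit_recovers_monomer_affinity():
    """As r -> 0 the curve becomes the monomer hyperbola: Hill 1, Kd = kdA."""
    p = CALIBRATED_WT_PARAMS
    l = np.geomspace(0.05, 20000.0, 40)
    # r must be small enough that even the doubly liganded dimer (favored
    # at the top of the grid) is negligible: its share scales as m*l
    curve = specific_binding_curve(p, 1e-8, l)
    one = fit_one_site(curve[:, 0], curve[:, 1])
    hill = fit_hill(np.log10(curve[:, 0]), curve[:, 1])
    assert one.kd == pytest.approx(p.kdA, rel=0.01)
    assert hill.hill_slope == pytest.approx(1.0, abs=0.02)


def test_delta_g_reporting():
    p = EquilibriumParams(10.0, 100.0, 20.0, 5.0)
    dg = p.delta_g()
    # detailed balance in free-energy form: 2*dG_A + dG_B = dG_C + dG_D1 + dG_D2
    assert 2 * dg["kdA"] + dg["kdB"] == pytest.approx(
        dg["kdC"] + dg["kdD1"] + dg["kdD2"], rel=1e-9
    )
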