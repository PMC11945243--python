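"""DDI mechanisms: inhibition arithmetic, enzyme turnover, paired runs."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from bevpbpk.ddi import (
    ConstantExposure,
    EnzymeState,
    OneCompartmentExposure,
    PerpetratorAction,
    TabulatedExposure,
    apparent_clint,
    enzyme_turnover_rhs,
    induction_rsyn,
    simulate_ddi,
)
from bevpbpk.pbpk_core import DosingRegimen, degenerate_one_compartment
from bevpbpk.pkmetrics import nca


class TestInhibitionArithmetic:
    @pytest.mark.parametrize(
        "i_over_ki,factor",
        [(0.0, 1.0), (1.0, 0.5), (9.0, 0.1)],
    )
    def test_apparent_clint_follows_competitive_form(self, i_over_ki, factor):
        assert apparent_clint(100.0, i_over_ki * 2.0, 2.0) == pytest.approx(100.0 * factor)

    def test_strictly_decreasing_in_inhibitor(self):
        values = [apparent_clint(50.0, i, 1.0) for i in (0.0, 0.5, 1.0, 5.0, 50.0)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invalid_ki_rejected(self):
        with pytest.raises(ValueError):
            apparent_clint(10.0, 1.0, 0.0)


class TestInductionArithmetic:
    def test_baseline_and_half_maximal_and_saturation(self):
        assert induction_rsyn(2.0, 0.0, 9.0, 0.5) == 2.0
        assert induction_rsyn(2.0, 0.5, 9.0, 0.5) == pytest.approx(2.0 * (1 + 4.5))
        sat = induction_rsyn(2.0, 1e6 * 0.5, 9.0, 0.5)
        assert sat == pytest.approx(2.0 * 10.0, rel=1e-4)

    def test_invalid_ec50_rejected(self):
        with pytest.raises(ValueError):
            induction_rsyn(1.0, 1.0, 5.0, 0.0)


class TestEnzymeTurnover:
    def test_steady_state_has_zero_derivative(self):
        st = EnzymeState(e=1.0)
        assert enzyme_turnover_rhs(st, st.k_deg * st.e) == pytest.approx(0.0)

    def test_constant_inducer_reaches_closed_form_fold(self):
        """After 10 turnover half-lives E/E0 is the steady-state fold."""
        st = EnzymeState()
        emax, ec50, i = 9.0, 0.5, 2.0
        rsyn_app = induction_rsyn(st.r_syn, i, emax, ec50)
        t_end = 10.0 * 36.0
        sol = solve_ivp(
            lambda t, y: [rsyn_app - st.k_deg * y[0]],
            (0.0, t_end),
            [1.0],
            rtol=1e-10,
            atol=1e-12,
        )
        expected = 1.0 + emax * i / (ec50 + i)
        assert sol.y[0, -1] == pytest.approx(expected, rel=2e-3)

    def test_washout_returns_to_baseline_with_degradation_halflife(self):
        st = EnzymeState()
        e0, e_induced = 1.0, 5.0
        sol = solve_ivp(
            lambda t, y: [st.k_deg * e0 - st.k_deg * y[0]],
            (0.0, 36.0),
            [e_induced],
            rtol=1e-10,
            atol=1e-12,
        )
        # one degradation half-life closes half the gap to baseline
        assert sol.y[0, -1] == pytest.approx(e0 + (e_induced - e0) / 2.0, rel=1e-6)


class TestExposureProviders:
    def test_constant(self):
        assert ConstantExposure(3.0)(17.0) == 3.0

    def test_one_compartment_zero_before_first_dose_and_peaks_after(self):
        exp = OneCompartmentExposure(
            dose_umol=100.0, ka=1.0, cl=5.0, v=50.0, tau_h=24.0, n_doses=4, start_h=-72.0
        )
        assert exp(-73.0) == 0.0
        assert exp(-69.0) > 0.0

    def test_tabulated_interpolates_and_validates(self):
        tab = TabulatedExposure(times=(0.0, 2.0, 4.0), concs=(0.0, 2.0, 1.0))
        assert tab(1.0) == pytest.approx(1.0)
        assert tab(10.0) == 1.0  # held at last value
        with pytest.raises(ValueError):
            TabulatedExposure(times=(0.0, 0.0), concs=(1.0, 1.0))

    def test_mechanism_parameter_validation(self):
        with pytest.raises(ValueError):
            PerpetratorAction(mechanism="competitive_inhibition", exposure=ConstantExposure(1.0))
        with pytest.raises(ValueError):
            PerpetratorAction(mechanism="induction", exposure=ConstantExposure(1.0), emax=2.0)


@pytest.fixture(scope="module")
def victim():
    cl, fm = 4.0, 0.95
    ind, cp = degenerate_one_compartment(
        40.0, clearance_l_h=cl * fm, renal_clearance_l_h=cl * (1 - fm)
    )
    return ind, cp


class TestPairedSimulation:
    def test_infinite_ki_leaves_victim_unchanged(self, victim):
        ind, cp = victim
        perp = PerpetratorAction(
            mechanism="competitive_inhibition", exposure=ConstantExposure(1.0), ki=1e12
        )
        c, t = simulate_ddi(ind, cp, [DosingRegimen(route="iv_bolus", dose=50.0)], perp, 120.0)
        assert np.allclose(c.plasma_conc, t.plasma_conc, rtol=1e-9)

    def test_strong_constant_inhibitor_matches_fm_closed_form(self, victim):
        """AUC ratio -> 1/(1 - fm + fm/(1 + I/Ki)) for fm = 0.95, I = 100 Ki."""
        ind, cp = victim
        perp = PerpetratorAction(
            mechanism="competitive_inhibition", exposure=ConstantExposure(100.0), ki=1.0
        )
        c, t = simulate_ddi(ind, cp, [DosingRegimen(route="iv_bolus", dose=50.0)], perp, 1200.0)
        ratio = nca(t.time, t.plasma_conc).auc_inf / nca(c.time, c.plasma_conc).auc_inf
        fm = 0.95
        expected = 1.0 / (1.0 - fm + fm / (1.0 + 100.0))
        assert ratio == pytest.approx(expected, rel=0.01)
        assert ratio > 1.0

    def test_zero_emax_induction_is_identity(self, victim):
        ind, cp = victim
        perp = PerpetratorAction(
            mechanism="induction", exposure=ConstantExposure(5.0), emax=0.0, ec50=1.0
        )
        c, t = simulate_ddi(ind, cp, [DosingRegimen(route="iv_bolus", dose=50.0)], perp, 120.0)
        assert np.allclose(c.plasma_conc, t.plasma_conc, rtol=1e-9)

    def test_inducer_lowers_auc_inhibitor_raises_it(self, victim):
        ind, cp = victim
        reg = [DosingRegimen(route="iv_bolus", dose=50.0)]
        inducer = PerpetratorAction(
            mechanism="induction", exposure=ConstantExposure(5.0), emax=9.0, ec50=1.0
        )
        c, t = simulate_ddi(ind, cp, reg, inducer, 240.0)
        assert t.auc() < c.auc()
        inhibitor = PerpetratorAction(
            mechanism="competitive_inhibition", exposure=ConstantExposure(5.0), ki=1.0
        )
        c2, t2 = simulate_ddi(ind, cp, reg, inhibitor, 240.0)
        assert t2.auc() > c2.auc()
        assert t2.mass_balance_error() < 1e-3 and c2.mass_balance_error() < 1e-3
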