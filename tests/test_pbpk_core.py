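"""Whole-body ODE engine: analytic limits, linearity, mass balance."""

import dataclasses

import numpy as np
import pytest

from bevpbpk.pbpk_core import (
    DosingRegimen,
    bioavailability,
    build_model,
    degenerate_one_compartment,
    simulate,
)


class TestDosingRegimen:
    def test_tablet_requires_formulation(self):
        with pytest.raises(ValueError):
            DosingRegimen(route="oral_tablet", dose=50.0)

    def test_unknown_route_rejected(self):
        with pytest.raises(ValueError):
            DosingRegimen(route="intrathecal", dose=1.0)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            DosingRegimen(route="iv_bolus", dose=0.0)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            DosingRegimen(route="iv_bolus", dose=1.0, times=(24.0, 0.0))


class TestAnalyticLimits:
    def test_one_compartment_iv_bolus_matches_closed_form(self):
        v, cl, dose = 40.0, 4.0, 100.0
        ind, cp = degenerate_one_compartment(v, cl)
        res = simulate(build_model(ind, cp, DosingRegimen(route="iv_bolus", dose=dose)), 48.0)
        analytic = cp.mg_to_umol(dose) / v * np.exp(-cl / v * res.time) * 1000.0
        mask = res.time > 0
        rel = np.abs(res.plasma_conc[mask] - analytic[mask]) / analytic[mask]
        assert np.max(rel) < 0.005

    def test_no_elimination_conserves_drug_indefinitely(self):
        ind, cp = degenerate_one_compartment(40.0, clearance_l_h=0.0)
        cp = dataclasses.replace(cp, clint_hepatic=0.0)
        res = simulate(build_model(ind, cp, DosingRegimen(route="iv_bolus", dose=10.0)), 200.0)
        total = res.compartments.to_numpy().sum(axis=1)
        assert np.max(np.abs(total - cp.mg_to_umol(10.0))) / cp.mg_to_umol(10.0) < 1e-9

    def test_superposition_of_repeated_doses(self):
        ind, cp = degenerate_one_compartment(40.0, 4.0)
        grid = np.linspace(0, 96, 961)
        reg2 = DosingRegimen(route="iv_bolus", dose=50.0, times=(0.0, 24.0))
        reg1 = DosingRegimen(route="iv_bolus", dose=50.0)
        r2 = simulate(build_model(ind, cp, reg2), 96.0, t_eval=grid)
        r1 = simulate(build_model(ind, cp, reg1), 96.0, t_eval=grid)
        shifted = np.interp(np.clip(r2.time - 24.0, 0, None), r1.time, r1.plasma_conc)
        expected = np.interp(r2.time, r1.time, r1.plasma_conc) + shifted * (r2.time >= 24.0)
        mask = r2.time > 0.1
        assert np.max(np.abs(r2.plasma_conc[mask] - expected[mask]) / expected[mask]) < 0.005

    def test_infusion_reaches_rate_over_clearance_plateau(self):
        v, cl = 20.0, 5.0
        ind, cp = degenerate_one_compartment(v, cl)
        reg = DosingRegimen(route="iv_infusion", dose=100.0, infusion_duration=200.0)
        res = simulate(build_model(ind, cp, reg), 200.0)
        rate = cp.mg_to_umol(100.0) / 200.0  # µmol/h
        css = rate / cl * 1000.0  # nmol/L
        assert res.plasma_conc[-1] == pytest.approx(css, rel=0.01)


class TestLinearity:
    def test_iv_auc_proportional_to_dose(self):
        ind, cp = degenerate_one_compartment(40.0, 4.0)
        aucs = []
        for dose in (10.0, 100.0):
            res = simulate(build_model(ind, cp, DosingRegimen(route="iv_bolus", dose=dose)), 300.0)
            aucs.append(res.auc() / dose)
        assert aucs[0] == pytest.approx(aucs[1], rel=1e-6)

    def test_terminal_slope_dose_independent(self, ind_fasted, cp):
        slopes = []
        for dose in (5.0, 50.0):
            res = simulate(
                build_model(ind_fasted, cp, DosingRegimen(route="iv_bolus", dose=dose)), 168.0
            )
            mask = res.time >= 96
            slopes.append(np.polyfit(res.time[mask], np.log(res.plasma_conc[mask]), 1)[0])
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-4)


class TestMassBalance:
    def test_iv_ledger_closes(self, sim_iv):
        assert sim_iv.mass_balance_error() < 1e-3

    def test_solution_ledger_closes(self, sim_solution):
        assert sim_solution.mass_balance_error() < 1e-3

    def test_tablet_ledger_closes(self, sim_tab400_override):
        assert sim_tab400_override.mass_balance_error() < 1e-3

    def test_renal_clearance_constant(self, ind_fasted, cp):
        """GFR fraction x GFR x fu: 0.059 x 120 x 0.154 = 1.090 mL/min."""
        m = build_model(ind_fasted, cp, DosingRegimen(route="iv_bolus", dose=1.0))
        assert m.renal_cl * 1000.0 / 60.0 == pytest.approx(1.090, abs=0.001)


class TestConvergenceAndEvents:
    def test_tolerance_refinement_leaves_auc_unchanged(self, ind_fasted, cp):
        reg = DosingRegimen(route="oral_solution", dose=25.0)
        a = simulate(build_model(ind_fasted, cp, reg), 72.0, rtol=1e-6, atol=1e-8).auc()
        b = simulate(build_model(ind_fasted, cp, reg), 72.0, rtol=1e-8, atol=1e-10).auc()
        assert a == pytest.approx(b, rel=1e-4)

    def test_simulation_deterministic(self, ind_fasted, cp):
        reg = DosingRegimen(route="oral_solution", dose=25.0)
        a = simulate(build_model(ind_fasted, cp, reg), 24.0)
        b = simulate(build_model(ind_fasted, cp, reg), 24.0)
        assert np.array_equal(a.plasma_conc, b.plasma_conc)

    def test_invalid_t_end_rejected(self, ind_fasted, cp):
        m = build_model(ind_fasted, cp, DosingRegimen(route="iv_bolus", dose=1.0))
        with pytest.raises(ValueError):
            simulate(m, -1.0)


class TestBioavailability:
    def test_identical_profiles_give_unity(self, sim_iv):
        assert bioavailability(sim_iv, sim_iv, 35.26, 35.26) == pytest.approx(1.0)

    def test_solution_bioavailability_in_unit_interval(self, sim_solution, sim_iv):
        f = bioavailability(sim_solution, sim_iv, 25.0, 35.26)
        assert 0.0 < f <= 1.0 + 1e-6

    def test_zero_iv_auc_rejected(self, sim_iv):
        empty = dataclasses.replace(sim_iv, plasma_conc=np.zeros_like(sim_iv.plasma_conc))
        with pytest.raises(ValueError):
            bioavailability(sim_iv, empty, 1.0, 1.0)


def test_simultaneous_oral_and_iv_microtracer_regimen(ind_fasted, cp, formulations):
    """The microtracer design: IV dose shortly after an oral dose."""
    form = formulations.get("1407-0001", 50, "fasted")
    regs = [
        DosingRegimen(route="oral_tablet", dose=50.0, formulation=form),
        DosingRegimen(route="iv_bolus", dose=0.1, times=(0.25,)),
    ]
    res = simulate(build_model(ind_fasted, cp, regs), 24.0)
    assert res.mass_balance_error() < 1e-3
    # the IV spike is visible right after 0.25 h
    i = np.searchsorted(res.time, 0.25)
    assert res.plasma_conc[i] > res.plasma_conc[max(i - 2, 0)]
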