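"""Weibull dissolution, luminal transit, and absorption flux."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from bevpbpk.absorption import (
    FormulationTable,
    LumenState,
    WeibullFormulation,
    absorption_flux,
    transit_step,
    weibull_fraction,
    weibull_hazard,
)


class TestWeibullFraction:
    def test_half_dissolved_exactly_at_t50_for_every_tabulated_shape(self, formulations):
        """The 50%-dissolution time is an exact anchor, whatever the shape."""
        for e in formulations.entries():
            f = WeibullFormulation(shape=e["shape"], t50=e["t50_min"])
            assert weibull_fraction(f, f.t50) == 0.5

    def test_zero_at_time_zero_and_during_lag(self):
        f = WeibullFormulation(shape=0.78, t50=328.0)
        assert weibull_fraction(f, 0.0) == 0.0
        f_lag = WeibullFormulation(shape=0.78, t50=328.0, lag=30.0)
        assert weibull_fraction(f_lag, 29.9) == 0.0
        assert weibull_fraction(f_lag, 30.0 + 328.0) == 0.5

    def test_closed_form_for_unit_shape(self):
        f = WeibullFormulation(shape=1.0, t50=100.0)
        assert weibull_fraction(f, 200.0) == pytest.approx(0.75)

    @settings(deadline=None, max_examples=50)
    @given(
        shape=st.floats(0.05, 5.0),
        t50=st.floats(1.0, 10000.0),
        t=st.floats(0.0, 50000.0),
    )
    def test_fraction_stays_in_unit_interval_and_grows(self, shape, t50, t):
        f = WeibullFormulation(shape=shape, t50=t50)
        v = weibull_fraction(f, t)
        assert 0.0 <= v <= 1.0
        assert weibull_fraction(f, t + 1.0) >= v

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            WeibullFormulation(shape=0.0, t50=100.0)
        with pytest.raises(ValueError):
            WeibullFormulation(shape=1.0, t50=-5.0)


class TestDissolutionHazard:
    @pytest.mark.parametrize("shape,t50", [(0.78, 328.0), (0.16, 5000.0), (1.4, 60.0)])
    def test_quantum_plus_hazard_reproduces_schedule(self, shape, t50):
        """Activation quantum + dS/dt = -h(t) S integrates to S = 1 - F(t)."""
        from bevpbpk.absorption import weibull_activation_quantum

        f = WeibullFormulation(shape=shape, t50=t50)
        s0 = 1.0 - weibull_activation_quantum(f)
        sol = solve_ivp(
            lambda t, y: [-weibull_hazard(f, t) * y[0]],
            (0.0, 2.0 * t50),
            [s0],
            rtol=1e-10,
            atol=1e-13,
            t_eval=np.linspace(0.0, 2.0 * t50, 50),
            method="LSODA",
        )
        expected = 1.0 - weibull_fraction(f, sol.t)
        assert np.max(np.abs(sol.y[0, 1:] - expected[1:])) < 1e-6

    def test_hazard_zero_before_lag(self):
        f = WeibullFormulation(shape=0.78, t50=328.0, lag=15.0)
        assert weibull_hazard(f, 10.0) == 0.0
        assert weibull_hazard(f, 20.0) > 0.0


class TestTransit:
    def test_single_loaded_segment_conserves_mass_with_fecal_loss(self, ind_fasted):
        lumen = LumenState.empty(ind_fasted)
        lumen.solid[0] = 100.0

        k = np.array([1.0 / s.transit_time_h("fasted") for s in ind_fasted.gi_tract])

        def rhs(t, y):
            st_ = LumenState(solid=y[:12], dissolved=y[12:24], fluid_volume=lumen.fluid_volume)
            ds, dd, fecal = transit_step(st_, ind_fasted)
            return np.concatenate([ds, dd, [fecal]])

        y0 = np.concatenate([lumen.solid, lumen.dissolved, [0.0]])
        sol = solve_ivp(rhs, (0, 96.0), y0, rtol=1e-10, atol=1e-12)
        total = sol.y[:24, -1].sum() + sol.y[24, -1]
        assert total == pytest.approx(100.0, rel=1e-8)
        assert sol.y[24, -1] > 1.0  # some material reached fecal loss

    def test_erlang_chain_peak_times(self):
        """Equal transit times: segment k peaks at (k-1) tau (Erlang mode)."""
        tau, n = 2.0, 5
        k = 1.0 / tau

        def rhs(t, y):
            dy = -k * y
            dy[1:] += k * y[:-1]
            return dy

        y0 = np.zeros(n)
        y0[0] = 1.0
        t_eval = np.linspace(0, 30, 3001)
        sol = solve_ivp(rhs, (0, 30), y0, t_eval=t_eval, rtol=1e-10, atol=1e-12)
        for seg in range(1, n):
            t_peak = t_eval[np.argmax(sol.y[seg])]
            assert t_peak == pytest.approx(seg * tau, abs=0.02)


class TestAbsorptionFlux:
    def test_no_dissolved_drug_no_flux(self, ind_fasted, cp):
        lumen = LumenState.empty(ind_fasted)
        seg = ind_fasted.gi_tract[2]
        assert absorption_flux(lumen, seg, 2, cp) == 0.0

    def test_sink_mode_is_permeability_times_area_times_concentration(self, ind_fasted, cp):
        lumen = LumenState.empty(ind_fasted)
        lumen.dissolved[2] = 12.0  # µmol in upper jejunum
        seg = ind_fasted.gi_tract[2]
        conc = 12.0 / seg.fluid_volume
        expected = cp.intestinal_permeability * seg.effective_area * conc * 60.0 / 1000.0
        assert absorption_flux(lumen, seg, 2, cp, sink=True) == pytest.approx(expected)

    def test_flux_linear_in_effective_area(self, ind_fasted, cp):
        import dataclasses

        lumen = LumenState.empty(ind_fasted)
        lumen.dissolved[3] = 5.0
        seg = ind_fasted.gi_tract[3]
        doubled = dataclasses.replace(seg, effective_area=2 * seg.effective_area)
        assert absorption_flux(lumen, doubled, 3, cp, sink=True) == pytest.approx(
            2.0 * absorption_flux(lumen, seg, 3, cp, sink=True)
        )

    def test_stomach_never_absorbs(self, ind_fasted, cp):
        lumen = LumenState.empty(ind_fasted)
        lumen.dissolved[0] = 50.0
        assert absorption_flux(lumen, ind_fasted.gi_tract[0], 0, cp, sink=True) == 0.0


class TestFormulationTable:
    def test_tabulated_fits_are_returned_verbatim(self, formulations):
        f = formulations.get("1407-0002", 400, "fed")
        assert (f.shape, f.t50) == (0.16, 5000.0)
        f = formulations.get("1407-0002", 50, "fed")
        assert (f.shape, f.t50) == (0.16, 9.9)
        f = formulations.get("1407-0014", 50, "fasted", tag="ddi")
        assert (f.shape, f.t50) == (0.79, 442.0)
        f = formulations.get("1407-0001", 400, "fasted")
        assert (f.shape, f.t50) == (0.58, 2570.0)

    def test_untested_dose_is_not_interpolated(self, formulations):
        with pytest.raises(KeyError):
            formulations.get("1407-0001", 300, "fasted")
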