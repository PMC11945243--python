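"""Shared fixtures: reference individual/compound and cached simulations.

The heavier whole-body simulations are session-scoped so that the mass
balance, absorption-property, and acceptance tests share one integration
each instead of re-running them.
"""

from __future__ import annotations

import numpy as np
import pytest

from bevpbpk.absorption import FormulationTable
from bevpbpk.compound import load_bi730357
from bevpbpk.pbpk_core import DosingRegimen, build_model, simulate
from bevpbpk.physiology import default_individual


@pytest.fixture(scope="session")
def ind_fasted():
    return default_individual("fasted")


@pytest.fixture(scope="session")
def ind_fed():
    return default_individual("fed")


@pytest.fixture(scope="session")
def cp():
    return load_bi730357()


@pytest.fixture(scope="session")
def formulations():
    return FormulationTable.load_default()


@pytest.fixture(scope="session")
def sim_iv(ind_fasted, cp):
    """35.26 mg IV bolus, 168 h."""
    reg = DosingRegimen(route="iv_bolus", dose=35.26)
    return simulate(build_model(ind_fasted, cp, reg), 168.0)


@pytest.fixture(scope="session")
def sim_solution(ind_fasted, cp):
    """25 mg oral solution, 168 h."""
    reg = DosingRegimen(route="oral_solution", dose=25.0)
    return simulate(build_model(ind_fasted, cp, reg), 168.0)


@pytest.fixture(scope="session")
def sim_tab400_override(ind_fasted, cp, formulations):
    """400 mg fasted tablet with the elevated colonic solubility, 48 h."""
    form = formulations.get("1407-0001", 400, "fasted")
    reg = DosingRegimen(route="oral_tablet", dose=400.0, formulation=form)
    return simulate(build_model(ind_fasted, cp, reg), 48.0)


@pytest.fixture(scope="session")
def sim_tab400_no_override(ind_fasted, cp, formulations):
    """Same run with the colonic override removed (pH-derived solubility)."""
    form = formulations.get("1407-0001", 400, "fasted")
    reg = DosingRegimen(route="oral_tablet", dose=400.0, formulation=form)
    return simulate(build_model(ind_fasted, cp.without_colon_override(), reg), 48.0)


@pytest.fixture(scope="session")
def sim_tab50_96(ind_fasted, cp, formulations):
    form = formulations.get("1407-0001", 50, "fasted")
    reg = DosingRegimen(route="oral_tablet", dose=50.0, formulation=form)
    return simulate(build_model(ind_fasted, cp, reg), 96.0)


@pytest.fixture(scope="session")
def sim_tab400_96(ind_fasted, cp, formulations):
    form = formulations.get("1407-0001", 400, "fasted")
    reg = DosingRegimen(route="oral_tablet", dose=400.0, formulation=form)
    return simulate(build_model(ind_fasted, cp, reg), 96.0)
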