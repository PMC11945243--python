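"""Victim-side CYP3A4 drug-drug interaction mechanisms.

Two mechanisms are supported, both acting on the victim's CYP3A4-mediated
intrinsic clearance:

* competitive inhibition — the apparent intrinsic clearance is
  ``CL_int / (1 + I/K_i)``, driven by the unbound perpetrator concentration
  ``I`` at the enzyme site.  Competitive inhibition raises the apparent
  Michaelis constant, so clearance falls as ``I`` rises.
* enzyme induction — the inducer raises the enzyme synthesis rate,
  ``R_syn,app = R_syn * (1 + E_max*I/(EC_50 + I))``, and the enzyme amount
  follows the turnover equation ``dE/dt = R_syn,app - k_deg*E`` toward a
  steady-state fold-induction of ``1 + E_max*I/(EC_50 + I)``.

The perpetrator itself is not modeled mechanistically: its exposure enters
through a pluggable time -> unbound-concentration profile (constant,
repeated-dose one-compartment, or tabulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

ExposureFn = Callable[[float], float]


# -- exposure providers ----------------------------------------------------


@dataclass(frozen=True)
class ConstantExposure:
    """Constant unbound perpetrator concentration, µmol/L."""

    conc: float

    def __call__(self, t_h: float) -> float:
        if self.conc < 0:
            raise ValueError("exposure must be >= 0")
        return self.conc


@dataclass(frozen=True)
class OneCompartmentExposure:
    """Repeated-dose one-compartment oral perpetrator profile.

    Unbound concentration at time t (h):
    fu * sum over doses of (D ka)/(V (ka - ke)) * (exp(-ke dt) - exp(-ka dt))
    with ke = CL/V.  Doses start at ``start_h`` and repeat every ``tau_h``.
    """

    dose_umol: float
    ka: float  # 1/h
    cl: float  # L/h
    v: float  # L
    fu: float = 1.0
    tau_h: float = 24.0
    n_doses: int = 1
    start_h: float = 0.0

    def __call__(self, t_h: float) -> float:
        ke = self.cl / self.v
        conc = 0.0
        for i in range(self.n_doses):
            dt = t_h - (self.start_h + i * self.tau_h)
            if dt <= 0:
                break
            if abs(self.ka - ke) < 1e-12:
                conc += self.dose_umol / self.v * self.ka * dt * np.exp(-self.ka * dt)
            else:
                conc += (
                    self.dose_umol
                    * self.ka
                    / (self.v * (self.ka - ke))
                    * (np.exp(-ke * dt) - np.exp(-self.ka * dt))
                )
        return self.fu * conc


@dataclass(frozen=True)
class TabulatedExposure:
    """Linearly interpolated exposure table (time h, unbound µmol/L)."""

    times: tuple
    concs: tuple

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concs, dtype=float)
        if t.ndim != 1 or t.shape != c.shape or len(t) < 1:
            raise ValueError("times and concs must be equal-length 1-D sequences")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("exposure must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "TabulatedExposure":
        df = pd.read_csv(path)
        return cls(tuple(df["time_h"]), tuple(df["conc_umol_per_l"]))

    def __call__(self, t_h: float) -> float:
        return float(np.interp(t_h, self.times, self.concs, left=0.0, right=self.concs[-1]))


# -- mechanism parameters --------------------------------------------------


@dataclass(frozen=True)
class PerpetratorAction:
    """A perpetrator mechanism plus its exposure profile.

    ``gut_exposure`` optionally replaces the systemic exposure for the
    gut-wall enzyme sites (enterocyte concentrations may differ from the
    unbound plasma concentration); by default the same profile drives both.
    """

    mechanism: Literal["competitive_inhibition", "induction"]
    exposure: ExposureFn
    ki: float | None = None  # µmol/L
    emax: float | None = None
    ec50: float | None = None  # µmol/L
    gut_exposure: ExposureFn | None = None

    def __post_init__(self) -> None:
        if self.mechanism == "competitive_inhibition":
            if self.ki is None or self.ki <= 0:
                raise ValueError("competitive inhibition requires K_i > 0")
        elif self.mechanism == "induction":
            if self.emax is None or self.emax < 0:
                raise ValueError("induction requires E_max >= 0")
            if self.ec50 is None or self.ec50 <= 0:
                raise ValueError("induction requires EC_50 > 0")
        else:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    def exposure_at(self, t_h: float, gut: bool = False) -> float:
        fn = self.gut_exposure if (gut and self.gut_exposure is not None) else self.exposure
        return max(0.0, float(fn(t_h)))


@dataclass
class EnzymeState:
    """Relative enzyme amount with first-order turnover (E0 = 1)."""

    e: float = 1.0
    k_deg: float = np.log(2.0) / 36.0  # 1/h
    e0: float = 1.0

    @property
    def r_syn(self) -> float:
        """Baseline synthesis rate: dE/dt = 0 at E = E0."""
        return self.k_deg * self.e0


# -- mechanism math --------------------------------------------------------


def apparent_clint(clint: float, i: float, ki: float) -> float:
    """Apparent intrinsic clearance under competitive inhibition.

    CL_int,app = CL_int / (1 + I/K_i); equal to CL_int at I = 0 and strictly
    decreasing in the inhibitor concentration.
    """
    if ki <= 0:
        raise ValueError("K_i must be > 0")
    if i < 0:
        raise ValueError("inhibitor concentration must be >= 0")
    return clint / (1.0 + i / ki)


def induction_rsyn(rsyn: float, i: float, emax: float, ec50: float) -> float:
    """Apparent enzyme synthesis rate under induction.

    R_syn,app = R_syn * (1 + E_max*I/(EC_50 + I)), bounded by R_syn*(1+E_max).
    """
    if ec50 <= 0:
        raise ValueError("EC_50 must be > 0")
    if i < 0:
        raise ValueError("inducer concentration must be >= 0")
    return rsyn * (1.0 + emax * i / (ec50 + i))


def enzyme_turnover_rhs(state: EnzymeState, rsyn_app: float) -> float:
    """dE/dt = R_syn,app - k_deg * E."""
    return rsyn_app - state.k_deg * state.e


def clint_modifier(action: PerpetratorAction | None, t_h: float, gut: bool = False) -> float:
    """Multiplicative modifier on CL_int from competitive inhibition (<= 1)."""
    if action is None or action.mechanism != "competitive_inhibition":
        return 1.0
    i = action.exposure_at(t_h, gut=gut)
    return 1.0 / (1.0 + i / action.ki)


def rsyn_fold(action: PerpetratorAction | None, t_h: float, gut: bool = False) -> float:
    """Fold-change of the enzyme synthesis rate from induction (>= 1)."""
    if action is None or action.mechanism != "induction":
        return 1.0
    i = action.exposure_at(t_h, gut=gut)
    return 1.0 + action.emax * i / (action.ec50 + i)


# -- paired victim simulation ----------------------------------------------


def simulate_ddi(
    ind,
    cp,
    regimens,
    perpetrator: PerpetratorAction,
    t_end: float,
    t_eval: Sequence[float] | None = None,
    **solver_opts,
):
    """Run the victim regimen with and without the perpetrator.

    Returns (control, treated) simulation results that differ only in the
    perpetrator action; both carry full mass ledgers.
    """
    from .pbpk_core import build_model, simulate

    control = simulate(build_model(ind, cp, regimens, ddi=None), t_end, t_eval=t_eval, **solver_opts)
    treated = simulate(
        build_model(ind, cp, regimens, ddi=perpetrator), t_end, t_eval=t_eval, **solver_opts
    )
    return control, treated


def perpetrator_from_dict(data: dict) -> PerpetratorAction:
    """Build a PerpetratorAction from a config mapping (YAML-friendly)."""
    exp_cfg = data["exposure"]
    kind = exp_cfg["kind"]
    if kind == "constant":
        exposure: ExposureFn = ConstantExposure(float(exp_cfg["conc_umol_per_l"]))
    elif kind == "one_compartment":
        exposure = OneCompartmentExposure(
            dose_umol=float(exp_cfg["dose_umol"]),
            ka=float(exp_cfg["ka_per_h"]),
            cl=float(exp_cfg["cl_l_h"]),
            v=float(exp_cfg["v_l"]),
            fu=float(exp_cfg.get("fu", 1.0)),
            tau_h=float(exp_cfg.get("tau_h", 24.0)),
            n_doses=int(exp_cfg.get("n_doses", 1)),
            start_h=float(exp_cfg.get("start_h", 0.0)),
        )
    elif kind == "table":
        exposure = TabulatedExposure.from_csv(exp_cfg["path"])
    else:
        raise ValueError(f"unknown exposure kind {kind!r}")
    return PerpetratorAction(
        mechanism=data["mechanism"],
        exposure=exposure,
        ki=data.get("ki_umol_per_l"),
        emax=data.get("emax"),
        ec50=data.get("ec50_umol_per_l"),
    )
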