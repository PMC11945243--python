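"""Luminal kinetics: Weibull dissolution, GI transit, and absorption flux.

The tablet is released according to an empirical Weibull schedule that is
anchored on the time to reach 50% dissolution::

    F(t) = 1 - 2**(-((t - lag)/t50)**shape)

so that F(lag + t50) = 1/2 holds exactly for every shape parameter.  The
schedule follows the dose (time since administration), not the segment the
material happens to occupy, and dissolution is capped whenever the local
dissolved concentration reaches the segment solubility — no precipitation or
re-dissolution kinetics beyond that cap.  Luminal material (solid and
dissolved) moves stomach -> rectum by first-order transit; rectal outflow is
fecal loss.  Dissolved drug crosses the mucosa with a single transcellular
permeability applied to the segment's effective area; there is no gastric
absorption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .compound import CompoundParameters, segment_solubility
from .physiology import FoodState, GISegment, PhysiologyIndividual

#: Clamp for the Weibull hazard near the lag time (min); the hazard of a
#: shape < 1 schedule is integrably singular at t = lag.
_HAZARD_T_EPS = 1e-6


@dataclass(frozen=True)
class WeibullFormulation:
    """Empirical in-vivo dissolution parameters (times in minutes)."""

    shape: float
    t50: float  # min, time to 50% dissolved
    lag: float = 0.0  # min

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.t50 <= 0:
            raise ValueError("t50 must be > 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")


def weibull_fraction(f: WeibullFormulation, t: float | np.ndarray) -> float | np.ndarray:
    """Cumulative fraction dissolved at time ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    tau = np.clip(t - f.lag, 0.0, None)
    out = 1.0 - np.exp2(-((tau / f.t50) ** f.shape))
    return float(out) if out.ndim == 0 else out


def weibull_hazard(f: WeibullFormulation, t: float) -> float:
    """Instantaneous dissolution hazard F'(t)/(1 - F(t)), 1/min.

    Zero on [lag, lag + eps] where the shape < 1 hazard is singular; the
    fraction released over that clamp window, ``weibull_activation_quantum``,
    is applied as an instantaneous bolus at dose time, which makes the
    combination (quantum + hazard on the remaining solid) reproduce the
    cumulative Weibull schedule exactly.
    """
    tau = t - f.lag
    if tau <= _HAZARD_T_EPS:
        return 0.0
    return math.log(2.0) * f.shape * tau ** (f.shape - 1.0) / f.t50**f.shape


def weibull_activation_quantum(f: WeibullFormulation) -> float:
    """Fraction dissolved over the clamped hazard window at release start."""
    return float(weibull_fraction(f, f.lag + _HAZARD_T_EPS))


@dataclass
class LumenState:
    """Per-segment luminal amounts (µmol) and fluid volumes (L)."""

    solid: np.ndarray
    dissolved: np.ndarray
    fluid_volume: np.ndarray

    @classmethod
    def empty(cls, ind: PhysiologyIndividual) -> "LumenState":
        n = len(ind.gi_tract)
        return cls(
            solid=np.zeros(n),
            dissolved=np.zeros(n),
            fluid_volume=np.array([s.fluid_volume for s in ind.gi_tract]),
        )


def saturation_concentrations(
    cp: CompoundParameters, ind: PhysiologyIndividual, food_state: FoodState | None = None
) -> np.ndarray:
    """Per-segment luminal solubility, µmol/L."""
    fs = food_state or ind.food_state
    return np.array(
        [cp.mg_to_umol(segment_solubility(cp, s, fs)) for s in ind.gi_tract]
    )


def dissolution_rate(
    f: WeibullFormulation,
    lumen: LumenState,
    seg_index: int,
    cp: CompoundParameters,
    t_min: float,
    sat_conc: np.ndarray | None = None,
    ind: PhysiologyIndividual | None = None,
) -> float:
    """Solid -> dissolved transfer in one segment, µmol/min.

    Zero when the segment holds no solid or its dissolved concentration has
    reached the segment solubility.
    """
    solid = lumen.solid[seg_index]
    if solid <= 0.0:
        return 0.0
    if sat_conc is None:
        if ind is None:
            raise ValueError("provide either sat_conc or ind")
        sat_conc = saturation_concentrations(cp, ind)
    conc = lumen.dissolved[seg_index] / lumen.fluid_volume[seg_index]
    if conc >= sat_conc[seg_index]:
        return 0.0
    return weibull_hazard(f, t_min) * solid


def transit_rates(ind: PhysiologyIndividual, food_state: FoodState | None = None) -> np.ndarray:
    """First-order segment outflow rate constants 1/transit_time, 1/h."""
    fs = food_state or ind.food_state
    return np.array([1.0 / s.transit_time_h(fs) for s in ind.gi_tract])


def transit_step(
    lumen: LumenState, ind: PhysiologyIndividual, food_state: FoodState | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Transit contributions d(amount)/dt (µmol/h) and the fecal-loss rate.

    Returns (d_solid, d_dissolved, fecal_rate); material leaving the rectum
    is fecal loss and must be booked to the mass ledger by the caller.
    """
    k = transit_rates(ind, food_state)
    out_solid = k * lumen.solid
    out_diss = k * lumen.dissolved
    d_solid = -out_solid
    d_diss = -out_diss
    d_solid[1:] += out_solid[:-1]
    d_diss[1:] += out_diss[:-1]
    return d_solid, d_diss, out_solid[-1] + out_diss[-1]


#: µmol/min per (cm/s * cm^2 * µmol/L): cm^3/s -> L/min conversion.
_FLUX_UNIT = 60.0 / 1000.0


def absorption_flux(
    lumen: LumenState,
    seg: GISegment,
    seg_index: int,
    cp: CompoundParameters,
    free_mucosal_conc: float = 0.0,
    sink: bool = False,
) -> float:
    """Transmucosal flux out of one segment, µmol/min.

    flux = P * A_eff * (C_lumen - C_free,mucosa); in sink mode the mucosal
    term is ignored.  Gastric flux is always zero.
    """
    if seg.name == "stomach":
        return 0.0
    conc = lumen.dissolved[seg_index] / lumen.fluid_volume[seg_index]
    gradient = conc if sink else conc - free_mucosal_conc
    return cp.intestinal_permeability * seg.effective_area * gradient * _FLUX_UNIT


# -- formulation lookup ----------------------------------------------------


class FormulationTable:
    """Lookup of fitted Weibull parameters keyed by (study, dose, food state).

    Parameters are dose- and study-specific fits; there is deliberately no
    interpolation to untested doses.
    """

    def __init__(self, entries: list[dict]):
        self._entries = entries

    @classmethod
    def load_default(cls) -> "FormulationTable":
        ref = resources.files("bevpbpk.data") / "formulations.yaml"
        return cls(yaml.safe_load(ref.read_text())["entries"])

    @classmethod
    def load(cls, path) -> "FormulationTable":
        with open(path) as fh:
            return cls(yaml.safe_load(fh)["entries"])

    def get(
        self,
        study: str,
        dose_mg: float,
        food_state: FoodState = "fasted",
        tag: str | None = None,
    ) -> WeibullFormulation:
        for e in self._entries:
            if (
                e["study"] == study
                and float(e["dose_mg"]) == float(dose_mg)
                and e["food_state"] == food_state
                and e.get("tag") == tag
            ):
                return WeibullFormulation(
                    shape=float(e["shape"]),
                    t50=float(e["t50_min"]),
                    lag=float(e.get("lag_min", 0.0)),
                )
        raise KeyError(
            f"no fitted formulation for study={study!r} dose={dose_mg} mg "
            f"food_state={food_state!r} tag={tag!r} (untested doses are not interpolated)"
        )

    def entries(self) -> list[dict]:
        return [dict(e) for e in self._entries]
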