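"""Virtual-individual system model.

The whole-body model consists of 15 organs or tissues connected by the
circulating blood (venous and arterial pools plus the lung in series), and a
gastrointestinal tract of 12 luminal segments, the last six of which are the
large-intestinal sub-compartments.  Feeding state switches gastric emptying,
the luminal pH table, and (downstream, in :mod:`bevpbpk.compound`) the active
biorelevant reference solubility; all systemic parameters are food-state
independent.

The shipped reference individual (``european_male_default.yaml``) is a
standard European male assembled from published human reference tables and is
the deterministic basis of every default simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal

import yaml

FoodState = Literal["fasted", "fed"]

#: Canonical luminal segment order, stomach -> rectum.
GI_SEGMENT_ORDER: tuple[str, ...] = (
    "stomach",
    "duodenum",
    "upper_jejunum",
    "lower_jejunum",
    "upper_ileum",
    "lower_ileum",
    "caecum",
    "colon_ascendens",
    "colon_transversum",
    "colon_descendens",
    "colon_sigmoid",
    "rectum",
)

#: Large-intestinal sub-compartments (six members).
COLONIC_SEGMENTS: tuple[str, ...] = GI_SEGMENT_ORDER[6:]

#: Segments whose absorption flux drains into the small-intestinal wall.
SMALL_INTESTINE_SEGMENTS: tuple[str, ...] = GI_SEGMENT_ORDER[1:6]

ORGAN_NAMES: tuple[str, ...] = (
    "lung",
    "heart",
    "brain",
    "muscle",
    "adipose",
    "skin",
    "bone",
    "liver",
    "kidney",
    "spleen",
    "pancreas",
    "stomach",
    "small_intestine",
    "large_intestine",
    "gonads",
)

#: Splanchnic organs whose venous outflow feeds the portal vein (-> liver).
PORTAL_ORGANS: tuple[str, ...] = (
    "stomach",
    "small_intestine",
    "large_intestine",
    "spleen",
    "pancreas",
)


@dataclass(frozen=True)
class TissueComposition:
    """Rodgers-Rowland fractional tissue volumes (dimensionless)."""

    f_intracellular_water: float
    f_extracellular_water: float
    f_neutral_lipid: float
    f_neutral_phospholipid: float

    def __post_init__(self) -> None:
        fractions = (
            self.f_intracellular_water,
            self.f_extracellular_water,
            self.f_neutral_lipid,
            self.f_neutral_phospholipid,
        )
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ValueError("composition fractions must lie in [0, 1]")
        if sum(fractions) > 1.0 + 1e-9:
            raise ValueError("composition fractions must sum to <= 1")

    @property
    def f_water(self) -> float:
        return self.f_intracellular_water + self.f_extracellular_water

    def to_dict(self) -> dict:
        return {
            "f_intracellular_water": self.f_intracellular_water,
            "f_extracellular_water": self.f_extracellular_water,
            "f_neutral_lipid": self.f_neutral_lipid,
            "f_neutral_phospholipid": self.f_neutral_phospholipid,
        }


@dataclass(frozen=True)
class Organ:
    """A perfusion-limited tissue compartment.

    ``blood_flow`` is the organ plasma/blood inflow in L/h (for the liver the
    hepatic-artery share only; portal inflow is added by the model builder).
    ``cyp3a4_rel_expression`` scales the CYP3A4 concentration relative to
    liver (= 1).
    """

    name: str
    volume: float  # L
    blood_flow: float  # L/h
    composition: TissueComposition
    cyp3a4_rel_expression: float = 0.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"organ {self.name}: volume must be > 0")
        if self.blood_flow < 0:
            raise ValueError(f"organ {self.name}: blood_flow must be >= 0")
        if self.cyp3a4_rel_expression < 0:
            raise ValueError(f"organ {self.name}: cyp3a4_rel_expression must be >= 0")

    def to_dict(self) -> dict:
        return {
            "volume_l": self.volume,
            "blood_flow_l_h": self.blood_flow,
            "cyp3a4_rel_expression": self.cyp3a4_rel_expression,
            "composition": self.composition.to_dict(),
        }


@dataclass(frozen=True)
class GISegment:
    """One luminal segment, with fasted and fed transit/pH values."""

    name: str
    transit_time: dict  # {"fasted": h, "fed": h}
    ph: dict  # {"fasted": pH, "fed": pH}
    fluid_volume: float  # L
    effective_area: float  # cm^2, mucosal amplification included
    solubility_override: float | None = None  # mg/L
    cyp3a4_rel_expression: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in GI_SEGMENT_ORDER:
            raise ValueError(f"unknown GI segment name {self.name!r}")
        for state in ("fasted", "fed"):
            if self.transit_time[state] <= 0:
                raise ValueError(f"{self.name}: transit_time must be > 0")
            if not 0.0 < self.ph[state] < 14.0:
                raise ValueError(f"{self.name}: pH out of range")
        if self.fluid_volume <= 0 or self.effective_area <= 0:
            raise ValueError(f"{self.name}: fluid volume and area must be > 0")

    @property
    def is_colonic(self) -> bool:
        return self.name in COLONIC_SEGMENTS

    def transit_time_h(self, food_state: FoodState) -> float:
        return float(self.transit_time[food_state])

    def ph_value(self, food_state: FoodState) -> float:
        return float(self.ph[food_state])

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "transit_time_h": dict(self.transit_time),
            "ph": dict(self.ph),
            "fluid_volume_l": self.fluid_volume,
            "effective_area_cm2": self.effective_area,
            "cyp3a4_rel_expression": self.cyp3a4_rel_expression,
        }
        if self.solubility_override is not None:
            d["solubility_override_mg_l"] = self.solubility_override
        return d


@dataclass(frozen=True)
class PhysiologyIndividual:
    """A fully parameterized virtual individual."""

    organs: tuple[Organ, ...]
    gi_tract: tuple[GISegment, ...]
    gfr: float  # mL/min
    venous_volume: float  # L
    arterial_volume: float  # L
    plasma_composition: TissueComposition
    liver_cyp3a4_conc: float = 4.32  # µmol/L
    liver_protein_per_gram: float = 40.0  # mg/g
    cyp3a4_halflife: float = 36.0  # h
    food_state: FoodState = "fasted"
    body_weight: float = 73.0  # kg
    height: float = 176.0  # cm

    def __post_init__(self) -> None:
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise ValueError("organ names must be unique")
        if self.gfr <= 0:
            raise ValueError("gfr must be > 0")
        if self.liver_cyp3a4_conc <= 0:
            raise ValueError("liver_cyp3a4_conc must be > 0")
        gi_names = tuple(s.name for s in self.gi_tract)
        if gi_names != GI_SEGMENT_ORDER[: len(gi_names)]:
            raise ValueError("GI segments must be ordered stomach -> rectum")

    def organ(self, name: str) -> Organ:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(f"individual has no organ {name!r}")

    def segment(self, name: str) -> GISegment:
        for s in self.gi_tract:
            if s.name == name:
                return s
        raise KeyError(f"individual has no GI segment {name!r}")

    @property
    def cyp3a4_kdeg(self) -> float:
        """First-order CYP3A4 degradation rate constant, 1/h."""
        return math.log(2.0) / self.cyp3a4_halflife

    def with_food_state(self, food_state: FoodState) -> "PhysiologyIndividual":
        return replace(self, food_state=food_state)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": "individual",
            "body_weight_kg": self.body_weight,
            "height_cm": self.height,
            "gfr_ml_min": self.gfr,
            "liver_cyp3a4_umol_per_l": self.liver_cyp3a4_conc,
            "liver_protein_mg_per_g": self.liver_protein_per_gram,
            "cyp3a4_halflife_h": self.cyp3a4_halflife,
            "food_state": self.food_state,
            "blood": {"venous_l": self.venous_volume, "arterial_l": self.arterial_volume},
            "plasma_composition": self.plasma_composition.to_dict(),
            "organs": {o.name: o.to_dict() for o in self.organs},
            "gi_tract": [s.to_dict() for s in self.gi_tract],
        }

    @classmethod
    def from_dict(cls, data: dict, food_state: FoodState | None = None) -> "PhysiologyIndividual":
        organs = tuple(
            Organ(
                name=name,
                volume=od["volume_l"],
                blood_flow=od["blood_flow_l_h"],
                cyp3a4_rel_expression=od.get("cyp3a4_rel_expression", 0.0),
                composition=TissueComposition(**od["composition"]),
            )
            for name, od in data["organs"].items()
        )
        gi = tuple(
            GISegment(
                name=sd["name"],
                transit_time=sd["transit_time_h"],
                ph=sd["ph"],
                fluid_volume=sd["fluid_volume_l"],
                effective_area=sd["effective_area_cm2"],
                solubility_override=sd.get("solubility_override_mg_l"),
                cyp3a4_rel_expression=sd.get("cyp3a4_rel_expression", 0.0),
            )
            for sd in data["gi_tract"]
        )
        return cls(
            organs=organs,
            gi_tract=gi,
            gfr=data["gfr_ml_min"],
            venous_volume=data["blood"]["venous_l"],
            arterial_volume=data["blood"]["arterial_l"],
            plasma_composition=TissueComposition(**data["plasma_composition"]),
            liver_cyp3a4_conc=data.get("liver_cyp3a4_umol_per_l", 4.32),
            liver_protein_per_gram=data.get("liver_protein_mg_per_g", 40.0),
            cyp3a4_halflife=data.get("cyp3a4_halflife_h", 36.0),
            food_state=food_state or data.get("food_state", "fasted"),
            body_weight=data.get("body_weight_kg", 73.0),
            height=data.get("height_cm", 176.0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path, food_state: FoodState | None = None) -> "PhysiologyIndividual":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), food_state=food_state)


def default_individual(food_state: FoodState = "fasted") -> PhysiologyIndividual:
    """The shipped standard-European-male reference individual.

    Fasted and fed variants differ only in gastric emptying time, the luminal
    pH table, and (via the compound module) the active reference solubility.
    """
    if food_state not in ("fasted", "fed"):
        raise ValueError(f"food_state must be 'fasted' or 'fed', got {food_state!r}")
    ref = resources.files("bevpbpk.data") / "european_male_default.yaml"
    data = yaml.safe_load(ref.read_text())
    return PhysiologyIndividual.from_dict(data, food_state=food_state)


def cyp3a4_abundance(ind: PhysiologyIndividual, organ: Organ | str) -> float:
    """Absolute CYP3A4 amount in an organ, µmol.

    The liver amount is liver concentration x liver volume; every other organ
    scales with its expression relative to liver.
    """
    if isinstance(organ, str):
        organ = ind.organ(organ)
    elif organ not in ind.organs:
        raise KeyError(f"organ {organ.name!r} does not belong to this individual")
    return ind.liver_cyp3a4_conc * organ.cyp3a4_rel_expression * organ.volume
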