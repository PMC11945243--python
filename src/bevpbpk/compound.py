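"""Compound parameterization, pH-dependent solubility, and tissue partitioning.

Bevurogant is a lipophilic monoprotic base (pKa 2.2), i.e. effectively
neutral at physiological pH: its ionized fraction at pH 7.4 is below 1e-5.
Solubility in the gastrointestinal lumen therefore falls steeply from the
acidic stomach to the near-neutral intestine and is described by the
Henderson-Hasselbalch relation anchored at a biorelevant reference medium
(FaSSIF when fasted, FeSSIF when fed).  Tissue:plasma partition coefficients
come from the Rodgers & Rowland composition-based model, using the neutral
branch (tissue water plus neutral-lipid and neutral-phospholipid
partitioning) scaled by the unbound plasma fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import yaml

from .physiology import (
    FoodState,
    GISegment,
    PhysiologyIndividual,
    TissueComposition,
)


@dataclass(frozen=True)
class CompoundParameters:
    """Physicochemical and ADME inputs of the compound model.

    ``clint_hepatic`` is the whole-body CYP3A4 intrinsic clearance in mL/min;
    ``clint_scaling`` is the stored normalization factor that converts it to
    the unbound-plasma-referenced intrinsic clearance the ODE model consumes
    (the source value's normalization convention is not part of the public
    parameter set, so the interpretation is pinned in the config).
    """

    name: str
    mw: float  # g/mol
    pka: float
    logp: float
    intestinal_permeability: float  # cm/s
    sol_ref_fasted: float  # mg/L at sol_ref_fasted_ph
    sol_ref_fed: float  # mg/L at sol_ref_fed_ph
    fu_plasma: float
    clint_hepatic: float  # mL/min
    gfr_fraction: float
    colon_solubility_override: float | None = None  # mg/L
    sol_ref_fasted_ph: float = 6.5
    sol_ref_fed_ph: float = 5.0
    pka_type: str = "base"
    clint_scaling: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fu_plasma <= 1.0:
            raise ValueError("fu_plasma must be in (0, 1]")
        if self.sol_ref_fasted <= 0 or self.sol_ref_fed <= 0:
            raise ValueError("reference solubilities must be > 0")
        if self.gfr_fraction < 0:
            raise ValueError("gfr_fraction must be >= 0")
        if self.intestinal_permeability <= 0:
            raise ValueError("permeability must be > 0")
        if self.mw <= 0:
            raise ValueError("mw must be > 0")

    # -- unit helpers ------------------------------------------------------

    def mg_to_umol(self, mg: float) -> float:
        return mg / self.mw * 1000.0

    def umol_to_mg(self, umol: float) -> float:
        return umol * self.mw / 1000.0

    @property
    def clint_effective_l_h(self) -> float:
        """Unbound-plasma-referenced whole-body intrinsic clearance, L/h."""
        return self.clint_hepatic * self.clint_scaling * 60.0 / 1000.0

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "mw_g_mol": self.mw,
            "pka": self.pka,
            "pka_type": self.pka_type,
            "logp": self.logp,
            "intestinal_permeability_cm_s": self.intestinal_permeability,
            "sol_ref_fasted_mg_l": self.sol_ref_fasted,
            "sol_ref_fasted_ph": self.sol_ref_fasted_ph,
            "sol_ref_fed_mg_l": self.sol_ref_fed,
            "sol_ref_fed_ph": self.sol_ref_fed_ph,
            "fu_plasma": self.fu_plasma,
            "clint_hepatic_ml_min": self.clint_hepatic,
            "clint_scaling": self.clint_scaling,
            "gfr_fraction": self.gfr_fraction,
        }
        if self.colon_solubility_override is not None:
            d["colon_solubility_override_mg_l"] = self.colon_solubility_override
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "CompoundParameters":
        return cls(
            name=data.get("name", "compound"),
            mw=data["mw_g_mol"],
            pka=data["pka"],
            pka_type=data.get("pka_type", "base"),
            logp=data["logp"],
            intestinal_permeability=data["intestinal_permeability_cm_s"],
            sol_ref_fasted=data["sol_ref_fasted_mg_l"],
            sol_ref_fasted_ph=data.get("sol_ref_fasted_ph", 6.5),
            sol_ref_fed=data["sol_ref_fed_mg_l"],
            sol_ref_fed_ph=data.get("sol_ref_fed_ph", 5.0),
            fu_plasma=data["fu_plasma"],
            clint_hepatic=data["clint_hepatic_ml_min"],
            clint_scaling=data.get("clint_scaling", 1.0),
            gfr_fraction=data["gfr_fraction"],
            colon_solubility_override=data.get("colon_solubility_override_mg_l"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CompoundParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def without_colon_override(self) -> "CompoundParameters":
        return replace(self, colon_solubility_override=None)


def load_bi730357(initial: bool = False) -> CompoundParameters:
    """The shipped bevurogant parameter set (final, or pre-optimization)."""
    fname = "bi730357_initial.yaml" if initial else "bi730357.yaml"
    ref = resources.files("bevpbpk.data") / fname
    return CompoundParameters.from_dict(yaml.safe_load(ref.read_text()))


def solubility_at_ph(cp: CompoundParameters, ph: float, food_state: FoodState = "fasted") -> float:
    """pH-dependent solubility of a monoprotic base, mg/L.

    Henderson-Hasselbalch scaling from the food-state reference medium:
    S(pH) = S_ref * (1 + 10^(pKa - pH)) / (1 + 10^(pKa - pH_ref)).
    """
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH {ph} out of range (0, 14)")
    if food_state == "fed":
        s_ref, ph_ref = cp.sol_ref_fed, cp.sol_ref_fed_ph
    else:
        s_ref, ph_ref = cp.sol_ref_fasted, cp.sol_ref_fasted_ph
    return s_ref * (1.0 + 10.0 ** (cp.pka - ph)) / (1.0 + 10.0 ** (cp.pka - ph_ref))


def segment_solubility(cp: CompoundParameters, seg: GISegment, food_state: FoodState = "fasted") -> float:
    """Luminal solubility in a GI segment, mg/L.

    A segment-level override (the elevated colonic solubility) wins over the
    Henderson-Hasselbalch value at the segment pH; the compound-level colonic
    override applies to the distal colon, transversum through sigmoid.
    """
    if seg.solubility_override is not None:
        return seg.solubility_override
    if cp.colon_solubility_override is not None and seg.name in (
        "colon_transversum",
        "colon_descendens",
        "colon_sigmoid",
    ):
        return cp.colon_solubility_override
    return solubility_at_ph(cp, seg.ph_value(food_state), food_state)


def logp_vow(logp: float) -> float:
    """Vegetable-oil:water log partition coefficient from logP (octanol).

    Standard empirical regression log P_vo:w = 1.115 logP - 1.35, used for
    the neutral-lipid term of adipose tissue.
    """
    return 1.115 * logp - 1.35


def kp_rodgers_rowland(
    cp: CompoundParameters,
    tc: TissueComposition,
    plasma: TissueComposition | None = None,
    adipose: bool = False,
) -> float:
    """Tissue:plasma partition coefficient, Rodgers & Rowland neutral branch.

    Kp = fu_p * [f_IW + f_EW + P*f_NL + (0.3P + 0.7)*f_NP]_tissue / D_plasma
    with P = 10^logP and D_plasma the same bracket evaluated for plasma
    (water plus plasma lipids).  For adipose tissue the neutral-lipid term
    uses the vegetable-oil:water coefficient instead of P (``adipose=True``).
    With the default pure-aqueous plasma reference the denominator is 1, so a
    lipid-free tissue with fu = 1 partitions exactly with its water fraction.
    """
    p = 10.0 ** cp.logp
    p_nl = 10.0 ** logp_vow(cp.logp) if adipose else p

    def bracket(c: TissueComposition, nl_p: float) -> float:
        return (
            c.f_intracellular_water
            + c.f_extracellular_water
            + nl_p * c.f_neutral_lipid
            + (0.3 * p + 0.7) * c.f_neutral_phospholipid
        )

    denom = bracket(plasma, p) if plasma is not None else 1.0
    if denom <= 0:
        raise ValueError("non-physical plasma reference composition")
    kp = cp.fu_plasma * bracket(tc, p_nl) / denom
    if kp <= 0:
        raise ValueError("non-physical tissue composition (Kp <= 0)")
    return kp


def partition_set(cp: CompoundParameters, ind: PhysiologyIndividual) -> dict[str, float]:
    """Per-organ Kp for every organ of an individual."""
    plasma = ind.plasma_composition
    return {
        o.name: kp_rodgers_rowland(cp, o.composition, plasma, adipose=o.name == "adipose")
        for o in ind.organs
    }
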