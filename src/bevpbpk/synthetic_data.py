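"""Synthetic "clinical-like" Phase I datasets.

The original concentration data are not shareable, so every pipeline stage
(fitting, NCA, DDI evaluation) is exercised on synthetic subject-level data
instead: each subject is a virtual individual drawn by the population module,
simulated under the arm's regimen, and observed through a residual-error
model (proportional log-normal with an additive floor near the LLOQ, then
LLOQ censoring).  The five shipped designs are reconstructions of the Phase I
roster — single ascending dose, 14-day multiple dose (fasted and fed),
IV microtracer after an oral dose, itraconazole DDI, and a food-effect
crossover — with dense standard sampling grids; they define study structure,
not the unavailable observed values.

Datasets are regenerable bit-identically from their metadata (design id,
truth parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .absorption import FormulationTable, WeibullFormulation
from .compound import CompoundParameters, load_bi730357
from .ddi import PerpetratorAction
from .pbpk_core import DosingRegimen, build_model, simulate
from .physiology import FoodState, PhysiologyIndividual, default_individual
from .population import DEFAULT_CVS, PopulationSpec, generate_population

#: Standard dense single-dose sampling grid, h.
SINGLE_DOSE_TIMES: tuple[float, ...] = (0.5, 1, 2, 3, 4, 6, 8, 12, 16, 24, 36, 48, 72)


@dataclass(frozen=True)
class Arm:
    arm_id: str
    route: str
    dose_mg: float
    food_state: FoodState = "fasted"
    n_doses: int = 1
    tau_h: float = 24.0
    n_subjects: int = 6
    sampling_times: tuple = SINGLE_DOSE_TIMES
    formulation_key: tuple | None = None  # (study, dose_mg, food_state, tag)
    co_medication: str | None = None  # label only; perpetrator passed at generation
    urine_intervals: tuple = ()  # ((t_start, t_end), ...) h

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        times = list(self.sampling_times)
        if times != sorted(times) or any(t < 0 for t in times):
            raise ValueError("sampling times must be sorted and nonnegative")


@dataclass(frozen=True)
class StudyDesign:
    design_id: str
    arms: tuple[Arm, ...]

    def subset(self, arm_ids: Sequence[str]) -> "StudyDesign":
        keep = tuple(a for a in self.arms if a.arm_id in set(arm_ids))
        if not keep:
            raise KeyError(f"no arms matching {arm_ids!r} in design {self.design_id}")
        return StudyDesign(self.design_id, keep)


@dataclass
class ObservedDataset:
    """Tidy records plus metadata sufficient to regenerate them."""

    records: pd.DataFrame  # study, subject, arm, matrix, time_h, value, blq
    metadata: dict

    def plasma(self, arm_id: str | None = None) -> pd.DataFrame:
        df = self.records[self.records["matrix"] == "plasma"]
        if arm_id is not None:
            df = df[df["arm"] == arm_id]
        return df.rename(columns={"value": "conc_nmol_per_l"})

    def urine(self, arm_id: str | None = None) -> pd.DataFrame:
        df = self.records[self.records["matrix"] == "urine"]
        if arm_id is not None:
            df = df[df["arm"] == arm_id]
        return df.rename(columns={"value": "amount_umol"})


def study_designs() -> dict[str, StudyDesign]:
    """The five reconstructed Phase I study designs."""
    mad_times = tuple(SINGLE_DOSE_TIMES[:-3]) + (24.0,)
    designs = {
        "1407-0001": StudyDesign(
            "1407-0001",
            tuple(
                [
                    Arm("sol-2mg", "oral_solution", 2.0, n_subjects=6),
                    Arm("sol-25mg", "oral_solution", 25.0, n_subjects=6,
                        urine_intervals=((0, 24), (24, 48), (48, 72))),
                ]
                + [
                    Arm(
                        f"tab-{d}mg",
                        "oral_tablet",
                        float(d),
                        n_subjects=6,
                        formulation_key=("1407-0001", float(d), "fasted", None),
                    )
                    for d in (50, 100, 200, 400)
                ]
            ),
        ),
        "1407-0002": StudyDesign(
            "1407-0002",
            tuple(
                [
                    Arm(
                        f"tab-{d}mg-fasted",
                        "oral_tablet",
                        float(d),
                        n_doses=14,
                        n_subjects=9,
                        sampling_times=mad_times,
                        formulation_key=("1407-0002", float(d), "fasted", None),
                    )
                    for d in (25, 50, 100, 200)
                ]
                + [
                    Arm(
                        f"tab-{d}mg-fed",
                        "oral_tablet",
                        float(d),
                        food_state="fed",
                        n_doses=14,
                        n_subjects=9,
                        sampling_times=mad_times,
                        formulation_key=("1407-0002", float(d), "fed", None),
                    )
                    for d in (50, 200, 400)
                ]
            ),
        ),
        "1407-0033": StudyDesign(
            "1407-0033",
            (
                Arm("iv-microtracer", "iv_bolus", 0.1, n_subjects=6),
                Arm("oral-ref", "oral_tablet", 35.26, n_subjects=6,
                    formulation_key=("1407-0001", 50.0, "fasted", None)),
            ),
        ),
        "1407-0014": StudyDesign(
            "1407-0014",
            (
                Arm(
                    "control",
                    "oral_tablet",
                    50.0,
                    n_subjects=12,
                    formulation_key=("1407-0014", 50.0, "fasted", "ddi"),
                ),
                Arm(
                    "treated",
                    "oral_tablet",
                    50.0,
                    n_subjects=12,
                    formulation_key=("1407-0014", 50.0, "fasted", "ddi"),
                    co_medication="itraconazole 200 mg q.d. from Day -3",
                ),
            ),
        ),
        "food-effect": StudyDesign(
            "food-effect",
            (
                Arm("fasted-50mg", "oral_tablet", 50.0,
                    formulation_key=("1407-0002", 50.0, "fasted", None)),
                Arm("fed-50mg", "oral_tablet", 50.0, food_state="fed",
                    formulation_key=("1407-0002", 50.0, "fed", None)),
            ),
        ),
    }
    return designs


DEFAULT_ERROR = {"prop_cv": 0.20, "additive_floor": 0.5, "lloq": 1.0}  # nmol/L


def _arm_regimen(arm: Arm, formulations: FormulationTable) -> DosingRegimen:
    form: WeibullFormulation | None = None
    if arm.route == "oral_tablet":
        if arm.formulation_key is None:
            raise ValueError(f"arm {arm.arm_id}: tablet arm needs a formulation key")
        study, dose, food, tag = arm.formulation_key
        form = formulations.get(study, dose, food, tag=tag)
    times = tuple(i * arm.tau_h for i in range(arm.n_doses))
    return DosingRegimen(
        route=arm.route,
        dose=arm.dose_mg,
        times=times,
        food_state=arm.food_state,
        formulation=form,
    )


def generate_study(
    design: StudyDesign,
    seed: int,
    cp: CompoundParameters | None = None,
    formulations: FormulationTable | None = None,
    variability: dict | None = None,
    error: dict | None = None,
    perpetrator: PerpetratorAction | None = None,
    n_subjects: int | None = None,
    rtol: float = 1e-6,
) -> ObservedDataset:
    """Simulate subject-level observations for one study design.

    Interindividual variability comes from seeded virtual individuals;
    residual error is proportional log-normal with an additive floor, then
    LLOQ-censored (BLQ rows keep the LLOQ value and are flagged).
    Deterministic for a fixed seed.
    """
    cp = cp or load_bi730357()
    formulations = formulations or FormulationTable.load_default()
    err = {**DEFAULT_ERROR, **(error or {})}
    cvs = dict(DEFAULT_CVS) if variability is None else dict(variability)

    ss = np.random.SeedSequence(seed)
    arm_seeds = ss.spawn(len(design.arms))
    rows = []
    for arm, arm_ss in zip(design.arms, arm_seeds):
        n = n_subjects or arm.n_subjects
        pop_seed = int(arm_ss.generate_state(1)[0] % (2**31))
        pop = generate_population(
            default_individual(arm.food_state),
            PopulationSpec(n=n, seed=pop_seed, variability=cvs),
        )
        rng = np.random.default_rng(arm_ss.spawn(1)[0])
        reg = _arm_regimen(arm, formulations)
        ddi = perpetrator if arm.co_medication else None
        t_last_dose = reg.times[-1]
        t_obs = np.asarray(arm.sampling_times, dtype=float) + t_last_dose
        t_end = max(float(t_obs[-1]), t_last_dose + 24.0)
        for subj, ind in enumerate(pop):
            res = simulate(
                build_model(ind, cp, reg, ddi=ddi), t_end, t_eval=t_obs, rtol=rtol, atol=1e-8
            )
            true_c = np.interp(t_obs, res.time, res.plasma_conc)
            sigma = np.sqrt(np.log(1.0 + err["prop_cv"] ** 2))
            noisy = true_c * np.exp(rng.normal(0.0, sigma, size=len(t_obs))) + rng.normal(
                0.0, err["additive_floor"], size=len(t_obs)
            )
            noisy = np.clip(noisy, 0.0, None)
            blq = noisy < err["lloq"]
            for tt, cc, true_cc, is_blq in zip(t_obs, noisy, true_c, blq):
                rows.append(
                    {
                        "study": design.design_id,
                        "subject": f"{arm.arm_id}-{subj:03d}",
                        "arm": arm.arm_id,
                        "matrix": "plasma",
                        "time_h": float(tt),
                        "value": float(err["lloq"] if is_blq else cc),
                        "true_value": float(true_cc),
                        "blq": bool(is_blq),
                    }
                )
            for (t_a, t_b) in arm.urine_intervals:
                renal = np.interp([t_a, t_b], res.time, res.ledger["renal"].to_numpy())
                amt_true = float(renal[1] - renal[0])
                amt = amt_true * np.exp(rng.normal(0.0, sigma))
                rows.append(
                    {
                        "study": design.design_id,
                        "subject": f"{arm.arm_id}-{subj:03d}",
                        "arm": arm.arm_id,
                        "matrix": "urine",
                        "time_h": float(t_b),
                        "interval_start_h": float(t_a),
                        "value": float(amt),
                        "true_value": amt_true,
                        "blq": False,
                    }
                )
    records = pd.DataFrame(rows)
    metadata = {
        "design_id": design.design_id,
        "seed": int(seed),
        "compound": cp.to_dict(),
        "error_model": err,
        "variability": cvs,
        "n_subjects_override": n_subjects,
    }
    return ObservedDataset(records=records, metadata=metadata)


def interstudy_shift(
    dataset: ObservedDataset, cv: float, seed: int
) -> ObservedDataset:
    """Apply a study-level log-normal exposure multiplier.

    Emulates interstudy variability (formulation batches, conduct
    differences) as a single shared factor on all concentration records of
    the study; regenerable per seed.
    """
    rng = np.random.default_rng(seed)
    factor = 1.0 if cv <= 0 else float(np.exp(rng.normal(0.0, np.sqrt(np.log(1 + cv**2)))))
    records = dataset.records.copy()
    mask = records["matrix"] == "plasma"
    records.loc[mask, "value"] *= factor
    records.loc[mask, "true_value"] *= factor
    meta = dict(dataset.metadata)
    meta["interstudy_shift"] = {"cv": cv, "seed": int(seed), "factor": factor}
    return ObservedDataset(records=records, metadata=meta)
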