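"""Parameter identification by staged, multi-start nonlinear least squares.

Fitting minimizes residuals between observed concentrations and simulation
output, by default on the log scale (plasma PK data span several decades).
Each fit runs from several randomized starting points (Latin-hypercube in
the transformed parameter space) through a trust-region least-squares
optimizer and keeps the best converged start; results are deterministic for
a fixed seed.

The staged workflow mirrors how a disposition-first model is informed:
IV data fix lipophilicity and metabolic clearance, oral-solution data fix
intestinal permeability, urinary excretion fixes the renal GFR fraction, and
tablet data fix the empirical Weibull dissolution parameters per dose/study.
Earlier-stage estimates are frozen before later stages run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .absorption import WeibullFormulation
from .compound import CompoundParameters
from .pbpk_core import DosingRegimen, build_model, simulate
from .physiology import PhysiologyIndividual


@dataclass(frozen=True)
class FitParameter:
    name: str
    lower: float
    upper: float
    transform: str = "log"  # or "linear"

    def __post_init__(self) -> None:
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            raise ValueError(f"{self.name}: bounds must be finite")
        if self.lower >= self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if self.transform == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log transform requires positive bounds")

    def to_internal(self, x: float) -> float:
        return np.log(x) if self.transform == "log" else x

    def from_internal(self, z: float) -> float:
        return float(np.exp(z)) if self.transform == "log" else float(z)


@dataclass(frozen=True)
class FitSpec:
    free_parameters: tuple[FitParameter, ...]
    objective: str = "log_residual_ss"  # or "linear_residual_ss"
    n_starts: int = 10
    n_prescreen: int = 40  # Monte Carlo screening points ranked before refinement
    seed: int = 0
    max_iter: int = 200
    xtol: float = 1e-10
    ftol: float = 1e-10
    #: finite-difference step in the transformed space; must dominate the
    #: ODE integration noise or the jacobian degenerates
    diff_step: float = 1e-3
    lloq: float = 0.0  # observations at/below this are excluded

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.objective not in ("log_residual_ss", "linear_residual_ss"):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class FitResult:
    estimates: dict
    objective_value: float
    best_start: int
    starts: pd.DataFrame  # per-start diagnostics

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


def fit(
    predict: Callable[[dict], np.ndarray],
    observed: np.ndarray,
    spec: FitSpec,
) -> FitResult:
    """Best-of-multi-start least squares.

    ``predict`` maps a parameter dict to model output aligned with
    ``observed``; residuals are taken on the scale set by ``spec.objective``.
    """
    obs = np.asarray(observed, dtype=float)
    keep = obs > spec.lloq
    if not np.any(keep):
        raise ValueError("no observations above the LLOQ")
    log_scale = spec.objective == "log_residual_ss"
    obs_used = np.log(obs[keep]) if log_scale else obs[keep]
    params = spec.free_parameters
    lo = np.array([p.to_internal(p.lower) for p in params])
    hi = np.array([p.to_internal(p.upper) for p in params])

    def residuals(z: np.ndarray) -> np.ndarray:
        values = {p.name: p.from_internal(zi) for p, zi in zip(params, z)}
        pred = np.asarray(predict(values), dtype=float)[keep]
        if log_scale:
            pred = np.log(np.clip(pred, 1e-12, None))
        return pred - obs_used

    # Monte Carlo screening: rank Latin-hypercube candidates by objective,
    # then refine the best ones with the local least-squares optimizer
    sampler = qmc.LatinHypercube(d=len(params), seed=spec.seed)
    n_cand = max(spec.n_prescreen, spec.n_starts)
    cands = lo + sampler.random(n_cand) * (hi - lo)
    if n_cand > spec.n_starts:
        scores = []
        for z in cands:
            try:
                r = residuals(z)
                scores.append(float(r @ r))
            except Exception:
                scores.append(np.inf)
        order = np.argsort(scores)[: spec.n_starts]
        z0s = cands[order]
    else:
        z0s = cands

    rows, best = [], None
    for s, z0 in enumerate(z0s):
        try:
            sol = least_squares(
                residuals,
                z0,
                bounds=(lo, hi),
                method="trf",
                xtol=spec.xtol,
                ftol=spec.ftol,
                diff_step=spec.diff_step,
                max_nfev=spec.max_iter * (len(params) + 1),
            )
            cost, ok, msg = 2.0 * sol.cost, sol.success, sol.message
            z_hat = sol.x
        except Exception as exc:  # pragma: no cover - solver pathologies
            cost, ok, msg, z_hat = np.inf, False, str(exc), z0
        rows.append(
            {
                "start": s,
                "objective": cost,
                "converged": ok,
                "message": msg,
                **{p.name: p.from_internal(zi) for p, zi in zip(params, z_hat)},
            }
        )
        if ok and (best is None or cost < best[0]):
            best = (cost, s, z_hat)
    starts = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError(f"no start converged:\n{starts}")
    cost, s_best, z_hat = best
    return FitResult(
        estimates={p.name: p.from_internal(zi) for p, zi in zip(params, z_hat)},
        objective_value=float(cost),
        best_start=int(s_best),
        starts=starts,
    )


# -- staged workflow -------------------------------------------------------


def _pooled(df: pd.DataFrame, value_col: str) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-mean pooling of repeated observations per time point."""
    g = df[df[value_col] > 0].groupby("time_h")[value_col]
    pooled = g.apply(lambda v: float(np.exp(np.mean(np.log(v)))))
    t = pooled.index.to_numpy(dtype=float)
    return t, pooled.to_numpy(dtype=float)


def staged_workflow(
    ind: PhysiologyIndividual,
    cp_init: CompoundParameters,
    data: dict,
    n_starts: int = 4,
    seed: int = 0,
    rtol: float = 1e-6,
) -> dict[str, FitResult | None]:
    """Sequential disposition-first fitting.

    ``data`` maps stage names to inputs:

    * ``"iv"``: {"df": tidy plasma data, "dose_mg", "t_end"} — fits
      {logp, clint_hepatic}
    * ``"solution"``: same shape — fits {intestinal_permeability}
    * ``"urine"``: {"df" with cumulative amount_umol, "dose_mg", "t_end"} —
      fits {gfr_fraction}
    * ``"tablet"``: {"df", "dose_mg", "t_end", "shape_init", "t50_init"} —
      fits the Weibull {shape, t50}

    Missing stages are skipped with a warning; each stage freezes its
    estimates into the compound before the next stage runs.
    """
    cp = cp_init
    results: dict[str, FitResult | None] = {}

    def plasma_predict(regimen_builder, t_obs, t_end):
        def predict(values: dict) -> np.ndarray:
            cp_trial = replace(cp, **{k: v for k, v in values.items() if hasattr(cp, k)})
            reg = regimen_builder(values, cp_trial)
            res = simulate(build_model(ind, cp_trial, reg), t_end, t_eval=t_obs, rtol=rtol, atol=1e-8)
            return np.interp(t_obs, res.time, res.plasma_conc)

        return predict

    # stage 1: disposition from IV data
    if "iv" in data:
        d = data["iv"]
        t_obs, c_obs = _pooled(d["df"], "conc_nmol_per_l")
        spec = FitSpec(
            free_parameters=(
                FitParameter("logp", 1.5, 4.0, transform="linear"),
                FitParameter("clint_hepatic", 30.0, 600.0),
            ),
            n_starts=n_starts,
            seed=seed,
        )
        reg = lambda values, cpx: DosingRegimen(route="iv_bolus", dose=d["dose_mg"])
        results["iv"] = fit(plasma_predict(reg, t_obs, d["t_end"]), c_obs, spec)
        cp = replace(cp, **results["iv"].estimates)
    else:
        warnings.warn("stage 'iv' skipped: no data")
        results["iv"] = None

    # stage 2: permeability from oral solution
    if "solution" in data:
        d = data["solution"]
        t_obs, c_obs = _pooled(d["df"], "conc_nmol_per_l")
        spec = FitSpec(
            free_parameters=(
                FitParameter("intestinal_permeability", 1e-8, 1e-4),
            ),
            n_starts=n_starts,
            seed=seed + 1,
        )
        reg = lambda values, cpx: DosingRegimen(route="oral_solution", dose=d["dose_mg"])
        results["solution"] = fit(plasma_predict(reg, t_obs, d["t_end"]), c_obs, spec)
        cp = replace(cp, **results["solution"].estimates)
    else:
        warnings.warn("stage 'solution' skipped: no data")
        results["solution"] = None

    # stage 3: renal fraction from urinary excretion (interval amounts)
    if "urine" in data:
        d = data["urine"]
        df_u = d["df"]
        t_obs, a_obs = _pooled(df_u, "amount_umol")
        route = d.get("route", "oral_solution")
        if "interval_start_h" in df_u.columns:
            starts = (
                df_u.dropna(subset=["interval_start_h"])
                .groupby("time_h")["interval_start_h"]
                .first()
                .reindex(t_obs)
                .to_numpy(dtype=float)
            )
        else:
            starts = np.concatenate([[0.0], t_obs[:-1]])

        def predict_urine(values: dict) -> np.ndarray:
            cp_trial = replace(cp, gfr_fraction=values["gfr_fraction"])
            reg = DosingRegimen(route=route, dose=d["dose_mg"], formulation=d.get("formulation"))
            res = simulate(build_model(ind, cp_trial, reg), d["t_end"], t_eval=t_obs, rtol=rtol, atol=1e-8)
            cum = res.ledger["renal"].to_numpy()
            return np.interp(t_obs, res.time, cum) - np.interp(starts, res.time, cum)

        spec = FitSpec(
            free_parameters=(FitParameter("gfr_fraction", 1e-3, 1.0),),
            n_starts=n_starts,
            seed=seed + 2,
        )
        results["urine"] = fit(predict_urine, a_obs, spec)
        cp = replace(cp, gfr_fraction=results["urine"].estimates["gfr_fraction"])
    else:
        warnings.warn("stage 'urine' skipped: no data")
        results["urine"] = None

    # stage 4: Weibull dissolution from tablet data
    if "tablet" in data:
        d = data["tablet"]
        t_obs, c_obs = _pooled(d["df"], "conc_nmol_per_l")

        def reg_tablet(values: dict, cpx) -> DosingRegimen:
            return DosingRegimen(
                route="oral_tablet",
                dose=d["dose_mg"],
                formulation=WeibullFormulation(shape=values["shape"], t50=values["t50"]),
            )

        spec = FitSpec(
            free_parameters=(
                FitParameter("shape", 0.05, 3.0),
                FitParameter("t50", 10.0, 8000.0),
            ),
            n_starts=n_starts,
            seed=seed + 3,
        )
        results["tablet"] = fit(plasma_predict(reg_tablet, t_obs, d["t_end"]), c_obs, spec)
    else:
        warnings.warn("stage 'tablet' skipped: no data")
        results["tablet"] = None

    results["final_compound"] = cp
    return results
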