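"""Synthetic "observed" clinical datasets and parameter recovery.

Real qualification datasets for this network are digitized mean(±SD)
concentration–time profiles from published trials plus sponsor data. This
module generates stand-ins with the same statistical structure — sparse
sampling schedules (typically 6–16 timepoints), multiplicative
(log-normal) residual error, optional log-normal inter-individual
variability, and lower-limit-of-quantification censoring — so the
end-to-end analysis and middle-out parameter estimation can be exercised
without any external data. Every dataset is reproducible from its seed and
carries the true generating parameters as metadata for recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy.optimize import least_squares

from .engine import DosingRegimen, SimulationResult, assemble, simulate
from .metrics import DDIRatios
from .network import DrugLibrary, TrialSpec, _prepare_individual, \
    _resolve_drugs, _victim_plasma
from .params import SimContext, get_parameter, set_parameter

__all__ = [
    "NoiseModel", "ObservedDataset", "generate_observed",
    "synthetic_observed_ratios", "generate_noncompliance_caffeine",
    "FitModel", "FitResult", "fit_parameters", "trial_fit_model",
]


class NoiseModel(BaseModel):
    """Residual and between-subject variability of a synthetic dataset."""

    model_config = ConfigDict(frozen=True)

    proportional_cv: float = 0.2     # multiplicative residual CV
    lloq: float = 0.0                # µM assay floor; values below are BLQ
    iiv_cvs: dict[str, float] = {}   # parameter handle -> log-normal CV
    seed: int = 0

    def sigma(self) -> float:
        # log-normal σ giving exactly this CV
        return float(np.sqrt(np.log1p(self.proportional_cv ** 2)))


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv ** 2)))


@dataclass
class ObservedDataset:
    """Long-format synthetic observations plus generating metadata."""

    data: pd.DataFrame  # study, arm, subject, time, concentration, blq
    true_parameters: dict
    noise: NoiseModel
    schedule: tuple[float, ...] = ()

    def to_csv(self, path: str | Path) -> None:
        """Write the observation table; a sidecar ``<path>.truth.json``
        records the true generating parameters for recovery scoring."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        with open(path.with_suffix(path.suffix + ".truth.json"), "w") as fh:
            json.dump({"true_parameters": self.true_parameters,
                       "noise": self.noise.model_dump()}, fh, indent=1)

    def csv_bytes(self) -> bytes:
        return self.data.to_csv(index=False).encode()


def generate_observed(sim: SimulationResult, schedule: Sequence[float],
                      noise: NoiseModel, n_subjects: int,
                      drug: Optional[str] = None,
                      resimulate: Optional[Callable[[Mapping[str, float]],
                                                    SimulationResult]] = None,
                      study: str = "study-1", arm: str = "arm-1",
                      true_parameters: Optional[dict] = None
                      ) -> ObservedDataset:
    """Sparse noisy observations of a simulated plasma profile.

    Per subject, inter-individual parameter variability is realized either
    by rerunning the model through ``resimulate`` (called with log-normal
    multiplicative factors per handle in ``noise.iiv_cvs``) or — without a
    resimulator — as a single log-normal amplitude on the profile whose
    variance pools the declared CVs (a scaling approximation). Multiplicative
    residual error is then applied per sample and values below the LLOQ are
    reported at the floor with a BLQ flag. Reproducible from ``noise.seed``.
    """
    schedule = np.asarray(sorted(schedule), dtype=float)
    if schedule[0] < sim.time[0] or schedule[-1] > sim.time[-1]:
        raise ValueError("sampling schedule outside simulation span")
    drug = drug or sim.system.meta["drugs"][0]
    base = np.interp(schedule, sim.time, sim.plasma(drug))
    rng = np.random.default_rng(noise.seed)
    sigma_res = noise.sigma()
    rows = []
    for subj in range(1, n_subjects + 1):
        profile = base
        if noise.iiv_cvs:
            factors = {h: float(rng.lognormal(0.0, _lognormal_sigma(cv)))
                       for h, cv in sorted(noise.iiv_cvs.items())}
            if resimulate is not None:
                res = resimulate(factors)
                profile = np.interp(schedule, res.time, res.plasma(drug))
            else:
                pooled = float(np.sqrt(sum(
                    _lognormal_sigma(cv) ** 2 for cv in noise.iiv_cvs.values())))
                profile = base * rng.lognormal(0.0, pooled)
        eps = rng.lognormal(0.0, sigma_res, size=len(schedule)) \
            if sigma_res > 0 else np.ones(len(schedule))
        conc = profile * eps
        blq = conc < noise.lloq
        conc = np.where(blq, noise.lloq, conc)
        for t, c, b in zip(schedule, conc, blq):
            rows.append({"study": study, "arm": arm, "subject": subj,
                         "time": t, "concentration": float(c),
                         "blq": bool(b)})
    data = pd.DataFrame(rows)
    return ObservedDataset(data=data, true_parameters=true_parameters or {},
                           noise=noise, schedule=tuple(schedule))


def synthetic_observed_ratios(predicted: Mapping[str, DDIRatios], cv: float,
                              seed: int) -> dict[str, tuple[float, float]]:
    """Observed DDI ratio table emulated as predicted ratios under
    log-normal study-level noise (one draw per pair per endpoint)."""
    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(cv)
    out = {}
    for name in sorted(predicted):
        r = predicted[name]
        out[name] = (r.auc_ratio * float(rng.lognormal(0.0, sigma)),
                     r.cmax_ratio * float(rng.lognormal(0.0, sigma)))
    return out


def generate_noncompliance_caffeine(
        spec: TrialSpec, library: DrugLibrary, baseline_intake: float,
        schedule: Sequence[float], noise: NoiseModel, n_subjects: int = 1
        ) -> ObservedDataset:
    """Dietary non-compliance scenario: a constant background intake of the
    victim drug (µmol/min, e.g. caffeine-containing beverages) runs over the
    whole trial, so pre-dose samples show a nonzero trough.

    The victim must be flagged ``dietary``. Returns observations of the
    victim-alone arm with the background input; the true intake rate is in
    the dataset metadata for recovery experiments.
    """
    victim = library.get(spec.victim_drugs[0])
    if not victim.dietary:
        raise ValueError(f"{victim.name!r} is not flagged dietary")
    drugs, regimens = _resolve_drugs(spec, library, with_perp=False)
    if baseline_intake < 0:
        raise ValueError("baseline_intake must be >= 0")
    if baseline_intake > 0:
        regimens = list(regimens) + [DosingRegimen(
            drug=victim.name, route="iv_infusion",
            dose=baseline_intake * spec.t_end, times=[0.0],
            infusion_duration=spec.t_end)]
    ind = _prepare_individual(spec, None)
    grid = np.linspace(0.0, spec.t_end, spec.n_grid)
    sim = simulate(assemble(ind, drugs, regimens), spec.t_end, grid,
                   spec.solver)
    return generate_observed(
        sim, schedule, noise, n_subjects, drug=victim.name,
        true_parameters={"background_rate_umol_min": baseline_intake})


# --------------------------------------------------------------------------
# least-squares parameter estimation (middle-out fitting)

N_MULTISTARTS = 3


@dataclass
class FitModel:
    """Prediction function plus free-parameter bounds for estimation.

    ``predict`` maps absolute parameter values (handle → value) to model
    concentrations aligned with the observation rows.
    """

    predict: Callable[[Mapping[str, float]], np.ndarray]
    bounds: dict[str, tuple[float, float]]
    starts: Optional[list[dict[str, float]]] = None


@dataclass
class FitResult:
    estimates: dict[str, float]
    stderr: dict[str, float]
    correlation: pd.DataFrame
    cost: float
    n_obs: int
    success: bool
    non_identifiable: bool
    multistart_costs: list[float] = field(default_factory=list)


def fit_parameters(observed: ObservedDataset, model: FitModel) -> FitResult:
    """Bounded least squares on log concentrations (BLQ rows excluded).

    Parameters are estimated on the log scale (all bounds must be positive
    and finite), which conditions the problem across decades and yields
    multiplicative standard errors. Three geometric multi-starts across the
    bound interval are used; ties are resolved by lowest objective, then by
    start order. Approximate standard errors and the pairwise correlation
    matrix come from the Jacobian at the optimum; a near-singular Jacobian
    flags non-identifiability and correlations are reported as NA.
    """
    names = sorted(model.bounds)
    if not names:
        raise ValueError("need at least one free parameter")
    for p, (lo, hi) in model.bounds.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
            raise ValueError(f"bounds for {p!r} must be finite and positive")
    keep = ~observed.data["blq"].to_numpy()
    obs = observed.data.loc[keep, "concentration"].to_numpy(dtype=float)
    if (obs <= 0).any():
        raise ValueError("non-BLQ observations must be positive")
    log_obs = np.log(obs)
    n_obs = len(obs)
    floor = 1e-12

    def residuals(x: np.ndarray) -> np.ndarray:
        params = {p: float(np.exp(v)) for p, v in zip(names, x)}
        pred = np.asarray(model.predict(params), dtype=float)[keep]
        return np.log(np.maximum(pred, floor)) - log_obs

    lo = np.array([np.log(model.bounds[p][0]) for p in names])
    hi = np.array([np.log(model.bounds[p][1]) for p in names])
    if model.starts:
        starts = [np.array([np.log(s[p]) for p in names])
                  for s in model.starts]
    else:
        starts = [lo + q * (hi - lo)
                  for q in np.linspace(0.25, 0.75, N_MULTISTARTS)]

    best = None
    costs = []
    for x0 in starts:
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            diff_step=1e-4)
        costs.append(float(sol.cost))
        if best is None or sol.cost < best.cost - 1e-14:
            best = sol

    estimates = {p: float(np.exp(v)) for p, v in zip(names, best.x)}
    jac = best.jac
    jtj = jac.T @ jac
    non_identifiable = (np.linalg.matrix_rank(jtj) < len(names)
                        or np.linalg.cond(jtj) > 1e8)
    stderr = {p: float("nan") for p in names}
    corr = pd.DataFrame(np.full((len(names), len(names)), np.nan),
                        index=names, columns=names)
    if not non_identifiable and n_obs > len(names):
        sigma2 = 2.0 * best.cost / (n_obs - len(names))
        cov = np.linalg.inv(jtj) * sigma2
        sd = np.sqrt(np.diag(cov))
        stderr = {p: float(s) for p, s in zip(names, sd)}  # SE of log-param
        with np.errstate(invalid="ignore"):
            corr = pd.DataFrame(cov / np.outer(sd, sd),
                                index=names, columns=names)
    elif non_identifiable and len(names) >= 2:
        # report the raw (unscaled) correlation structure where computable
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt(np.diag(jtj))
            raw = jtj / np.outer(d, d)
        corr = pd.DataFrame(raw, index=names, columns=names)
    return FitResult(estimates=estimates, stderr=stderr, correlation=corr,
                     cost=float(best.cost), n_obs=n_obs,
                     success=bool(best.success),
                     non_identifiable=bool(non_identifiable),
                     multistart_costs=costs)


def trial_fit_model(spec: TrialSpec, library: DrugLibrary,
                    observed: ObservedDataset,
                    free_parameters: dict[str, tuple[float, float]],
                    arm: str = "combo",
                    extra_regimens: Optional[Sequence[DosingRegimen]] = None,
                    background_rate_handle: Optional[str] = None
                    ) -> FitModel:
    """Fit model predicting victim plasma concentrations at the observation
    times of one trial arm.

    ``background_rate_handle`` (if given, e.g. ``"background_rate"``) adds a
    constant victim intake as an estimable input, for the dietary
    non-compliance use case; its bounds must appear in ``free_parameters``.
    """
    with_perp = arm == "combo" and bool(spec.perpetrator)
    drugs, regimens = _resolve_drugs(spec, library, with_perp=with_perp)
    if extra_regimens:
        regimens = list(regimens) + list(extra_regimens)
    ind = _prepare_individual(spec, None)
    base_ctx = SimContext(drugs=tuple(drugs), individual=ind,
                          regimens=tuple(regimens))
    times = observed.data["time"].to_numpy(dtype=float)
    grid = np.linspace(0.0, spec.t_end, spec.n_grid)
    victim = spec.victim_drugs[0]

    def predict(params: Mapping[str, float]) -> np.ndarray:
        ctx = base_ctx
        regs = list(ctx.regimens)
        for handle, value in params.items():
            if handle == background_rate_handle:
                regs = [r for r in regs if r.route != "iv_infusion"
                        or r.drug != victim]
                if value > 0:
                    regs.append(DosingRegimen(
                        drug=victim, route="iv_infusion",
                        dose=value * spec.t_end, times=[0.0],
                        infusion_duration=spec.t_end))
            else:
                ctx = set_parameter(ctx, handle, value)
        res = simulate(assemble(ctx.individual, ctx.drugs, regs),
                       spec.t_end, grid, spec.solver)
        profile = _victim_plasma(res, spec)
        return np.interp(times, res.time, profile)

    # sanity: non-background handles must resolve on the baseline context
    for handle in free_parameters:
        if handle != background_rate_handle:
            get_parameter(base_ctx, handle)
    return FitModel(predict=predict, bounds=dict(free_parameters))
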