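"""Trial simulation and qualification of the CYP1A2/CYP2C19 DDI network.

A :class:`TrialSpec` declares a victim drug (one or two components — racemic
omeprazole is its two enantiomers co-dosed at half dose each), an optional
perpetrator, the phenotype arm (enzyme → activity multiplier), the sampling
grid and the endpoint interval. :func:`run_trial` simulates the victim alone
and with the perpetrator on the same individual and returns the AUC/Cmax
exposure ratios; :func:`qualify_network` sweeps the eleven perpetrator–victim
pairs of the network and compares predictions against observed ratios with
the 2-fold acceptance band; :func:`compare_mechanisms` ranks competing
inhibition hypotheses (e.g. competitive-only vs competitive plus
time-dependent inactivation, or alternative k_inact values) by goodness of
fit to an observed AUC ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .drugs import Drug, Inhibition, ki_for_pair, load_builtin_drug, \
    builtin_drug_names
from .engine import DosingRegimen, SimulationResult, SolverSettings, \
    assemble, simulate
from .metrics import DDIRatios, PKMetrics, PredObsComparison, \
    compute_metrics, ddi_ratios, pred_obs_ratio
from .params import SimContext, get_parameter, list_parameters, set_parameter
from .physiology import Individual, Phenotype, apply_phenotype, \
    default_individual, scale_gut_expression
from .sensitivity import SimulationTask

__all__ = [
    "TrialSpec", "TrialResult", "QualificationReport", "DrugLibrary",
    "run_trial", "qualify_network", "compare_mechanisms",
    "default_qualification_network", "load_trial_spec",
    "trial_sensitivity_task", "TRIAL_SOLVER",
]

#: solver accuracy used for network trials; tighter than needed for 2-fold
#: qualification decisions while keeping the 22-arm sweep fast
TRIAL_SOLVER = SolverSettings(rtol=1e-6, atol=1e-9)


class DrugLibrary:
    """Named collection of drug models resolvable by trial specs."""

    def __init__(self, drugs: Sequence[Drug] = ()):
        self._drugs = {d.name: d for d in drugs}

    @classmethod
    def builtin(cls) -> "DrugLibrary":
        return cls([load_builtin_drug(n) for n in builtin_drug_names()])

    def get(self, name: str) -> Drug:
        if name not in self._drugs:
            raise KeyError(f"drug {name!r} not in library; "
                           f"available: {sorted(self._drugs)}")
        return self._drugs[name]

    def add(self, drug: Drug) -> None:
        self._drugs[drug.name] = drug

    def names(self) -> list[str]:
        return sorted(self._drugs)


class TrialSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    victim: list[DosingRegimen]
    perpetrator: list[DosingRegimen] = []
    phenotypes: dict[str, float] = {}
    gut_expression_scale: dict[str, float] = {}
    t_end: float
    n_grid: int = 1441
    #: (t0, t1) interval AUC for multiple-dose designs; None = AUC(0→∞)
    #: with log-linear terminal extrapolation, per the study design
    endpoint_interval: Optional[tuple[float, float]] = None
    #: interaction-constant-library substrate key; perpetrator inhibition
    #: entries for (perpetrator, this key) override the drug-file defaults
    victim_substrate: Optional[str] = None
    use_pair_ki: bool = True
    category: Optional[str] = None
    solver: SolverSettings = TRIAL_SOLVER

    @model_validator(mode="after")
    def _valid(self) -> "TrialSpec":
        if not self.victim:
            raise ValueError("trial needs at least one victim regimen")
        if self.endpoint_interval is not None:
            t0, t1 = self.endpoint_interval
            if not (0 <= t0 < t1 <= self.t_end):
                raise ValueError("endpoint interval must lie within the "
                                 "sampled span")
        last_dose = max(t for r in self.victim + self.perpetrator
                        for t in r.times)
        if last_dose > self.t_end:
            raise ValueError("t_end must cover all dose events")
        return self

    @property
    def victim_drugs(self) -> list[str]:
        seen = []
        for r in self.victim:
            if r.drug not in seen:
                seen.append(r.drug)
        return seen

    @property
    def perpetrator_drugs(self) -> list[str]:
        seen = []
        for r in self.perpetrator:
            if r.drug not in seen:
                seen.append(r.drug)
        return seen

    def substrate_key(self) -> str:
        return self.victim_substrate or self.victim_drugs[0]


@dataclass
class TrialResult:
    spec: TrialSpec
    alone: SimulationResult
    combo: Optional[SimulationResult]
    metrics_alone: PKMetrics
    metrics_combo: PKMetrics
    ratios: DDIRatios

    def victim_profile(self, which: str = "combo") -> np.ndarray:
        res = self.combo if which == "combo" and self.combo is not None \
            else self.alone
        return _victim_plasma(res, self.spec)


def _victim_plasma(result: SimulationResult, spec: TrialSpec) -> np.ndarray:
    total = np.zeros_like(result.time)
    for name in spec.victim_drugs:
        total = total + result.plasma(name)
    return total


def _prepare_individual(spec: TrialSpec,
                        individual: Optional[Individual]) -> Individual:
    ind = individual or default_individual()
    for enzyme, mult in spec.phenotypes.items():
        ind = apply_phenotype(ind, Phenotype(enzyme=enzyme,
                                             activity_multiplier=mult))
    for enzyme, factor in spec.gut_expression_scale.items():
        ind = scale_gut_expression(ind, enzyme, factor)
    return ind


def _override_pair_ki(perp: Drug, substrate: str) -> Drug:
    """Replace the perpetrator's inhibition constants with the network
    library entries for this perpetrator→victim pair, where available."""
    entries = ki_for_pair(perp.name, substrate)
    if not entries:
        return perp
    keep = [inh for inh in perp.inhibitions
            if not any(e.target_enzyme == inh.target_enzyme
                       and e.mechanism == inh.mechanism for e in entries)]
    return perp.with_inhibitions(keep + entries)


def _resolve_drugs(spec: TrialSpec, library: DrugLibrary,
                   with_perp: bool) -> tuple[list[Drug], list[DosingRegimen]]:
    drugs = [library.get(n) for n in spec.victim_drugs]
    regimens = list(spec.victim)
    if with_perp and spec.perpetrator:
        for name in spec.perpetrator_drugs:
            perp = library.get(name)
            if spec.use_pair_ki:
                perp = _override_pair_ki(perp, spec.substrate_key())
            drugs.append(perp)
        regimens += list(spec.perpetrator)
    return drugs, regimens


def _victim_metrics(result: SimulationResult, spec: TrialSpec) -> PKMetrics:
    profile = _victim_plasma(result, spec)
    if spec.endpoint_interval is not None:
        return compute_metrics(result.time, profile,
                               interval=spec.endpoint_interval)
    return compute_metrics(result.time, profile, extrapolate=True)


def run_trial(spec: TrialSpec, library: DrugLibrary,
              individual: Optional[Individual] = None) -> TrialResult:
    """Simulate victim-alone and victim-plus-perpetrator arms.

    Both arms share the same individual (phenotype multipliers applied), so
    the exposure ratios isolate the interaction. Deterministic given the
    spec and library.
    """
    ind = _prepare_individual(spec, individual)
    grid = np.linspace(0.0, spec.t_end, spec.n_grid)

    drugs_a, regs_a = _resolve_drugs(spec, library, with_perp=False)
    alone = simulate(assemble(ind, drugs_a, regs_a), spec.t_end, grid,
                     spec.solver)
    m_alone = _victim_metrics(alone, spec)

    if spec.perpetrator:
        drugs_b, regs_b = _resolve_drugs(spec, library, with_perp=True)
        victim_enzymes = {p.enzyme for n in spec.victim_drugs
                          for p in library.get(n).pathways}
        perp_targets = {inh.target_enzyme
                        for d in drugs_b[len(spec.victim_drugs):]
                        for inh in d.inhibitions}
        if not victim_enzymes & perp_targets:
            warnings.warn(
                f"{spec.name}: perpetrator inhibits none of the victim's "
                f"pathways; exposure ratio will be 1", RuntimeWarning,
                stacklevel=2)
        combo = simulate(assemble(ind, drugs_b, regs_b), spec.t_end, grid,
                         spec.solver)
        m_combo = _victim_metrics(combo, spec)
    else:
        combo, m_combo = None, m_alone

    return TrialResult(spec=spec, alone=alone, combo=combo,
                       metrics_alone=m_alone, metrics_combo=m_combo,
                       ratios=ddi_ratios(m_alone, m_combo))


# --------------------------------------------------------------------------
# network qualification

@dataclass
class QualificationReport:
    frame: pd.DataFrame
    results: dict[str, TrialResult]
    overall_pass: bool

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _as_ratios(value) -> DDIRatios:
    if isinstance(value, DDIRatios):
        return value
    auc_r, cmax_r = value
    return DDIRatios(auc_ratio=float(auc_r), cmax_ratio=float(cmax_r))


def qualify_network(specs: Sequence[TrialSpec],
                    observed: Optional[Mapping[str, object]] = None,
                    library: Optional[DrugLibrary] = None,
                    individual: Optional[Individual] = None
                    ) -> QualificationReport:
    """Run every trial and compare predicted vs observed exposure ratios.

    ``observed`` maps trial names to observed (AUC_R, Cmax_R); pairs without
    an observed entry are reported as prediction-only. Overall pass requires
    every compared pair within 2-fold on both endpoints.
    """
    library = library or DrugLibrary.builtin()
    observed = observed or {}
    rows = []
    results: dict[str, TrialResult] = {}
    all_pass = True
    for spec in specs:
        res = run_trial(spec, library, individual)
        results[spec.name] = res
        row = {
            "pair": spec.name,
            "category": spec.category,
            "pred_auc_r": res.ratios.auc_ratio,
            "pred_cmax_r": res.ratios.cmax_ratio,
            "obs_auc_r": np.nan, "obs_cmax_r": np.nan,
            "pred_obs_auc": np.nan, "pred_obs_cmax": np.nan,
            "within_twofold": np.nan, "status": "prediction-only",
        }
        if spec.name in observed:
            obs = _as_ratios(observed[spec.name])
            cmp_: PredObsComparison = pred_obs_ratio(res.ratios, obs)
            row.update(obs_auc_r=obs.auc_ratio, obs_cmax_r=obs.cmax_ratio,
                       pred_obs_auc=cmp_.auc_ratio,
                       pred_obs_cmax=cmp_.cmax_ratio,
                       within_twofold=cmp_.within_twofold, status="compared")
            all_pass = all_pass and cmp_.within_twofold
        rows.append(row)
    frame = pd.DataFrame(rows)
    return QualificationReport(frame=frame, results=results,
                               overall_pass=bool(all_pass))


def compare_mechanisms(spec: TrialSpec,
                       variants: Sequence[tuple[str, list[Inhibition]]],
                       observed_auc_r: float,
                       library: Optional[DrugLibrary] = None,
                       individual: Optional[Individual] = None
                       ) -> pd.DataFrame:
    """Rank competing perpetrator inhibition hypotheses by fit.

    Each variant replaces the perpetrator's inhibition entries, the trial is
    rerun, and variants are ranked by |log(predicted/observed AUC ratio)|
    ascending. Ties keep the input order (stable sort), and every variant is
    reported so alternatives stay visible.
    """
    if len(variants) < 2:
        raise ValueError("need at least 2 mechanism variants")
    if not spec.perpetrator:
        raise ValueError("mechanism comparison needs a perpetrator")
    library = library or DrugLibrary.builtin()
    perp_name = spec.perpetrator_drugs[0]
    base = spec.model_copy(update={"use_pair_ki": False})
    rows = []
    for label, inhibitions in variants:
        lib = DrugLibrary([library.get(n) for n in library.names()])
        lib.add(library.get(perp_name).with_inhibitions(inhibitions))
        res = run_trial(base, lib, individual)
        pred = res.ratios.auc_ratio
        rows.append({"variant": label, "pred_auc_r": pred,
                     "pred_cmax_r": res.ratios.cmax_ratio,
                     "obs_auc_r": observed_auc_r,
                     "fit_metric": abs(np.log(pred / observed_auc_r))})
    frame = pd.DataFrame(rows).sort_values("fit_metric", kind="mergesort")
    frame["rank"] = range(1, len(frame) + 1)
    return frame.reset_index(drop=True)


# --------------------------------------------------------------------------
# the eleven qualification pairs

_DAY = 1440.0


def _times(start: float, interval: float, until: float) -> list[float]:
    return [float(t) for t in np.arange(start, until, interval)]


def default_qualification_network() -> list[TrialSpec]:
    """The eleven perpetrator–victim pairs of the qualification network:
    2 strong CYP2C19, 3 strong CYP1A2, 2 moderate CYP2C19 and 4 moderate
    CYP1A2 inhibition studies. Perpetrators are dosed to steady state from
    time zero; the single-dose victim is given on day 2 and its exposure is
    read over the following 24 h."""
    t_v = 2 * _DAY
    t_end = 3 * _DAY
    interval = (t_v, t_end)

    def oral(drug, dose, times):
        return DosingRegimen(drug=drug, route="oral", dose=dose, times=times)

    fluvox = [oral("fluvoxamine", "50 mg", _times(0, 720, t_end))]
    omep_perp = [oral("esomeprazole", "20 mg", _times(0, _DAY, t_end)),
                 oral("r_omeprazole", "20 mg", _times(0, _DAY, t_end))]
    moclo_perp = [oral("moclobemide", "300 mg", _times(0, 720, t_end))]
    mexi_perp = [oral("mexiletine", "200 mg", _times(0, 480, t_end))]
    ee_perp = [oral("ethinylestradiol", "0.03 mg", _times(0, _DAY, t_end))]

    omep_victim = [oral("esomeprazole", "20 mg", [t_v]),
                   oral("r_omeprazole", "20 mg", [t_v])]

    def spec(name, category, victim, perpetrator, substrate):
        return TrialSpec(name=name, category=category, victim=victim,
                         perpetrator=perpetrator, t_end=t_end,
                         endpoint_interval=interval,
                         victim_substrate=substrate)

    return [
        spec("fluvoxamine-omeprazole (EM)", "strong CYP2C19",
             omep_victim, fluvox, "omeprazole"),
        spec("fluvoxamine-s_mephenytoin", "strong CYP2C19",
             [oral("s_mephenytoin", "100 mg", [t_v])], fluvox,
             "s_mephenytoin"),
        spec("fluvoxamine-caffeine", "strong CYP1A2",
             [oral("caffeine", "150 mg", [t_v])], fluvox, "caffeine"),
        spec("fluvoxamine-tizanidine", "strong CYP1A2",
             [oral("tizanidine", "4 mg", [t_v])], fluvox, "tizanidine"),
        spec("fluvoxamine-mexiletine", "strong CYP1A2",
             [oral("mexiletine", "200 mg", [t_v])], fluvox, "mexiletine"),
        spec("omeprazole-moclobemide", "moderate CYP2C19",
             [oral("moclobemide", "300 mg", [t_v])], omep_perp,
             "moclobemide"),
        spec("moclobemide-omeprazole", "moderate CYP2C19",
             omep_victim, moclo_perp, "omeprazole"),
        spec("mexiletine-caffeine", "moderate CYP1A2",
             [oral("caffeine", "150 mg", [t_v])], mexi_perp, "caffeine"),
        spec("mexiletine-tizanidine", "moderate CYP1A2",
             [oral("tizanidine", "4 mg", [t_v])], mexi_perp, "tizanidine"),
        spec("ethinylestradiol-caffeine", "moderate CYP1A2",
             [oral("caffeine", "150 mg", [t_v])], ee_perp, "caffeine"),
        spec("ethinylestradiol-tizanidine", "moderate CYP1A2",
             [oral("tizanidine", "4 mg", [t_v])], ee_perp, "tizanidine"),
    ]


# --------------------------------------------------------------------------
# sensitivity bridge and trial-spec files

def trial_sensitivity_task(spec: TrialSpec, library: DrugLibrary,
                           parameters: Optional[Sequence[str]] = None,
                           individual: Optional[Individual] = None,
                           arm: str = "combo") -> SimulationTask:
    """Sensitivity task over the victim's AUC and Cmax in one trial arm.

    ``arm`` is ``"combo"`` (victim with perpetrator, the default when a
    perpetrator is declared) or ``"alone"``.
    """
    with_perp = arm == "combo" and bool(spec.perpetrator)
    drugs, regimens = _resolve_drugs(spec, library, with_perp=with_perp)
    ind = _prepare_individual(spec, individual)
    base_ctx = SimContext(drugs=tuple(drugs), individual=ind,
                          regimens=tuple(regimens))
    handles = list(parameters) if parameters is not None \
        else list_parameters(base_ctx)
    baseline = {h: get_parameter(base_ctx, h) for h in handles}
    grid = np.linspace(0.0, spec.t_end, spec.n_grid)

    def evaluate(overrides: dict[str, float]) -> dict[str, float]:
        ctx = base_ctx
        for handle, value in overrides.items():
            ctx = set_parameter(ctx, handle, value)
        res = simulate(assemble(ctx.individual, ctx.drugs, ctx.regimens),
                       spec.t_end, grid, spec.solver)
        m = _victim_metrics(res, spec)
        return {"AUC": m.auc, "Cmax": m.cmax}

    return SimulationTask(evaluate=evaluate, baseline_parameters=baseline)


def load_trial_spec(path: str | Path) -> TrialSpec:
    """Read a trial specification from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: trial spec must be a mapping")
    if "endpoint_interval" in doc and doc["endpoint_interval"] is not None:
        doc["endpoint_interval"] = tuple(doc["endpoint_interval"])
    return TrialSpec(**doc)
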