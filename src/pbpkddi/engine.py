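"""Whole-body PBPK ODE assembly and integration.

The model is flow-limited (perfusion-limited): each organ is a well-stirred
compartment and the blood concentration leaving an organ is
``C_tissue · B:P / Kp``. Per drug and organ the mass balance is

    dA/dt = Q · (C_in − C_tissue · B:P / Kp)

with the lung between venous and arterial blood and the liver fed by the
hepatic artery plus portal drainage from gut wall and spleen. Metabolism is
driven by the unbound (plasma-referenced) tissue concentration
``C_u = fu · C_tissue / Kp`` in every organ expressing the pathway enzyme:

    linear      rate = CLint · E_active · C_u / (1 + Σ I_u/Ki)
    saturable   rate = Vmax · E_active · C_u / (Km·(1 + Σ I_u/Ki) + C_u)
    unspecific  rate = CL_apparent · C_u          (liver only, uninhibitable)

Competitive inhibitors contribute ``I_u/Ki`` terms from their local unbound
concentration. Time-dependent (mechanism-based) inactivation adds a dynamic
active-enzyme state per (enzyme, expressing organ), shared by all co-dosed
drugs, with turnover

    dE/dt = kdeg · (E0 − E) − E · Σ k_inact · I_u / (KI + I_u)

so autoinhibition and cross-inhibition interact through one enzyme pool.

Oral dosing enters a gut-lumen state (optionally behind a Weibull release)
and is absorbed into the gut wall with first-order rate ka; the fraction
1 − f_abs is never absorbed. All simulations carry per-drug cumulative
metabolized/unabsorbed bookkeeping states so mass balance is checkable.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.integrate import solve_ivp

from .drugs import Drug, Pathway
from .physiology import BLOOD_COMPARTMENTS, Individual
from .units import UnitError, parse_quantity

__all__ = [
    "DosingRegimen", "SolverSettings", "ODESystem", "SimulationResult",
    "SolverError", "assemble", "simulate", "metabolic_rate",
    "enzyme_turnover_rate", "one_compartment_system", "DEFAULT_KDEG",
]

#: Default enzyme degradation rate constants (1/min), i.e. ln2 / turnover
#: half-life; documented package constants, overridable per simulation.
DEFAULT_KDEG = {
    "CYP3A4": 3.2e-4,   # t1/2 ~ 36 h
    "CYP1A2": 3.0e-4,   # t1/2 ~ 39 h
    "CYP2C19": 4.4e-4,  # t1/2 ~ 26 h
    "CYP2D6": 2.3e-4,   # t1/2 ~ 51 h
    "CYP2C9": 1.1e-4,   # t1/2 ~ 104 h
    "UGT1A1": 2.4e-4,   # t1/2 ~ 48 h
}


class SolverError(RuntimeError):
    """Integration failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_good_time: float):
        super().__init__(f"{message} (last good time: {last_good_time} min)")
        self.last_good_time = last_good_time


class DosingRegimen(BaseModel):
    """Administrations of one drug: route, dose and times.

    ``dose`` may be a number (µmol) or a string with units — amounts
    ("150 umol") or masses ("40 mg", converted via the drug's molecular
    weight). A zero dose is allowed and denotes a placebo arm.
    """

    model_config = ConfigDict(frozen=True)

    drug: str
    route: Literal["iv_bolus", "iv_infusion", "oral"]
    dose: float | str
    times: list[float] = [0.0]
    infusion_duration: Optional[float] = None  # min

    @model_validator(mode="after")
    def _valid(self) -> "DosingRegimen":
        if isinstance(self.dose, (int, float)) and self.dose < 0:
            raise ValueError("dose must be >= 0")
        if any(t < 0 for t in self.times):
            raise ValueError("administration times must be >= 0")
        if sorted(self.times) != list(self.times):
            raise ValueError("administration times must be sorted")
        if self.route == "iv_infusion":
            if not self.infusion_duration or self.infusion_duration <= 0:
                raise ValueError("iv_infusion requires infusion_duration > 0")
        return self

    def dose_umol(self, drug: Drug) -> float:
        raw = self.dose
        if isinstance(raw, (int, float)):
            return float(raw)
        try:
            return parse_quantity(raw, "amount")
        except UnitError:
            pass
        mg = parse_quantity(raw, "mass")
        return drug.dose_to_umol(mg)


class SolverSettings(BaseModel):
    model_config = ConfigDict(frozen=True)

    method: str = "LSODA"   # stiff-capable
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: Optional[float] = None


# --------------------------------------------------------------------------
# kinetic rate laws (exposed for direct use and unit testing)

def metabolic_rate(pw: Pathway, c_unbound: float, enzyme_active: float,
                   inhibitor_terms: Sequence[tuple[float, float]] = ()) -> float:
    """Metabolic rate (µmol/min) of one pathway at local conditions.

    ``inhibitor_terms`` is a sequence of (unbound inhibitor concentration µM,
    Ki µM) pairs of competitive inhibitors sharing the enzyme. The unspecific
    hepatic route is insensitive to inhibitors.
    """
    if c_unbound < 0:
        raise ValueError(f"negative unbound concentration {c_unbound}")
    if pw.kinetics == "unspecific_hepatic":
        return pw.cl_apparent * c_unbound
    comp = 1.0 + sum(i / ki for i, ki in inhibitor_terms)
    if pw.kinetics == "linear":
        return pw.cl_int * enzyme_active * c_unbound / comp
    return (pw.vmax * enzyme_active * c_unbound
            / (pw.km * comp + c_unbound))


def enzyme_turnover_rate(
        E: float, E0: float, kdeg: float,
        tdi_terms: Sequence[tuple[float, float, float]] = ()) -> float:
    """dE/dt (µmol/min) for an enzyme pool under synthesis/degradation
    turnover and mechanism-based inactivation.

    ``tdi_terms`` is a sequence of (unbound inhibitor µM, k_inact 1/min,
    KI µM). With no inhibitor the steady state is E0.
    """
    if E < 0 or E0 < 0 or kdeg < 0:
        raise ValueError("negative enzyme state or rate constant")
    inact = sum(k_inact * iu / (k_i + iu) for iu, k_inact, k_i in tdi_terms)
    return kdeg * (E0 - E) - E * inact


# --------------------------------------------------------------------------
# generic ODE system + simulation driver

@dataclass(frozen=True)
class DoseEvent:
    time: float
    state_index: int
    amount: float  # µmol


@dataclass(frozen=True)
class Infusion:
    state_index: int
    rate: float  # µmol/min
    start: float
    end: float


@dataclass
class ODESystem:
    """Assembled state equations with dosing events and named outputs."""

    n_states: int
    y0: np.ndarray
    rhs: Callable[[float, np.ndarray], np.ndarray]
    events: list[DoseEvent]
    infusions: list[Infusion]
    state_labels: list[str]
    #: output name -> callable(states matrix [n_t, n_states]) -> array
    outputs: dict[str, Callable[[np.ndarray], np.ndarray]]
    #: label -> (total_in_system(y), administered(t)) for mass-balance checks
    balances: dict[str, tuple[Callable[[np.ndarray], float],
                              Callable[[float], float]]]
    meta: dict = field(default_factory=dict)


@dataclass
class SimulationResult:
    """Dense simulation output on a user grid."""

    time: np.ndarray
    states: np.ndarray  # (n_t, n_states)
    system: ODESystem
    diagnostics: dict
    mass_balance_rel_error: float

    def output(self, name: str) -> np.ndarray:
        return self.system.outputs[name](self.states)

    def plasma(self, drug: str) -> np.ndarray:
        """Venous plasma concentration (µM) of a drug."""
        return self.output(f"plasma:{drug}")

    def compartment(self, drug: str, organ: str) -> np.ndarray:
        """Tissue concentration (µM) of a drug in one organ."""
        return self.output(f"conc:{drug}:{organ}")

    def enzyme_fraction(self, enzyme: str, organ: str) -> np.ndarray:
        """Active enzyme as a fraction of baseline expression."""
        return self.output(f"enzyme:{enzyme}:{organ}")

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time, output, value."""
        rows = []
        for name in self.system.outputs:
            vals = self.output(name)
            rows.append(pd.DataFrame(
                {"time": self.time, "output": name, "value": vals}))
        return pd.concat(rows, ignore_index=True)


def simulate(sys: ODESystem, t_end: float,
             output_grid: Optional[Sequence[float]] = None,
             settings: Optional[SolverSettings] = None) -> SimulationResult:
    """Integrate an assembled system with hard restarts at every dose event.

    The integration is split at every instantaneous dose and infusion edge;
    within a segment the forcing is constant, so the stiff solver never steps
    over a discontinuity. States are floored at zero between segments (with a
    warning if the floor exceeds 100·atol). Mass balance over the whole grid
    is reported as the maximum relative error across all balance checks.
    """
    settings = settings or SolverSettings()
    late = [e.time for e in sys.events if e.time > t_end]
    if late:
        raise ValueError(
            f"dose events at {late} min fall after t_end={t_end} min")
    if output_grid is None:
        grid = np.linspace(0.0, t_end, 501)
    else:
        grid = np.asarray(output_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("output_grid must be strictly increasing")
        if grid[0] < 0 or grid[-1] > t_end:
            raise ValueError("output_grid must lie within [0, t_end]")

    breaks = {0.0, float(t_end)}
    breaks.update(e.time for e in sys.events)
    for inf in sys.infusions:
        breaks.add(inf.start)
        if inf.end < t_end:
            breaks.add(inf.end)
    breaks = sorted(b for b in breaks if 0.0 <= b <= t_end)

    events_at: dict[float, list[DoseEvent]] = {}
    for e in sys.events:
        events_at.setdefault(e.time, []).append(e)

    y = np.array(sys.y0, dtype=float, copy=True)
    for e in events_at.get(0.0, []):
        y[e.state_index] += e.amount

    Y = np.empty((len(grid), sys.n_states))
    filled = np.zeros(len(grid), dtype=bool)
    if grid[0] == 0.0:
        Y[0] = y
        filled[0] = True

    nfev = 0
    max_negative = 0.0
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        u = np.zeros(sys.n_states)
        for inf in sys.infusions:
            if inf.start <= t0 and t1 <= inf.end:
                u[inf.state_index] += inf.rate

        def fun(t, yv, _u=u):
            return sys.rhs(t, yv) + _u

        mask = (grid > t0) & (grid <= t1)
        t_eval = np.unique(np.concatenate([grid[mask], [t1]]))
        kwargs = {}
        if settings.max_step:
            kwargs["max_step"] = settings.max_step
        sol = solve_ivp(fun, (t0, t1), y, method=settings.method,
                        rtol=settings.rtol, atol=settings.atol,
                        t_eval=t_eval, **kwargs)
        nfev += sol.nfev
        if not sol.success:
            raise SolverError(f"solver failed in segment [{t0}, {t1}]: "
                              f"{sol.message}", t0)
        for j, tg in enumerate(t_eval):
            g = np.searchsorted(grid, tg)
            if g < len(grid) and grid[g] == tg:
                Y[g] = sol.y[:, j]
                filled[g] = True
        y = sol.y[:, -1].copy()
        max_negative = max(max_negative, float(-y.min()) if y.min() < 0 else 0.0)
        np.maximum(y, 0.0, out=y)
        for e in events_at.get(t1, []):
            y[e.state_index] += e.amount
        # grid points at dose instants report the post-dose state (same
        # convention as t=0), keeping mass balance consistent with the
        # administered-dose step function
        if events_at.get(t1):
            g = np.searchsorted(grid, t1)
            if g < len(grid) and grid[g] == t1:
                Y[g] = y

    if max_negative > 100 * settings.atol:
        warnings.warn(
            f"states floored at 0; largest negative excursion {max_negative:g}",
            RuntimeWarning, stacklevel=2)
    if not filled.all():
        raise RuntimeError("internal error: output grid not fully covered")
    np.maximum(Y, 0.0, out=Y)

    mb_err = 0.0
    for label, (total_fn, admin_fn) in sys.balances.items():
        for ti, yi in zip(grid, Y):
            admin = admin_fn(float(ti))
            if admin <= 0:
                continue
            mb_err = max(mb_err, abs(total_fn(yi) - admin) / admin)

    return SimulationResult(
        time=grid, states=Y, system=sys,
        diagnostics={"nfev": nfev, "segments": len(breaks) - 1,
                     "method": settings.method,
                     "max_negative_excursion": max_negative},
        mass_balance_rel_error=mb_err)


# --------------------------------------------------------------------------
# whole-body assembly

@dataclass
class _Site:
    """One (drug pathway, organ) metabolism site, fully resolved."""
    drug: int
    organ: int
    pathway: Pathway
    e0: float            # static active enzyme (µmol); unused if e_idx >= 0
    e_idx: int           # dynamic enzyme state index, or -1
    ub: float            # unbound factor fu/Kp at this organ
    met_idx: int         # cumulative-metabolized state of the drug
    # competitive terms: (inhibitor drug state index at this organ or -1,
    #                     unbound factor or fixed I_u, ki, inv_volume)
    comp: list[tuple[int, float, float, float]]


@dataclass
class _EnzymeState:
    enzyme: str
    organ: int
    idx: int
    e0: float
    kdeg: float
    # tdi terms: (inhibitor state index or -1, ub-or-fixed-I, k_inact, KI, inv_V)
    tdi: list[tuple[int, float, float, float, float]]


def assemble(ind: Individual, drugs: Sequence[Drug],
             regimens: Sequence[DosingRegimen],
             constant_inhibitors: Optional[dict[str, list[tuple[float, float]]]] = None,
             constant_tdi: Optional[dict[str, list[tuple[float, float, float]]]] = None,
             kdeg: Optional[dict[str, float]] = None,
             inhibitor_unbound_correction: bool = True) -> ODESystem:
    """Assemble the coupled ODE system for co-administered drugs.

    ``constant_inhibitors`` / ``constant_tdi`` clamp an inhibitor at a fixed
    unbound concentration per enzyme (used for analytic verification and
    hypothesis screening): entries are (I_u µM, Ki µM) and
    (I_u µM, k_inact 1/min, KI µM) respectively.

    ``inhibitor_unbound_correction`` controls whether co-dosed inhibitor
    concentrations are corrected for plasma protein binding (I_u = fu·C/Kp,
    the default) or used as total plasma-referenced concentrations (C/Kp).
    """
    drugs = list(drugs)
    regimens = list(regimens)
    names = [d.name for d in drugs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate drug names")
    by_name = {d.name: i for i, d in enumerate(drugs)}
    for reg in regimens:
        if reg.drug not in by_name:
            raise ValueError(f"regimen for unknown drug {reg.drug!r}; "
                             f"supplied: {names}")

    organs = ind.organs
    n_org = len(organs)
    oidx = {o.name: i for i, o in enumerate(organs)}
    i_lung, i_art, i_ven = oidx["lung"], oidx["arterial_blood"], oidx["venous_blood"]
    i_liv, i_gut = oidx["liver"], oidx["gut"]
    portal_idx = [oidx[n] for n in ("gut", "spleen") if n in oidx]
    vols = np.array([o.volume for o in organs])
    inv_vols = 1.0 / vols
    co = ind.cardiac_output
    systemic = [i for i, o in enumerate(organs)
                if o.name not in BLOOD_COMPARTMENTS and o.name != "lung"]
    q = np.array([o.blood_flow for o in organs])
    q_liv_total = q[i_liv] + sum(q[j] for j in portal_idx)
    to_ven = [i for i in systemic if i not in portal_idx and i != i_liv]
    sys_arr = np.array(systemic)
    to_ven_arr = np.array(to_ven)
    q_sys = q[sys_arr]
    q_to_ven = q[to_ven_arr]
    q_portal = np.array([q[j] for j in portal_idx])

    kdeg_map = dict(DEFAULT_KDEG)
    kdeg_map.update(kdeg or {})
    constant_inhibitors = constant_inhibitors or {}
    constant_tdi = constant_tdi or {}

    # --- state layout -----------------------------------------------------
    labels: list[str] = []
    drug_ctx = []
    for d in drugs:
        off = len(labels)
        labels += [f"{d.name}:{o.name}" for o in organs]
        oral_regs = [r for r in regimens
                     if r.drug == d.name and r.route == "oral"]
        has_oral = bool(oral_regs)
        absorption = None
        if has_oral:
            if "oral" not in d.absorption:
                raise ValueError(
                    f"drug {d.name!r} is dosed orally but has no oral "
                    f"absorption block")
            absorption = d.absorption["oral"]
        i_solid = -1
        if absorption is not None and absorption.weibull_scale is not None:
            i_solid = len(labels)
            labels.append(f"{d.name}:lumen_solid")
        i_lumen = -1
        i_unabs = -1
        if has_oral:
            i_lumen = len(labels)
            labels.append(f"{d.name}:lumen")
            i_unabs = len(labels)
            labels.append(f"{d.name}:unabsorbed")
        i_met = len(labels)
        labels.append(f"{d.name}:metabolized")

        # partitioning factors; KeyError -> missing Kp for an organ
        r_out = np.ones(n_org)
        ub = np.zeros(n_org)
        for i, o in enumerate(organs):
            if o.name in BLOOD_COMPARTMENTS:
                continue
            try:
                kp = d.kp_for(o.name)
            except KeyError as exc:
                raise ValueError(str(exc)) from None
            r_out[i] = d.blood_plasma_ratio / kp
            ub[i] = d.fu / kp
        drug_ctx.append(dict(
            drug=d, off=off, sl=slice(off, off + n_org),
            i_solid=i_solid, i_lumen=i_lumen, i_unabs=i_unabs, i_met=i_met,
            absorption=absorption, r_out=r_out, ub=ub,
            oral_times=sorted(t for r in oral_regs for t in r.times),
        ))

    # dynamic enzyme states only where some TDI (drug-borne or clamped)
    # targets the enzyme
    tdi_targets = sorted(
        {inh.target_enzyme for d in drugs for inh in d.inhibitions
         if inh.mechanism == "tdi"} | set(constant_tdi))
    enzyme_states: list[_EnzymeState] = []
    estate_idx: dict[tuple[str, int], int] = {}
    inh_factor = (lambda dd, o: dd.fu / dd.kp_for(organs[o].name)) \
        if inhibitor_unbound_correction else \
        (lambda dd, o: 1.0 / dd.kp_for(organs[o].name))
    for enz in tdi_targets:
        if enz not in kdeg_map:
            raise ValueError(f"no kdeg default for enzyme {enz!r}")
        for i, o in enumerate(organs):
            e0 = o.enzyme_expression.get(enz, 0.0)
            if e0 <= 0:
                continue
            idx = len(labels)
            labels.append(f"enzyme:{enz}:{o.name}")
            tdi_terms = []
            for j, dd in enumerate(drugs):
                for inh in dd.inhibitions:
                    if inh.mechanism == "tdi" and inh.target_enzyme == enz:
                        tdi_terms.append((drug_ctx[j]["off"] + i,
                                          inh_factor(dd, i),
                                          inh.k_inact, inh.k_i_tdi,
                                          inv_vols[i]))
            for iu, kin, k_i in constant_tdi.get(enz, []):
                tdi_terms.append((-1, iu, kin, k_i, 1.0))
            enzyme_states.append(_EnzymeState(
                enzyme=enz, organ=i, idx=idx, e0=e0,
                kdeg=kdeg_map[enz], tdi=tdi_terms))
            estate_idx[(enz, i)] = idx

    n_states = len(labels)

    # --- metabolism sites ---------------------------------------------------
    sites: list[_Site] = []
    for di, ctx in enumerate(drug_ctx):
        d = ctx["drug"]
        for pw in d.pathways:
            if pw.kinetics == "unspecific_hepatic":
                site_organs = [i_liv]
            else:
                site_organs = [i for i, o in enumerate(organs)
                               if o.enzyme_expression.get(pw.enzyme, 0.0) > 0]
                if not site_organs and not any(
                        o.enzyme_expression.get(pw.enzyme) is not None
                        for o in organs):
                    warnings.warn(
                        f"{d.name}: pathway enzyme {pw.enzyme} is expressed "
                        f"nowhere; pathway inactive", RuntimeWarning,
                        stacklevel=2)
            for o in site_organs:
                comp = []
                if pw.kinetics != "unspecific_hepatic":
                    for j, dd in enumerate(drugs):
                        for inh in dd.inhibitions:
                            if (inh.mechanism == "competitive"
                                    and inh.target_enzyme == pw.enzyme):
                                comp.append((drug_ctx[j]["off"] + o,
                                             inh_factor(dd, o),
                                             inh.ki, inv_vols[o]))
                    for iu, ki in constant_inhibitors.get(pw.enzyme, []):
                        comp.append((-1, iu, ki, 1.0))
                e_idx = estate_idx.get((pw.enzyme, o), -1)
                e0 = organs[o].enzyme_expression.get(pw.enzyme, 0.0)
                sites.append(_Site(
                    drug=di, organ=o, pathway=pw, e0=e0, e_idx=e_idx,
                    ub=ctx["ub"][o], met_idx=ctx["i_met"], comp=comp))

    # --- dosing events ------------------------------------------------------
    events: list[DoseEvent] = []
    infusions: list[Infusion] = []
    dosed: dict[str, list[tuple[float, float]]] = {d.name: [] for d in drugs}
    inf_by_drug: dict[str, list[Infusion]] = {d.name: [] for d in drugs}
    for reg in regimens:
        di = by_name[reg.drug]
        ctx = drug_ctx[di]
        amount = reg.dose_umol(drugs[di])
        if amount == 0:
            continue
        for t in reg.times:
            if reg.route == "iv_bolus":
                events.append(DoseEvent(t, ctx["off"] + i_ven, amount))
                dosed[reg.drug].append((t, amount))
            elif reg.route == "oral":
                target = ctx["i_solid"] if ctx["i_solid"] >= 0 else ctx["i_lumen"]
                events.append(DoseEvent(t, target, amount))
                dosed[reg.drug].append((t, amount))
            else:
                inf = Infusion(ctx["off"] + i_ven,
                               amount / reg.infusion_duration,
                               t, t + reg.infusion_duration)
                infusions.append(inf)
                inf_by_drug[reg.drug].append(inf)

    # --- right-hand side ----------------------------------------------------
    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n_states)
        conc = []
        for ctx in drug_ctx:
            A = y[ctx["sl"]]
            C = A * inv_vols
            conc.append(C)
            c_out = C * ctx["r_out"]
            c_art = C[i_art]
            dA = np.zeros(n_org)
            dA[sys_arr] = q_sys * (c_art - c_out[sys_arr])
            # liver: arterial + portal inflow, pooled outflow
            dA[i_liv] = (q[i_liv] * c_art
                         + float(q_portal @ c_out[portal_idx])
                         - q_liv_total * c_out[i_liv])
            dA[i_ven] = (float(q_to_ven @ c_out[to_ven_arr])
                         + q_liv_total * c_out[i_liv] - co * C[i_ven])
            dA[i_lung] = co * (C[i_ven] - c_out[i_lung])
            dA[i_art] = co * (c_out[i_lung] - c_art)

            if ctx["i_lumen"] >= 0:
                ab = ctx["absorption"]
                lumen = y[ctx["i_lumen"]]
                release = 0.0
                if ctx["i_solid"] >= 0:
                    solid = y[ctx["i_solid"]]
                    times = ctx["oral_times"]
                    k = bisect.bisect_right(times, t) - 1
                    age = t - times[k] if k >= 0 else 0.0
                    shape, scale = ab.weibull_shape, ab.weibull_scale
                    hazard = (shape / scale) * ((max(age, 0.0) + 1e-9)
                                                / scale) ** (shape - 1.0)
                    release = hazard * solid
                    dy[ctx["i_solid"]] = -release
                absorbed = ab.ka * lumen
                dy[ctx["i_lumen"]] = release - absorbed
                dA[i_gut] += ab.f_abs * absorbed
                dy[ctx["i_unabs"]] = (1.0 - ab.f_abs) * absorbed

            dy[ctx["sl"]] += dA

        for s in sites:
            C = conc[s.drug]
            cu = s.ub * C[s.organ]
            if cu <= 0:
                continue
            pw = s.pathway
            if pw.kinetics == "unspecific_hepatic":
                rate = pw.cl_apparent * cu
            else:
                denom = 1.0
                for sidx, f, ki, iv in s.comp:
                    iu = f * max(y[sidx], 0.0) * iv if sidx >= 0 else f
                    denom += iu / ki
                E = y[s.e_idx] if s.e_idx >= 0 else s.e0
                if E <= 0:
                    continue
                if pw.kinetics == "linear":
                    rate = pw.cl_int * E * cu / denom
                else:
                    rate = pw.vmax * E * cu / (pw.km * denom + cu)
            dy[drug_ctx[s.drug]["off"] + s.organ] -= rate
            dy[s.met_idx] += rate

        for es in enzyme_states:
            E = max(y[es.idx], 0.0)
            inact = 0.0
            for sidx, f, kin, k_i, iv in es.tdi:
                iu = f * max(y[sidx], 0.0) * iv if sidx >= 0 else f
                inact += kin * iu / (k_i + iu)
            dy[es.idx] = es.kdeg * (es.e0 - E) - E * inact
        return dy

    # --- initial state, outputs, balances ------------------------------------
    y0 = np.zeros(n_states)
    for es in enzyme_states:
        y0[es.idx] = es.e0

    outputs: dict[str, Callable[[np.ndarray], np.ndarray]] = {}
    for ctx in drug_ctx:
        d = ctx["drug"]

        def plasma(Y, _ctx=ctx, _d=d):
            return (Y[:, _ctx["off"] + i_ven] / vols[i_ven]
                    / _d.blood_plasma_ratio)

        outputs[f"plasma:{d.name}"] = plasma
        for i, o in enumerate(organs):
            outputs[f"conc:{d.name}:{o.name}"] = \
                (lambda Y, _j=ctx["off"] + i, _v=vols[i]: Y[:, _j] / _v)
    for es in enzyme_states:
        outputs[f"enzyme:{es.enzyme}:{organs[es.organ].name}"] = \
            (lambda Y, _j=es.idx, _e0=es.e0: Y[:, _j] / _e0)

    balances = {}
    for ctx in drug_ctx:
        d = ctx["drug"]
        idxs = list(range(ctx["off"], ctx["off"] + n_org))
        for j in (ctx["i_solid"], ctx["i_lumen"], ctx["i_unabs"],
                  ctx["i_met"]):
            if j >= 0:
                idxs.append(j)
        idx_arr = np.array(idxs)
        doses = sorted(dosed[d.name])
        infs = inf_by_drug[d.name]

        def administered(t, _doses=doses, _infs=infs):
            total = sum(a for tt, a in _doses if tt <= t)
            for inf in _infs:
                total += inf.rate * max(0.0, min(t, inf.end) - inf.start)
            return total

        balances[d.name] = (
            (lambda yv, _ia=idx_arr: float(yv[_ia].sum())), administered)

    return ODESystem(
        n_states=n_states, y0=y0, rhs=rhs, events=events,
        infusions=infusions, state_labels=labels, outputs=outputs,
        balances=balances,
        meta={"drugs": names,
              "organs": [o.name for o in organs],
              "enzyme_states": [(es.enzyme, organs[es.organ].name)
                                for es in enzyme_states],
              "n_drug_states": sum(
                  n_org + (1 if c["i_solid"] >= 0 else 0)
                  + (2 if c["i_lumen"] >= 0 else 0) + 1 for c in drug_ctx)})


# --------------------------------------------------------------------------
# one-compartment reduction (verification oracle and sensitivity baseline)

def one_compartment_system(volume: float, clearance: float,
                           doses: Sequence[tuple[float, float]],
                           infusions: Sequence[tuple[float, float, float]] = (),
                           drug: str = "drug") -> ODESystem:
    """Single well-stirred compartment: dA/dt = −CL·A/V.

    ``doses`` are (time min, amount µmol) IV boluses; ``infusions`` are
    (rate µmol/min, start, end). Runs through the same :func:`simulate`
    driver as the whole-body model, so closed-form solutions
    (C(t) = (D/V)·e^{−CL·t/V}, AUC = D/CL) exercise the production solver.
    """
    if volume <= 0 or clearance < 0:
        raise ValueError("volume must be > 0 and clearance >= 0")
    kel = clearance / volume

    def rhs(t, y):
        return np.array([-kel * y[0], kel * y[0]])

    events = [DoseEvent(t, 0, a) for t, a in doses]
    infs = [Infusion(0, r, t0, t1) for r, t0, t1 in infusions]

    def administered(t):
        total = sum(a for tt, a in doses if tt <= t)
        for r, t0, t1 in infusions:
            total += r * max(0.0, min(t, t1) - t0)
        return total

    return ODESystem(
        n_states=2, y0=np.zeros(2), rhs=rhs, events=events, infusions=infs,
        state_labels=[f"{drug}:central", f"{drug}:eliminated"],
        outputs={f"plasma:{drug}": (lambda Y: Y[:, 0] / volume)},
        balances={drug: ((lambda y: float(y.sum())), administered)},
        meta={"drugs": [drug], "one_compartment": True})
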