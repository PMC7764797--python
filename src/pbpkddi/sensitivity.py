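"""Local sensitivity analysis of PK endpoints to model input parameters.

The sensitivity coefficient of endpoint PK_j to input p_i is the ratio of
relative changes,

    S_ij = (ΔPK_j / PK_j) / (Δp_i / p_i),

averaged over several relative perturbations Δ_k for numerical stability
(symmetric ±Δ pairs cancel the leading quadratic bias). Parameters with a
baseline value of zero are skipped — a relative perturbation is undefined
there. Parameters contributing to a chosen share (default 90%) of the summed
absolute sensitivity form the ranked short list carried forward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import pandas as pd

__all__ = ["SensitivityTable", "SimulationTask", "sensitivity_coefficient",
           "sensitivity_table", "rank_by_cumulative_sensitivity",
           "DEFAULT_DELTAS", "SKIPPED"]

#: default relative perturbations Δ_k
DEFAULT_DELTAS = (-0.1, -0.05, 0.05, 0.1)

#: sentinel for parameters skipped because their baseline value is 0
SKIPPED = None


@dataclass
class SimulationTask:
    """A rerunnable simulation exposing endpoints as functions of parameters.

    ``evaluate`` maps a dict of absolute parameter overrides (handle →
    value) to endpoint values (e.g. ``{"AUC": ..., "Cmax": ...}``);
    ``baseline_parameters`` holds the unperturbed values of every
    addressable handle.
    """

    evaluate: Callable[[dict[str, float]], dict[str, float]]
    baseline_parameters: dict[str, float]

    def __post_init__(self):
        self._baseline_endpoints: Optional[dict[str, float]] = None

    def baseline_endpoints(self) -> dict[str, float]:
        if self._baseline_endpoints is None:
            self._baseline_endpoints = self.evaluate({})
        return self._baseline_endpoints


class SensitivityTable:
    """Rows of (parameter, endpoint, mean coefficient, per-Δ coefficients)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"parameter", "endpoint", "coefficient", "per_delta", "n"}
        if not required.issubset(frame.columns):
            raise ValueError(f"sensitivity table needs columns {required}")
        self.frame = frame.reset_index(drop=True)

    def for_endpoint(self, endpoint: str) -> pd.DataFrame:
        return self.frame[self.frame.endpoint == endpoint]

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["per_delta"] = out["per_delta"].map(
            lambda v: ";".join(f"{x:.6g}" for x in v))
        out.to_csv(path, index=False)


def sensitivity_coefficient(
        task: SimulationTask, parameter: str, endpoint: str,
        deltas: Sequence[float] = DEFAULT_DELTAS) -> tuple[Optional[float],
                                                           list[float]]:
    """Mean sensitivity coefficient and its per-perturbation components.

    Returns ``(SKIPPED, [])`` when the baseline parameter value is zero.
    Each component reruns the simulation at p_i·(1+Δ_k) with all other
    inputs unchanged.
    """
    if not deltas or any(d == 0 for d in deltas):
        raise ValueError("deltas must be nonzero")
    p0 = task.baseline_parameters[parameter]
    if p0 == 0:
        return SKIPPED, []
    pk0 = task.baseline_endpoints()[endpoint]
    if pk0 == 0:
        raise ValueError(f"baseline endpoint {endpoint} is zero")
    per_delta = []
    for d in deltas:
        pk = task.evaluate({parameter: p0 * (1.0 + d)})[endpoint]
        per_delta.append(((pk - pk0) / pk0) / d)
    return sum(per_delta) / len(per_delta), per_delta


def sensitivity_table(task: SimulationTask,
                      parameters: Optional[Sequence[str]] = None,
                      endpoints: Sequence[str] = ("AUC", "Cmax"),
                      deltas: Sequence[float] = DEFAULT_DELTAS
                      ) -> SensitivityTable:
    """Coefficients for every (parameter, endpoint) pair.

    Zero-baseline parameters are recorded with a missing coefficient rather
    than silently dropped.
    """
    parameters = list(parameters if parameters is not None
                      else task.baseline_parameters)
    rows = []
    for p in parameters:
        s_by_endpoint = {}
        for e in endpoints:
            s, per = sensitivity_coefficient(task, p, e, deltas)
            s_by_endpoint[e] = (s, per)
        for e in endpoints:
            s, per = s_by_endpoint[e]
            rows.append({"parameter": p, "endpoint": e,
                         "coefficient": s, "per_delta": per,
                         "n": len(per)})
    return SensitivityTable(pd.DataFrame(rows))


def one_compartment_task(volume: float = 10.0, clearance: float = 0.1,
                         dose: float = 100.0, t_end: float = 1000.0,
                         n_grid: int = 501) -> SimulationTask:
    """Sensitivity task on a one-compartment IV model (AUC = Dose/CL).

    The closed form makes the exact coefficients known (S(AUC, CL) = −1,
    S(AUC, Dose) = +1, S(Cmax, V) = −1), so this task verifies the
    perturbation machinery against analytic values while still running the
    production solver.
    """
    from .engine import one_compartment_system, simulate
    from .metrics import compute_metrics
    import numpy as np

    baseline = {"CL": clearance, "V": volume, "Dose": dose}

    def evaluate(overrides: dict[str, float]) -> dict[str, float]:
        p = dict(baseline)
        p.update(overrides)
        sys = one_compartment_system(p["V"], p["CL"], [(0.0, p["Dose"])])
        res = simulate(sys, t_end, np.linspace(0.0, t_end, n_grid))
        m = compute_metrics(res.time, res.plasma("drug"), extrapolate=True)
        return {"AUC": m.auc, "Cmax": m.cmax}

    return SimulationTask(evaluate=evaluate, baseline_parameters=baseline)


def rank_by_cumulative_sensitivity(table: SensitivityTable, endpoint: str,
                                   threshold: float = 0.90) -> list[str]:
    """Minimal |S|-descending prefix reaching the cumulative share threshold.

    Parameters are sorted by |S| descending (ties broken by name for
    determinism); the returned prefix is the smallest whose Σ|S| is at least
    ``threshold`` of the total Σ|S| for the endpoint.
    """
    sub = table.for_endpoint(endpoint).dropna(subset=["coefficient"])
    if sub.empty:
        raise ValueError(f"no sensitivities for endpoint {endpoint!r}")
    sub = sub.assign(abs_s=sub.coefficient.abs()).sort_values(
        ["abs_s", "parameter"], ascending=[False, True], kind="mergesort")
    total = sub.abs_s.sum()
    if total == 0:
        warnings.warn("all sensitivities are zero; empty ranking",
                      RuntimeWarning, stacklevel=2)
        return []
    # boundary is strict: a prefix landing exactly on the threshold share
    # still pulls in the next parameter
    cum = 0.0
    out = []
    for _, row in sub.iterrows():
        out.append(row.parameter)
        cum += row.abs_s
        if cum > threshold * total + 1e-12:
            break
    return out
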