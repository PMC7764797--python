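"""String handles addressing tunable model parameters.

A handle names one scalar input of a simulation context (drugs, individual,
regimens) so that sensitivity analysis and parameter estimation can read and
perturb it without touching model structure. Structural choices (pathway
kinetics, organ topology, dose times) are deliberately not addressable.

Handle grammar (segments joined by ``/``)::

    drug:<name>/fu
    drug:<name>/blood_plasma_ratio
    drug:<name>/kp:<tissue>
    drug:<name>/pathway:<ENZYME>/<cl_int|vmax|km|cl_apparent>
    drug:<name>/inhibition:<ENZYME>:<mechanism>/<ki|k_i_tdi|k_inact>
    drug:<name>/absorption:oral/<ka|f_abs>
    individual/organ:<name>/<volume|blood_flow>
    individual/organ:<name>/expression:<ENZYME>
    regimen:<drug>[:<index>]/dose
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .drugs import Drug
from .engine import DosingRegimen
from .physiology import Individual

__all__ = ["SimContext", "get_parameter", "set_parameter", "list_parameters"]


@dataclass(frozen=True)
class SimContext:
    """Immutable bundle of everything a trial simulation consumes."""

    drugs: tuple[Drug, ...]
    individual: Individual
    regimens: tuple[DosingRegimen, ...]

    def drug(self, name: str) -> Drug:
        for d in self.drugs:
            if d.name == name:
                return d
        raise KeyError(f"no drug {name!r} in context")


class HandleError(KeyError):
    pass


def _split(handle: str) -> list[str]:
    parts = handle.split("/")
    if not all(parts):
        raise HandleError(f"malformed handle {handle!r}")
    return parts


def _drug_get(d: Drug, parts: list[str]) -> float:
    head, rest = parts[0], parts[1:]
    if not rest:
        if head in ("fu", "blood_plasma_ratio", "molecular_weight"):
            return getattr(d, head)
        if head.startswith("kp:"):
            tissue = head[3:]
            if tissue not in d.kp_map:
                raise HandleError(f"{d.name}: no explicit Kp for {tissue!r}")
            return d.kp_map[tissue]
        raise HandleError(f"unknown drug field {head!r}")
    if head.startswith("pathway:"):
        pw = d.pathway_for(head[len("pathway:"):])
        value = getattr(pw, rest[0], None)
        if value is None:
            raise HandleError(f"{d.name}/{head} has no parameter {rest[0]!r}")
        return value
    if head.startswith("inhibition:"):
        _, enzyme, mechanism = head.split(":")
        for inh in d.inhibitions:
            if inh.target_enzyme == enzyme and inh.mechanism == mechanism:
                value = getattr(inh, rest[0], None)
                if value is None:
                    raise HandleError(
                        f"{d.name}/{head} has no parameter {rest[0]!r}")
                return value
        raise HandleError(f"{d.name}: no {mechanism} inhibition of {enzyme}")
    if head.startswith("absorption:"):
        route = head[len("absorption:"):]
        if route not in d.absorption:
            raise HandleError(f"{d.name}: no {route} absorption block")
        return getattr(d.absorption[route], rest[0])
    raise HandleError(f"unknown drug sub-handle {head!r}")


def _drug_set(d: Drug, parts: list[str], value: float) -> Drug:
    head, rest = parts[0], parts[1:]
    if not rest:
        if head in ("fu", "blood_plasma_ratio", "molecular_weight"):
            return d.model_copy(update={head: value})
        if head.startswith("kp:"):
            kp = dict(d.kp_map)
            tissue = head[3:]
            if tissue not in kp:
                raise HandleError(f"{d.name}: no explicit Kp for {tissue!r}")
            kp[tissue] = value
            return d.model_copy(update={"kp_map": kp})
        raise HandleError(f"unknown drug field {head!r}")
    if head.startswith("pathway:"):
        enzyme = head[len("pathway:"):]
        pathways = []
        found = False
        for pw in d.pathways:
            if pw.enzyme == enzyme:
                if getattr(pw, rest[0], None) is None:
                    raise HandleError(
                        f"{d.name}/{head} has no parameter {rest[0]!r}")
                pw = pw.model_copy(update={rest[0]: value})
                found = True
            pathways.append(pw)
        if not found:
            raise HandleError(f"{d.name}: no {enzyme} pathway")
        return d.model_copy(update={"pathways": pathways})
    if head.startswith("inhibition:"):
        _, enzyme, mechanism = head.split(":")
        inhibitions = []
        found = False
        for inh in d.inhibitions:
            if inh.target_enzyme == enzyme and inh.mechanism == mechanism:
                if getattr(inh, rest[0], None) is None:
                    raise HandleError(
                        f"{d.name}/{head} has no parameter {rest[0]!r}")
                inh = inh.model_copy(update={rest[0]: value})
                found = True
            inhibitions.append(inh)
        if not found:
            raise HandleError(f"{d.name}: no {mechanism} inhibition of {enzyme}")
        return d.model_copy(update={"inhibitions": inhibitions})
    if head.startswith("absorption:"):
        route = head[len("absorption:"):]
        if route not in d.absorption:
            raise HandleError(f"{d.name}: no {route} absorption block")
        ab = d.absorption[route].model_copy(update={rest[0]: value})
        absorption = dict(d.absorption)
        absorption[route] = ab
        return d.model_copy(update={"absorption": absorption})
    raise HandleError(f"unknown drug sub-handle {head!r}")


def get_parameter(ctx: SimContext, handle: str) -> float:
    parts = _split(handle)
    if parts[0].startswith("drug:"):
        return _drug_get(ctx.drug(parts[0][5:]), parts[1:])
    if parts[0] == "individual":
        return _individual_get(ctx.individual, parts[1:])
    if parts[0].startswith("regimen:"):
        return _regimen_get(ctx.regimens, parts, ctx)
    raise HandleError(f"unknown handle root {parts[0]!r}")


def set_parameter(ctx: SimContext, handle: str, value: float) -> SimContext:
    """Return a new context with one parameter replaced; never mutates."""
    parts = _split(handle)
    if parts[0].startswith("drug:"):
        name = parts[0][5:]
        drugs = tuple(_drug_set(d, parts[1:], value) if d.name == name else d
                      for d in ctx.drugs)
        ctx.drug(name)  # raise if absent
        return replace(ctx, drugs=drugs)
    if parts[0] == "individual":
        return replace(ctx, individual=_individual_set(
            ctx.individual, parts[1:], value))
    if parts[0].startswith("regimen:"):
        return _regimen_set(ctx, parts, value)
    raise HandleError(f"unknown handle root {parts[0]!r}")


def _individual_get(ind: Individual, parts: list[str]) -> float:
    if not parts or not parts[0].startswith("organ:"):
        raise HandleError(f"unknown individual handle {'/'.join(parts)!r}")
    organ = ind.organ(parts[0][6:])
    field = parts[1]
    if field in ("volume", "blood_flow"):
        return getattr(organ, field)
    if field.startswith("expression:"):
        enzyme = field[len("expression:"):]
        if enzyme not in organ.enzyme_expression:
            raise HandleError(f"{organ.name} does not express {enzyme}")
        return organ.enzyme_expression[enzyme]
    raise HandleError(f"unknown organ field {field!r}")


def _individual_set(ind: Individual, parts: list[str],
                    value: float) -> Individual:
    if not parts or not parts[0].startswith("organ:"):
        raise HandleError(f"unknown individual handle {'/'.join(parts)!r}")
    name = parts[0][6:]
    field = parts[1]
    organs = []
    for o in ind.organs:
        if o.name == name:
            if field in ("volume", "blood_flow"):
                o = o.model_copy(update={field: value})
            elif field.startswith("expression:"):
                enzyme = field[len("expression:"):]
                if enzyme not in o.enzyme_expression:
                    raise HandleError(f"{name} does not express {enzyme}")
                expr = dict(o.enzyme_expression)
                expr[enzyme] = value
                o = o.model_copy(update={"enzyme_expression": expr})
            else:
                raise HandleError(f"unknown organ field {field!r}")
        organs.append(o)
    ind.organ(name)  # raise if absent
    # blood-flow edits may break the cardiac-output sum; rebalance via CO
    systemic = [o for o in organs
                if o.name not in ("arterial_blood", "venous_blood", "lung")]
    co = sum(o.blood_flow for o in systemic)
    organs = [o.model_copy(update={"blood_flow": co})
              if o.name in ("arterial_blood", "venous_blood", "lung") else o
              for o in organs]
    return Individual(organs=organs, body_weight=ind.body_weight,
                      cardiac_output=co)


def _regimen_key(part: str) -> tuple[str, int | None]:
    bits = part.split(":")
    if len(bits) == 2:
        return bits[1], None
    if len(bits) == 3:
        return bits[1], int(bits[2])
    raise HandleError(f"malformed regimen handle {part!r}")


def _matching_regimens(regimens: Sequence[DosingRegimen], drug: str,
                       index: int | None) -> list[int]:
    hits = [i for i, r in enumerate(regimens) if r.drug == drug]
    if not hits:
        raise HandleError(f"no regimen for drug {drug!r}")
    if index is None:
        if len(hits) > 1:
            raise HandleError(
                f"multiple regimens for {drug!r}; use regimen:{drug}:<index>")
        return hits
    if index >= len(hits):
        raise HandleError(f"regimen index {index} out of range for {drug!r}")
    return [hits[index]]


def _regimen_get(regimens, parts, ctx: SimContext) -> float:
    drug, index = _regimen_key(parts[0])
    if parts[1] != "dose":
        raise HandleError(f"unknown regimen field {parts[1]!r}")
    (i,) = _matching_regimens(regimens, drug, index)
    return regimens[i].dose_umol(ctx.drug(drug))


def _regimen_set(ctx: SimContext, parts, value: float) -> SimContext:
    drug, index = _regimen_key(parts[0])
    if parts[1] != "dose":
        raise HandleError(f"unknown regimen field {parts[1]!r}")
    (i,) = _matching_regimens(ctx.regimens, drug, index)
    regimens = list(ctx.regimens)
    regimens[i] = regimens[i].model_copy(update={"dose": float(value)})
    return replace(ctx, regimens=tuple(regimens))


def list_parameters(ctx: SimContext) -> list[str]:
    """The documented whitelist of perturbable parameter handles."""
    handles: list[str] = []
    for d in ctx.drugs:
        handles += [f"drug:{d.name}/fu", f"drug:{d.name}/blood_plasma_ratio"]
        handles += [f"drug:{d.name}/kp:{t}" for t in d.kp_map]
        for pw in d.pathways:
            for p in ("cl_int", "vmax", "km", "cl_apparent"):
                if getattr(pw, p) is not None:
                    handles.append(f"drug:{d.name}/pathway:{pw.enzyme}/{p}")
        for inh in d.inhibitions:
            for p in ("ki", "k_i_tdi", "k_inact"):
                if getattr(inh, p) is not None:
                    handles.append(
                        f"drug:{d.name}/inhibition:{inh.target_enzyme}:"
                        f"{inh.mechanism}/{p}")
        for route, ab in d.absorption.items():
            handles += [f"drug:{d.name}/absorption:{route}/ka",
                        f"drug:{d.name}/absorption:{route}/f_abs"]
    for o in ctx.individual.organs:
        handles += [f"individual/organ:{o.name}/volume",
                    f"individual/organ:{o.name}/blood_flow"]
        for enz in o.enzyme_expression:
            handles.append(f"individual/organ:{o.name}/expression:{enz}")
    seen: dict[str, int] = {}
    for r in ctx.regimens:
        k = seen.get(r.drug, 0)
        seen[r.drug] = k + 1
    for drug, count in seen.items():
        if count == 1:
            handles.append(f"regimen:{drug}/dose")
        else:
            handles += [f"regimen:{drug}:{i}/dose" for i in range(count)]
    return handles
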