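"""Reference individual physiology and CYP phenotype scaling.

A reduced whole-body compartment set (14 organs including separate arterial
and venous blood, lung, and a liver fed by the hepatic artery plus portal
drainage from gut wall and spleen) with literature-standard adult volumes and
blood flows. CYP enzymes are expressed in the liver; CYP3A4 and CYP2C19 are
additionally expressed in the gut wall, where they drive intestinal
first-pass extraction.

Genotype effects (extensive vs poor metabolizer, EM/PM) are represented as
multiplicative activity factors on an enzyme's expression in every organ:
EM = 1.0, PM = 0.0, intermediate values allowed.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .drugs import ENZYMES

__all__ = [
    "Organ", "Individual", "Phenotype", "default_individual",
    "apply_phenotype", "scale_gut_expression", "load_physiology_config",
    "BLOOD_COMPARTMENTS", "PORTAL_ORGANS",
]

BLOOD_COMPARTMENTS = ("arterial_blood", "venous_blood")
#: organs whose venous outflow drains into the portal vein (then liver)
PORTAL_ORGANS = ("gut", "spleen")


class Organ(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    volume: float      # L
    blood_flow: float  # L/min (arterial inflow; for lung: cardiac output)
    enzyme_expression: dict[str, float] = {}  # enzyme -> µmol in organ

    @model_validator(mode="after")
    def _positive(self) -> "Organ":
        if self.volume <= 0:
            raise ValueError(f"{self.name}: volume must be > 0")
        if self.blood_flow <= 0:
            raise ValueError(f"{self.name}: blood_flow must be > 0")
        for enz, amount in self.enzyme_expression.items():
            if enz not in ENZYMES:
                raise ValueError(f"{self.name}: unknown enzyme {enz!r}")
            if amount < 0:
                raise ValueError(f"{self.name}: expression of {enz} < 0")
        return self


class Individual(BaseModel):
    model_config = ConfigDict(frozen=True)

    organs: list[Organ]
    body_weight: float = 73.0   # kg
    cardiac_output: float       # L/min

    @model_validator(mode="after")
    def _topology(self) -> "Individual":
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate organ names")
        for required in ("liver", "gut", "kidney", "lung",
                         "arterial_blood", "venous_blood"):
            if required not in names:
                raise ValueError(f"individual must include organ {required!r}")
        # systemic (arterial-receiving) flows must sum to cardiac output
        systemic = [o for o in self.organs
                    if o.name not in BLOOD_COMPARTMENTS and o.name != "lung"]
        total = sum(o.blood_flow for o in systemic)
        if abs(total - self.cardiac_output) > 1e-9 * self.cardiac_output:
            raise ValueError(
                f"organ blood flows sum to {total} L/min but cardiac output "
                f"is {self.cardiac_output} L/min")
        return self

    def organ(self, name: str) -> Organ:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(f"no organ {name!r}")

    def expression(self, enzyme: str, organ: str) -> float:
        return self.organ(organ).enzyme_expression.get(enzyme, 0.0)

    def liver_inflow(self) -> float:
        """Total liver blood inflow: hepatic artery plus portal drainage."""
        return self.organ("liver").blood_flow + sum(
            self.organ(n).blood_flow for n in PORTAL_ORGANS if self._has(n))

    def _has(self, name: str) -> bool:
        return any(o.name == name for o in self.organs)

    def _replace_organs(self, organs: list[Organ]) -> "Individual":
        return self.model_copy(update={"organs": organs})


class Phenotype(BaseModel):
    """Genotype-driven activity multiplier for one enzyme (EM=1, PM=0)."""

    model_config = ConfigDict(frozen=True)

    enzyme: str
    activity_multiplier: float

    @model_validator(mode="after")
    def _valid(self) -> "Phenotype":
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.activity_multiplier < 0:
            raise ValueError("activity_multiplier must be >= 0")
        return self


# reference adult: volumes (L) and regional blood flows (L/min); cardiac
# output 5.4 L/min; liver inflow = hepatic artery + portal vein (gut+spleen)
_REFERENCE_ORGANS: list[tuple[str, float, float, dict[str, float]]] = [
    ("lung",           0.53, 5.400, {}),
    ("arterial_blood", 1.70, 5.400, {}),
    ("venous_blood",   3.90, 5.400, {}),
    ("brain",          1.45, 0.700, {}),
    ("heart",          0.33, 0.215, {}),
    ("muscle",        29.00, 0.900, {}),
    ("adipose",       14.50, 0.260, {}),
    ("skin",           3.30, 0.300, {}),
    ("bone",          10.50, 0.280, {}),
    ("kidney",         0.31, 1.100, {}),
    ("spleen",         0.18, 0.080, {}),
    ("gut",            1.10, 1.000, {"CYP3A4": 0.07, "CYP2C19": 0.05}),
    ("liver",          1.80, 0.320, {"CYP3A4": 4.0, "CYP2C19": 0.9,
                                     "CYP1A2": 1.6, "CYP2D6": 0.35,
                                     "CYP2C9": 3.2, "UGT1A1": 2.5}),
    ("rest",           4.30, 0.245, {}),
]


def default_individual() -> Individual:
    """Documented reference adult (73 kg, cardiac output 5.4 L/min).

    Liver expresses all modeled enzymes; gut wall expresses CYP3A4 and
    CYP2C19 (the enzymes responsible for intestinal first-pass extraction in
    this network). Expression amounts (µmol enzyme per organ) are
    illustrative scalers: only the product of expression and per-µmol
    pathway rates is identifiable.
    """
    organs = [Organ(name=n, volume=v, blood_flow=q, enzyme_expression=e)
              for n, v, q, e in _REFERENCE_ORGANS]
    return Individual(organs=organs, body_weight=73.0, cardiac_output=5.4)


def apply_phenotype(ind: Individual, ph: Phenotype) -> Individual:
    """Scale one enzyme's expression in every organ; returns a new Individual."""
    if ph.enzyme not in ENZYMES:
        raise KeyError(f"unknown enzyme {ph.enzyme!r}")
    organs = []
    for o in ind.organs:
        if ph.enzyme in o.enzyme_expression:
            expr = dict(o.enzyme_expression)
            expr[ph.enzyme] = expr[ph.enzyme] * ph.activity_multiplier
            o = o.model_copy(update={"enzyme_expression": expr})
        organs.append(o)
    return ind._replace_organs(organs)


def scale_gut_expression(ind: Individual, enzyme: str,
                         factor: float) -> Individual:
    """Scale gut-wall expression of one enzyme; liver is untouched.

    Lowering gut expression of an enzyme raises the oral bioavailability of
    its substrates by reducing intestinal first-pass extraction.
    """
    if enzyme not in ENZYMES:
        raise KeyError(f"unknown enzyme {enzyme!r}")
    if factor < 0:
        raise ValueError("factor must be >= 0")
    organs = []
    for o in ind.organs:
        if o.name == "gut" and enzyme in o.enzyme_expression:
            expr = dict(o.enzyme_expression)
            expr[enzyme] = expr[enzyme] * factor
            o = o.model_copy(update={"enzyme_expression": expr})
        organs.append(o)
    return ind._replace_organs(organs)


def load_physiology_config(path: str | Path,
                           base: Individual | None = None) -> Individual:
    """Apply per-organ volume/flow/expression overrides from a YAML file.

    Schema::

        schema: pbpkddi-physiology/1
        body_weight: 73
        cardiac_output: 5.4
        organs:
          liver: {volume: 1.9, enzyme_expression: {CYP2C19: 0.5}}
    """
    base = base or default_individual()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if doc.get("schema", "pbpkddi-physiology/1") != "pbpkddi-physiology/1":
        raise ValueError(f"unsupported physiology schema in {path}")
    organs = []
    overrides = doc.get("organs") or {}
    known = {o.name for o in base.organs}
    for name in overrides:
        if name not in known:
            raise ValueError(f"{path}: unknown organ {name!r}")
    for o in base.organs:
        ov = overrides.get(o.name)
        if ov:
            update = {k: ov[k] for k in ("volume", "blood_flow") if k in ov}
            if "enzyme_expression" in ov:
                expr = dict(o.enzyme_expression)
                expr.update(ov["enzyme_expression"])
                update["enzyme_expression"] = expr
            o = o.model_copy(update=update)
        organs.append(o)
    update: dict = {"organs": organs}
    for k in ("body_weight", "cardiac_output"):
        if k in doc:
            update[k] = doc[k]
    return Individual(organs=organs,
                      body_weight=update.get("body_weight", base.body_weight),
                      cardiac_output=update.get("cardiac_output",
                                                base.cardiac_output))
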