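"""Drug, pathway and inhibition data model plus configuration file I/O.

A :class:`Drug` bundles the physicochemical, absorption, metabolic-pathway
and enzyme-inhibition parameters needed to place a compound in a whole-body
PBPK simulation. Configurations are YAML documents (schema
``pbpkddi-drug/1``) with explicit unit strings; everything is normalised to
canonical internal units (µM, µmol, L, min) at load time.

The module also ships :func:`builtin_ki_library`, the interaction-constant
table of the CYP1A2/CYP2C19 inhibition network (competitive Ki and
time-dependent-inhibition KI/kinact per perpetrator-victim pair), and a
small library of illustrative drug files for the eight network compounds.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .units import parse_quantity

__all__ = [
    "ENZYMES", "Pathway", "Inhibition", "Absorption", "Drug",
    "ConfigError", "load_drug_config", "write_drug_config",
    "builtin_ki_library", "ki_for_pair", "builtin_drug_names",
    "load_builtin_drug", "KiEntry",
]

#: Recognised enzyme identifiers. UNSPECIFIC marks a non-enzymatic hepatic
#: clearance scaled from an in vivo apparent clearance.
ENZYMES = (
    "CYP1A2", "CYP2C19", "CYP2D6", "CYP3A4", "CYP2C9", "UGT1A1", "UNSPECIFIC",
)

SCHEMA_ID = "pbpkddi-drug/1"


class ConfigError(ValueError):
    """Configuration file violates the documented schema."""


def _check_enzyme(enzyme: str) -> str:
    if enzyme not in ENZYMES:
        raise ValueError(
            f"unknown enzyme identifier {enzyme!r}; allowed: {list(ENZYMES)}")
    return enzyme


class Pathway(BaseModel):
    """One metabolic pathway of a drug.

    kinetics:
      * ``linear`` — rate = cl_int · E_active · C_u / (1 + Σ I_u/Ki)
      * ``saturable`` — rate = vmax · E_active · C_u / (Km·(1+Σ I_u/Ki) + C_u)
      * ``unspecific_hepatic`` — rate = cl_apparent · C_u (liver only,
        insensitive to inhibitors)
    """

    model_config = ConfigDict(frozen=True)

    enzyme: str
    kinetics: Literal["linear", "saturable", "unspecific_hepatic"]
    cl_int: Optional[float] = None       # L/min/µmol enzyme
    vmax: Optional[float] = None         # µmol/min/µmol enzyme
    km: Optional[float] = None           # µM unbound
    cl_apparent: Optional[float] = None  # L/min

    _enzyme_ok = field_validator("enzyme")(_check_enzyme)

    @model_validator(mode="after")
    def _exact_parameter_set(self) -> "Pathway":
        required = {
            "linear": ("cl_int",),
            "saturable": ("vmax", "km"),
            "unspecific_hepatic": ("cl_apparent",),
        }[self.kinetics]
        all_params = ("cl_int", "vmax", "km", "cl_apparent")
        for p in all_params:
            v = getattr(self, p)
            if p in required:
                if v is None:
                    raise ValueError(
                        f"pathway with kinetics={self.kinetics!r} requires {p}")
                if v <= 0:
                    raise ValueError(f"{p} must be > 0, got {v}")
            elif v is not None:
                raise ValueError(
                    f"{p} is not a parameter of kinetics={self.kinetics!r}")
        if (self.kinetics == "unspecific_hepatic") != (self.enzyme == "UNSPECIFIC"):
            raise ValueError(
                "enzyme UNSPECIFIC and kinetics unspecific_hepatic go together")
        return self


class Inhibition(BaseModel):
    """Inhibition exerted by a drug on one target enzyme.

    ``competitive`` carries Ki (µM unbound); ``tdi`` (mechanism-based,
    time-dependent inactivation) carries the binding constant KI
    (``k_i_tdi``, µM unbound) and the maximum inactivation rate ``k_inact``
    (1/min).
    """

    model_config = ConfigDict(frozen=True)

    target_enzyme: str
    mechanism: Literal["competitive", "tdi"]
    ki: Optional[float] = None       # µM unbound
    k_i_tdi: Optional[float] = None  # µM unbound
    k_inact: Optional[float] = None  # 1/min
    basis: Literal["in_vitro", "in_vivo_unbound", "optimized"] = "in_vitro"
    metadata: dict[str, Any] = {}

    _enzyme_ok = field_validator("target_enzyme")(_check_enzyme)

    @model_validator(mode="after")
    def _mechanism_params(self) -> "Inhibition":
        if self.mechanism == "competitive":
            if self.ki is None or self.ki <= 0:
                raise ValueError("competitive inhibition requires ki > 0")
            if self.k_i_tdi is not None or self.k_inact is not None:
                raise ValueError("competitive inhibition carries only ki")
        else:
            if self.k_i_tdi is None or self.k_i_tdi <= 0:
                raise ValueError("tdi requires k_i_tdi > 0")
            if self.k_inact is None or self.k_inact <= 0:
                raise ValueError("tdi requires k_inact > 0")
            if self.ki is not None:
                raise ValueError("tdi inhibition carries k_i_tdi, not ki")
        if self.target_enzyme == "UNSPECIFIC":
            raise ValueError("UNSPECIFIC clearance cannot be inhibited")
        return self


class Absorption(BaseModel):
    """Route-specific absorption parameters (currently oral only)."""

    model_config = ConfigDict(frozen=True)

    ka: float                              # 1/min
    f_abs: float = 1.0                     # fraction absorbed (0, 1]
    weibull_scale: Optional[float] = None  # min
    weibull_shape: Optional[float] = None

    @model_validator(mode="after")
    def _ranges(self) -> "Absorption":
        if self.ka <= 0:
            raise ValueError("ka must be > 0")
        if not (0 < self.f_abs <= 1):
            raise ValueError("f_abs must be in (0, 1]")
        if (self.weibull_scale is None) != (self.weibull_shape is None):
            raise ValueError("Weibull release needs both scale and shape")
        if self.weibull_scale is not None:
            if self.weibull_scale <= 0 or self.weibull_shape <= 0:
                raise ValueError("Weibull scale and shape must be > 0")
        return self


class Drug(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    molecular_weight: float               # g/mol
    fu: float                             # unbound fraction in plasma (0, 1]
    blood_plasma_ratio: float = 1.0
    kp_map: dict[str, float] = {}         # tissue -> Kp; "default" allowed
    pathways: list[Pathway] = []
    inhibitions: list[Inhibition] = []
    absorption: dict[str, Absorption] = {}
    dietary: bool = False                 # background intake possible (caffeine)
    notes: Optional[str] = None

    @model_validator(mode="after")
    def _invariants(self) -> "Drug":
        if not (0 < self.fu <= 1):
            raise ValueError(f"fu must be in (0, 1], got {self.fu}")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        if self.blood_plasma_ratio <= 0:
            raise ValueError("blood_plasma_ratio must be > 0")
        for organ, kp in self.kp_map.items():
            if kp <= 0:
                raise ValueError(f"kp for {organ!r} must be > 0, got {kp}")
        enzymes = [p.enzyme for p in self.pathways]
        if len(set(enzymes)) != len(enzymes):
            raise ValueError(f"pathway enzymes must be unique, got {enzymes}")
        return self

    def kp_for(self, organ: str) -> float:
        """Tissue:plasma partition coefficient for an organ.

        Falls back to the ``default`` entry; raises KeyError if neither is
        present (a flow-limited model needs a Kp for every perfused organ).
        """
        if organ in self.kp_map:
            return self.kp_map[organ]
        if "default" in self.kp_map:
            return self.kp_map["default"]
        raise KeyError(f"drug {self.name!r} has no Kp for organ {organ!r}")

    def dose_to_umol(self, dose_mg: float) -> float:
        return dose_mg / self.molecular_weight * 1e3  # mg / (g/mol) -> µmol

    def pathway_for(self, enzyme: str) -> Pathway:
        for p in self.pathways:
            if p.enzyme == enzyme:
                return p
        raise KeyError(f"drug {self.name!r} has no {enzyme} pathway")

    def with_inhibitions(self, inhibitions: list[Inhibition]) -> "Drug":
        return self.model_copy(update={"inhibitions": list(inhibitions)})


# --------------------------------------------------------------------------
# configuration I/O

_PATHWAY_UNITS = {"cl_int": "cl_int", "vmax": "vmax", "km": "concentration",
                  "cl_apparent": "clearance"}
_INHIB_UNITS = {"ki": "concentration", "k_i_tdi": "concentration",
                "k_inact": "rate"}
_ABS_UNITS = {"ka": "rate", "weibull_scale": "time"}


def _parse_block(block: dict, unit_map: dict[str, str], where: str) -> dict:
    out = {}
    for key, value in block.items():
        if key in unit_map and value is not None:
            try:
                out[key] = parse_quantity(value, unit_map[key])
            except ValueError as exc:
                raise ConfigError(f"{where}.{key}: {exc}") from exc
        else:
            out[key] = value
    return out


def drug_from_dict(doc: dict) -> Drug:
    """Build a validated Drug from a parsed configuration document."""
    if not isinstance(doc, dict):
        raise ConfigError("drug configuration must be a mapping")
    doc = dict(doc)
    schema = doc.pop("schema", SCHEMA_ID)
    if schema != SCHEMA_ID:
        raise ConfigError(f"unsupported schema {schema!r}; expected {SCHEMA_ID}")
    for scalar, kind in (("molecular_weight", "molar_mass"),):
        if scalar in doc:
            doc[scalar] = parse_quantity(doc[scalar], kind)
    doc["pathways"] = [
        _parse_block(p, _PATHWAY_UNITS, f"pathways[{i}]")
        for i, p in enumerate(doc.get("pathways") or [])
    ]
    doc["inhibitions"] = [
        _parse_block(p, _INHIB_UNITS, f"inhibitions[{i}]")
        for i, p in enumerate(doc.get("inhibitions") or [])
    ]
    doc["absorption"] = {
        route: _parse_block(a, _ABS_UNITS, f"absorption.{route}")
        for route, a in (doc.get("absorption") or {}).items()
    }
    if "kp" in doc:  # accept 'kp' as alias in files
        doc["kp_map"] = doc.pop("kp")
    try:
        return Drug(**doc)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid drug configuration: {exc}") from exc


def load_drug_config(path: str | Path) -> Drug:
    """Load and validate a YAML drug configuration file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return drug_from_dict(doc)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def drug_to_dict(drug: Drug) -> dict:
    """Serialise a Drug to a configuration document in canonical units."""
    doc: dict[str, Any] = {"schema": SCHEMA_ID}
    doc.update(drug.model_dump(exclude_none=True, exclude_defaults=False))
    doc.pop("notes", None) if drug.notes is None else None
    return doc


def write_drug_config(drug: Drug, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(drug_to_dict(drug), fh, sort_keys=False,
                       allow_unicode=True)


# --------------------------------------------------------------------------
# interaction-constant library

class KiEntry(BaseModel):
    """One perpetrator→victim interaction constant of the DDI network."""

    model_config = ConfigDict(frozen=True)

    inhibitor: str
    substrate: str
    category: str  # e.g. "strong CYP2C19"
    inhibition: Inhibition


#: k_inact is not tabulated for the omeprazole-enantiomer and moclobemide
#: autoinhibition entries; an illustrative mechanism-based-inactivation rate
#: is used and flagged in the entry metadata.
ILLUSTRATIVE_KINACT = 0.05  # 1/min


def builtin_ki_library() -> list[KiEntry]:
    """The interaction constants of the CYP2C19/CYP1A2 DDI network.

    Competitive Ki are unbound values; rows whose source reports a
    time-dependent component additionally yield a ``tdi`` entry with the
    TDI binding constant KI. Basis flags mark optimized constants and the
    corresponding literature values are kept as metadata.
    """
    E = Inhibition
    entries = [
        # strong CYP2C19 inhibition
        KiEntry(inhibitor="fluvoxamine", substrate="omeprazole",
                category="strong CYP2C19",
                inhibition=E(target_enzyme="CYP2C19", mechanism="competitive",
                             ki=3.6e-3, basis="in_vivo_unbound")),
        KiEntry(inhibitor="fluvoxamine", substrate="s_mephenytoin",
                category="strong CYP2C19",
                inhibition=E(target_enzyme="CYP2C19", mechanism="competitive",
                             ki=2.6e-3, basis="in_vivo_unbound")),
        # strong CYP1A2 inhibition
        KiEntry(inhibitor="fluvoxamine", substrate="caffeine",
                category="strong CYP1A2",
                inhibition=E(target_enzyme="CYP1A2", mechanism="competitive",
                             ki=2.97e-3, basis="in_vivo_unbound")),
        KiEntry(inhibitor="fluvoxamine", substrate="tizanidine",
                category="strong CYP1A2",
                inhibition=E(target_enzyme="CYP1A2", mechanism="competitive",
                             ki=0.8697e-3, basis="optimized",
                             metadata={"literature_lowest_uM": 0.9e-3})),
        KiEntry(inhibitor="fluvoxamine", substrate="mexiletine",
                category="strong CYP1A2",
                inhibition=E(target_enzyme="CYP1A2", mechanism="competitive",
                             ki=2.97e-3, basis="in_vivo_unbound")),
        # moderate CYP2C19 inhibition
        KiEntry(inhibitor="moclobemide", substrate="omeprazole",
                category="moderate CYP2C19",
                inhibition=E(target_enzyme="CYP2C19", mechanism="competitive",
                             ki=203.83, basis="in_vitro")),
        KiEntry(inhibitor="moclobemide", substrate="omeprazole",
                category="moderate CYP2C19",
                inhibition=E(target_enzyme="CYP2C19", mechanism="tdi",
                             k_i_tdi=94.85, k_inact=ILLUSTRATIVE_KINACT,
                             basis="in_vitro",
                             metadata={"k_inact_illustrative": True})),
        KiEntry(inhibitor="esomeprazole", substrate="moclobemide",
                category="moderate CYP2C19",
                inhibition=E(target_enzyme="CYP2C19", mechanism="competitive",
                             ki=3.1, basis="in_vitro")),
        KiEntry(inhibitor="esomeprazole", substrate="moclobemide",
                category="moderate CYP2C19",
                inhibition=E(target_enzyme="CYP2C19", mechanism="tdi",
                             k_i_tdi=0.3, k_inact=ILLUSTRATIVE_KINACT,
                             basis="in_vitro",
                             metadata={"k_inact_illustrative": True})),
        KiEntry(inhibitor="r_omeprazole", substrate="moclobemide",
                category="moderate CYP2C19",
                inhibition=E(target_enzyme="CYP2C19", mechanism="competitive",
                             ki=5.3, basis="in_vitro")),
        KiEntry(inhibitor="r_omeprazole", substrate="moclobemide",
                category="moderate CYP2C19",
                inhibition=E(target_enzyme="CYP2C19", mechanism="tdi",
                             k_i_tdi=1.6, k_inact=ILLUSTRATIVE_KINACT,
                             basis="in_vitro",
                             metadata={"k_inact_illustrative": True})),
        # moderate CYP1A2 inhibition
        KiEntry(inhibitor="mexiletine", substrate="caffeine",
                category="moderate CYP1A2",
                inhibition=E(target_enzyme="CYP1A2", mechanism="competitive",
                             ki=0.28, basis="in_vitro")),
        KiEntry(inhibitor="mexiletine", substrate="tizanidine",
                category="moderate CYP1A2",
                inhibition=E(target_enzyme="CYP1A2", mechanism="competitive",
                             ki=0.28, basis="in_vitro")),
        KiEntry(inhibitor="ethinylestradiol", substrate="caffeine",
                category="moderate CYP1A2",
                inhibition=E(target_enzyme="CYP1A2", mechanism="competitive",
                             ki=0.48, basis="optimized",
                             metadata={"literature_uM": 10.6})),
        KiEntry(inhibitor="ethinylestradiol", substrate="tizanidine",
                category="moderate CYP1A2",
                inhibition=E(target_enzyme="CYP1A2", mechanism="competitive",
                             ki=0.48, basis="optimized",
                             metadata={"literature_uM": 10.6})),
    ]
    return entries


def ki_for_pair(inhibitor: str, substrate: str) -> list[Inhibition]:
    """All network inhibition entries for one perpetrator→victim pair."""
    return [e.inhibition for e in builtin_ki_library()
            if e.inhibitor == inhibitor and e.substrate == substrate]


# --------------------------------------------------------------------------
# bundled illustrative drug files

def _data_dir():
    return importlib.resources.files("pbpkddi") / "data"


def builtin_drug_names() -> list[str]:
    return sorted(
        p.name[:-5] for p in _data_dir().iterdir()
        if p.name.endswith(".yaml") and not p.name.startswith("physiology"))


def load_builtin_drug(name: str) -> Drug:
    res = _data_dir() / f"{name}.yaml"
    try:
        text = res.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"no bundled drug {name!r}; available: {builtin_drug_names()}")
    return drug_from_dict(yaml.safe_load(text))
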