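"""Model constants: rat physiology and TiO2-nanoparticle chemical parameters.

The simulator is parameterized for a 0.263 kg rat.  Physiological values
(organ volumes, capillary/tissue sub-volumes, regional blood flows) and
chemical-specific values (capillary permeabilities X, tissue:blood partition
ratios P, Hill phagocytic-uptake constants, release and excretion rate
constants) are stored here with their defaults, can be overridden from a
YAML/JSON mapping of dotted names, and are validated for internal
consistency (positivity, sub-volume sums, blood-flow closure).

Units are fixed: volumes L, flows L/h, first-order rates 1/h, half-uptake
times h, masses ng; permeability and partition coefficients dimensionless.
No allometric rescaling is performed: the parameter set describes the
reference animal only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "OrganPhysiology",
    "PhysiologicalParameters",
    "OrganChemicalParameters",
    "RespiratoryParameters",
    "ParameterSet",
    "ConfigurationError",
    "ParameterValidationError",
    "default_parameters",
    "load_parameters",
    "validate_parameters",
    "serialize",
    "resolve_parameter_name",
    "PARAMETER_ALIASES",
]

SYSTEMIC_ORGANS = ("liver", "kidney", "spleen", "rob")

#: relative tolerance on the organ-flow sum (Table values are rounded)
FLOW_SUM_RTOL = 1e-3
#: slack on V_cab + V_tis <= V (printed sub-volumes sum almost exactly)
SUBVOLUME_RTOL = 1e-6


class ConfigurationError(ValueError):
    """An override document refers to an unknown parameter."""


class ParameterValidationError(ValueError):
    """A parameter set violates a structural invariant."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(violations))


@dataclass(frozen=True)
class OrganPhysiology:
    """Volumes (L) and blood flow (L/h) of one organ compartment."""

    V: float
    V_cab: float
    V_tis: float
    Q: float


@dataclass(frozen=True)
class PhysiologicalParameters:
    BW: float  # kg
    QC: float  # cardiac output, L/h
    V_ven: float
    V_art: float
    organs: Mapping[str, OrganPhysiology]  # liver, lung, kidney, spleen, rob


@dataclass(frozen=True)
class OrganChemicalParameters:
    """Chemical-specific constants of one systemic organ.

    ``K_excrete`` is the organ's excretion rate constant: for the liver it
    drains the phagocytic-cell pool to feces (hepatobiliary route), for the
    kidney it drains the tissue pool to urine; spleen and rest-of-body do
    not excrete.
    """

    X: float        # capillary-tissue permeability coefficient, dimensionless
    P: float        # tissue:blood partition ratio, dimensionless
    K_max: float    # maximal phagocytic uptake rate, 1/h
    K_50: float     # time of half-maximal uptake, h
    K_out: float    # release rate from phagocytic cells, 1/h
    K_excrete: float = 0.0  # 1/h
    n0: float = 1.0  # Hill coefficient, dimensionless


@dataclass(frozen=True)
class RespiratoryParameters:
    """Respiratory-tract transfer constants plus the lung exchange block."""

    K_upp_robtis: float   # upper airway -> rest-of-body tissue, 1/h
    K_upp_feces: float    # upper airway -> feces (swallowed), 1/h
    K_trach_feces: float  # tracheobronchial -> feces (mucociliary), 1/h
    K_alvpcs_trach: float  # alveolar PCs -> tracheobronchial, 1/h
    K_alv_inter: float    # alveolar surface -> interstitium, 1/h
    K_inter_alv: float    # interstitium -> alveolar surface, 1/h
    K_alvmax: float       # alveolar Hill uptake: maximal rate, 1/h
    K_alv50: float        # alveolar Hill uptake: half time, h
    K_alvout: float       # alveolar PC release, 1/h
    K_inter_max: float    # interstitial Hill uptake: maximal rate, 1/h
    K_inter50: float      # interstitial Hill uptake: half time, h
    K_interout: float     # interstitial PC release, 1/h
    P_lu: float           # lung tissue:blood partition ratio
    X_lu: float           # lung capillary-tissue permeability
    n0_alv: float = 1.0
    n0_inter: float = 1.0


@dataclass(frozen=True)
class ParameterSet:
    physiological: PhysiologicalParameters
    chemical: Mapping[str, OrganChemicalParameters]  # systemic organs
    respiratory: RespiratoryParameters

    def to_flat(self) -> dict[str, float]:
        return serialize(self)

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        flat = serialize(self)
        for key, value in overrides.items():
            key = resolve_parameter_name(key)
            if key not in flat:
                raise ConfigurationError(f"unknown parameter {key!r}")
            flat[key] = float(value)
        return _from_flat(flat)

    def get(self, name: str) -> float:
        return serialize(self)[resolve_parameter_name(name)]

    def fingerprint(self) -> str:
        payload = json.dumps(serialize(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_parameters() -> ParameterSet:
    """The reference rat parameter set (0.263 kg animal).

    Hill coefficients default to 1 for every organ and lung region; they are
    ordinary overridable parameters (``chemical.<organ>.n0``,
    ``respiratory.n0_alv``, ``respiratory.n0_inter``).
    """
    physiological = PhysiologicalParameters(
        BW=0.263,
        QC=6.0345,
        V_ven=0.0106,
        V_art=0.0025,
        organs={
            "liver": OrganPhysiology(V=0.00983, V_cab=0.00023, V_tis=0.0096, Q=1.05),
            "lung": OrganPhysiology(V=0.00167, V_cab=0.00047, V_tis=0.0012, Q=6.0345),
            "kidney": OrganPhysiology(V=0.00221, V_cab=0.00031, V_tis=0.0019, Q=0.8509),
            "spleen": OrganPhysiology(V=0.00065, V_cab=0.00012, V_tis=0.00053, Q=0.0736),
            "rob": OrganPhysiology(V=0.2613, V_cab=0.0102, V_tis=0.2511, Q=4.06),
        },
    )
    chemical = {
        "liver": OrganChemicalParameters(
            X=489.2806, P=47.4101, K_max=263.8254, K_50=0.3592,
            K_out=19.4813, K_excrete=0.0884,
        ),
        "spleen": OrganChemicalParameters(
            X=130.1283, P=150.0, K_max=240.0, K_50=1000.0, K_out=0.9507,
        ),
        "kidney": OrganChemicalParameters(
            X=0.0199, P=209.0, K_max=0.9929, K_50=13.6432,
            K_out=20.0, K_excrete=0.00005,
        ),
        "rob": OrganChemicalParameters(
            X=0.0001, P=10.8944, K_max=0.000001, K_50=0.008, K_out=0.00005,
        ),
    }
    respiratory = RespiratoryParameters(
        K_upp_robtis=0.05,
        K_upp_feces=0.008,
        K_trach_feces=0.3099,
        K_alvpcs_trach=8.3465,
        K_alv_inter=0.353,
        K_inter_alv=0.09,
        K_alvmax=0.000004,
        K_alv50=202.1309,
        K_alvout=0.0109,
        K_inter_max=0.000050504,
        K_inter50=628.416,
        K_interout=0.0672,
        P_lu=30359.0,
        X_lu=49.1745,
    )
    return ParameterSet(physiological, chemical, respiratory)


#: Field-notation shorthands accepted wherever a dotted parameter name is.
PARAMETER_ALIASES: dict[str, str] = {
    "P_lu": "respiratory.P_lu",
    "X_lu": "respiratory.X_lu",
    "K_alv_inter": "respiratory.K_alv_inter",
    "K_inter_alv": "respiratory.K_inter_alv",
    "K_alvout": "respiratory.K_alvout",
    "K_alvmax": "respiratory.K_alvmax",
    "K_trach_feces": "respiratory.K_trach_feces",
    "K_alvpcs_trach": "respiratory.K_alvpcs_trach",
    "P_li": "chemical.liver.P",
    "X_li": "chemical.liver.X",
    "K_limax": "chemical.liver.K_max",
    "K_liout": "chemical.liver.K_out",
    "K_lipcs_feces": "chemical.liver.K_excrete",
    "P_ki": "chemical.kidney.P",
    "X_ki": "chemical.kidney.X",
    "K_kid_urine": "chemical.kidney.K_excrete",
    "P_spl": "chemical.spleen.P",
    "X_spl": "chemical.spleen.X",
    "K_splout": "chemical.spleen.K_out",
    "P_rob": "chemical.rob.P",
    "X_rob": "chemical.rob.X",
}


def resolve_parameter_name(name: str) -> str:
    """Map a shorthand like ``P_lu`` to its dotted path; dotted names pass through."""
    return PARAMETER_ALIASES.get(name, name)


def serialize(params: ParameterSet) -> dict[str, float]:
    """Flatten a parameter set into a dotted-name -> value mapping."""
    flat: dict[str, float] = {}
    phys = params.physiological
    flat["physiological.BW"] = phys.BW
    flat["physiological.QC"] = phys.QC
    flat["physiological.V_ven"] = phys.V_ven
    flat["physiological.V_art"] = phys.V_art
    for organ, op in phys.organs.items():
        for f in dataclasses.fields(op):
            flat[f"physiological.{organ}.{f.name}"] = getattr(op, f.name)
    for organ, oc in params.chemical.items():
        for f in dataclasses.fields(oc):
            flat[f"chemical.{organ}.{f.name}"] = getattr(oc, f.name)
    for f in dataclasses.fields(params.respiratory):
        flat[f"respiratory.{f.name}"] = getattr(params.respiratory, f.name)
    return flat


def _from_flat(flat: Mapping[str, float]) -> ParameterSet:
    organs = {}
    for organ in ("liver", "lung", "kidney", "spleen", "rob"):
        organs[organ] = OrganPhysiology(
            **{f.name: flat[f"physiological.{organ}.{f.name}"]
               for f in dataclasses.fields(OrganPhysiology)}
        )
    phys = PhysiologicalParameters(
        BW=flat["physiological.BW"], QC=flat["physiological.QC"],
        V_ven=flat["physiological.V_ven"], V_art=flat["physiological.V_art"],
        organs=organs,
    )
    chemical = {
        organ: OrganChemicalParameters(
            **{f.name: flat[f"chemical.{organ}.{f.name}"]
               for f in dataclasses.fields(OrganChemicalParameters)}
        )
        for organ in SYSTEMIC_ORGANS
    }
    respiratory = RespiratoryParameters(
        **{f.name: flat[f"respiratory.{f.name}"]
           for f in dataclasses.fields(RespiratoryParameters)}
    )
    return ParameterSet(phys, chemical, respiratory)


def load_parameters(source: Mapping[str, float] | str | Path | None = None) -> ParameterSet:
    """Defaults overridden by a mapping or a YAML/JSON file of dotted names.

    Raises :class:`ConfigurationError` for unknown keys and
    :class:`ParameterValidationError` if the overridden set breaks an
    invariant (e.g. a non-positive value where positivity is required).
    """
    overrides: Mapping[str, float]
    if source is None:
        overrides = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            loaded = yaml.safe_load(fh)  # YAML is a JSON superset
        overrides = loaded or {}
    else:
        overrides = source
    if not isinstance(overrides, Mapping):
        raise ConfigurationError("parameter document must be a mapping of dotted names")
    params = default_parameters().with_overrides(overrides)
    violations = validate_parameters(params)
    if violations:
        raise ParameterValidationError(violations)
    return params


def validate_parameters(params: ParameterSet) -> list[str]:
    """Check every structural invariant; return human-readable violations."""
    v: list[str] = []
    phys = params.physiological

    for name in ("BW", "QC", "V_ven", "V_art"):
        if not getattr(phys, name) > 0:
            v.append(f"physiological.{name} must be strictly positive")
    for organ, op in phys.organs.items():
        for fname in ("V", "V_cab", "V_tis", "Q"):
            if not getattr(op, fname) > 0:
                v.append(f"physiological.{organ}.{fname} must be strictly positive")
        if op.V_cab + op.V_tis > op.V * (1 + SUBVOLUME_RTOL):
            v.append(
                f"physiological.{organ}: V_cab + V_tis = {op.V_cab + op.V_tis:g} "
                f"exceeds organ volume V = {op.V:g}"
            )

    flow_sum = sum(phys.organs[o].Q for o in SYSTEMIC_ORGANS)
    if abs(flow_sum - phys.QC) > FLOW_SUM_RTOL * phys.QC:
        v.append(
            f"systemic organ flows sum to {flow_sum:g} L/h, "
            f"not cardiac output QC = {phys.QC:g} L/h"
        )
    if abs(phys.organs["lung"].Q - phys.QC) > FLOW_SUM_RTOL * phys.QC:
        v.append("lung blood flow must equal cardiac output QC")

    for organ, oc in params.chemical.items():
        prefix = f"chemical.{organ}"
        if oc.X < 0:
            v.append(f"{prefix}.X must be non-negative")
        for fname in ("P", "K_50", "n0"):
            if not getattr(oc, fname) > 0:
                v.append(f"{prefix}.{fname} must be strictly positive")
        for fname in ("K_max", "K_out", "K_excrete"):
            if getattr(oc, fname) < 0:
                v.append(f"{prefix}.{fname} must be non-negative")

    resp = params.respiratory
    strictly_positive = ("P_lu", "K_alv50", "K_inter50", "n0_alv", "n0_inter")
    for f in dataclasses.fields(resp):
        if f.name in strictly_positive:
            if not getattr(resp, f.name) > 0:
                v.append(f"respiratory.{f.name} must be strictly positive")
        elif getattr(resp, f.name) < 0:
            v.append(f"respiratory.{f.name} must be non-negative")
    return v
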