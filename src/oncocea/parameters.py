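"""Typed model inputs, bundled subgroup fixtures, YAML IO and validation.

Every input the decision model consumes is represented here: the fitted
Weibull laws per endpoint and arm, adverse-event risks, utilities, unit
costs, the patient profile used for weight-based dosing, cycle/horizon
settings and the probabilistic-sensitivity distribution of each parameter.
One fixture file per molecular subgroup (overall, BRCA-mutated,
HRD-positive, HRD-positive/BRCA-wild-type) is bundled under
``oncocea/fixtures``; the YAML schema mirrors these types field for field.

Parameters are addressed throughout the package by dotted paths rooted at
one of ``econ``, ``patient``, ``settings``, ``intervention`` or
``comparator`` — e.g. ``econ.utility_pfs``, ``intervention.ae_risks.fatigue``
or ``comparator.pfs.scale``.  ``intervention.utility_pfs`` resolves to the
arm override when set and to the shared economic utility otherwise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from .errors import FormatError, ValidationError
from .survival import SurvivalSpec

SUBGROUPS = ("overall", "brca_mut", "hrd_pos", "hrd_pos_brca_wt")

PSA_FAMILIES = ("beta", "gamma", "normal", "uniform", "fixed")


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    message: str


@dataclass(frozen=True)
class PatientProfile:
    """Reference patient used to rescale weight-based drug pricing."""

    body_weight: float = 70.0
    body_surface_area: float = 1.84
    serum_creatinine: float = 1.0


@dataclass(frozen=True)
class ModelSettings:
    """Cycle/horizon bookkeeping and the state-transition clock convention.

    ``os_clock`` selects how the fitted OS law drives the death process:
    ``"progression"`` restarts the OS clock when a patient enters the
    progressed state (the convention that replicates the source analysis),
    ``"model_start"`` reads death straight off the OS curve from
    randomisation (classic partitioned survival).
    """

    cycle_length_days: float = 21.0
    horizon_years: float = 15.0
    half_cycle_correction: bool = True
    os_clock: str = "progression"

    def __post_init__(self):
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be positive")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if self.os_clock not in ("progression", "model_start"):
            raise ValueError("os_clock must be 'progression' or 'model_start'")


@dataclass(frozen=True)
class EconomicInputs:
    utility_pfs: float
    utility_pd: float
    disutilities: Mapping[str, float]
    admin_cost_per_cycle: float
    lab_cost_per_cycle: float
    imaging_cost_per_cycle: float
    brca_test_cost: float
    hrd_test_cost: float
    second_line_drug_cost_per_cycle: float
    second_line_duration_cycles: int
    bsc_cost_per_cycle: float
    terminal_care_cost: float
    discount_rate_annual: float
    wtp_per_qaly: float


@dataclass(frozen=True)
class ArmParams:
    """One strategy arm: survival laws, drug prices/caps, AE burden."""

    name: str
    pfs: SurvivalSpec
    os: SurvivalSpec
    olaparib_cost_per_cycle: float
    bevacizumab_cost_per_cycle: float
    olaparib_max_cycles: int
    bevacizumab_max_cycles: int
    ae_risks: Mapping[str, float]
    ae_management_cost: float
    second_line_proportion: float
    # optional arm-specific utility overrides (None -> shared econ values);
    # the published one-/two-way analyses vary PFS utility per arm.
    utility_pfs: Optional[float] = None
    utility_pd: Optional[float] = None

    @property
    def drug_cost_per_cycle(self) -> float:
        """Sum of maintenance-agent prices while both are active."""
        return self.olaparib_cost_per_cycle + self.bevacizumab_cost_per_cycle


@dataclass(frozen=True)
class PsaParameterSpec:
    """Distribution assigned to one parameter path for the PSA.

    ``name`` may join several dotted paths with ``|`` when a single price
    must move identically in both arms (e.g. the bevacizumab unit cost).
    """

    name: str
    family: str
    mean: float
    low: float
    high: float

    def __post_init__(self):
        if self.family not in PSA_FAMILIES:
            raise ValueError(f"unknown PSA family {self.family!r}")

    @property
    def paths(self) -> tuple[str, ...]:
        return tuple(p.strip() for p in self.name.split("|"))


@dataclass(frozen=True)
class AnalysisInputs:
    subgroup: str
    intervention: ArmParams
    comparator: ArmParams
    econ: EconomicInputs
    patient: PatientProfile = field(default_factory=PatientProfile)
    settings: ModelSettings = field(default_factory=ModelSettings)
    psa_specs: tuple[PsaParameterSpec, ...] = ()

    @property
    def arms(self) -> dict[str, ArmParams]:
        return {"intervention": self.intervention, "comparator": self.comparator}


# ---------------------------------------------------------------------------
# dotted-path access
# ---------------------------------------------------------------------------

_ROOTS = ("econ", "patient", "settings", "intervention", "comparator")

# arm fields that fall back to the shared economic inputs when unset
_ARM_UTILITY_FALLBACK = {"utility_pfs", "utility_pd"}


def get_param(inputs: AnalysisInputs, path: str) -> float:
    """Resolve a dotted parameter path to its effective numeric value."""
    parts = path.split(".")
    if parts[0] not in _ROOTS:
        raise KeyError(f"unknown parameter root in {path!r}")
    obj = getattr(inputs, parts[0])
    if (
        parts[0] in ("intervention", "comparator")
        and len(parts) == 2
        and parts[1] in _ARM_UTILITY_FALLBACK
    ):
        override = getattr(obj, parts[1])
        return getattr(inputs.econ, parts[1]) if override is None else override
    for key in parts[1:]:
        if isinstance(obj, Mapping):
            obj = obj[key]
        elif dataclasses.is_dataclass(obj) and key in {f.name for f in dataclasses.fields(obj)}:
            obj = getattr(obj, key)
        else:
            raise KeyError(f"cannot resolve {key!r} while reading {path!r}")
    if not isinstance(obj, (int, float, bool)):
        raise KeyError(f"{path!r} does not name a numeric parameter")
    return obj


def set_param(inputs: AnalysisInputs, path: str, value) -> AnalysisInputs:
    """Return a copy of ``inputs`` with the parameter at ``path`` replaced."""

    def _set(obj, parts):
        key = parts[0]
        if isinstance(obj, Mapping):
            if key not in obj:
                raise KeyError(f"cannot resolve {key!r} while writing {path!r}")
            if len(parts) > 1:
                raise KeyError(f"path continues past mapping leaf in {path!r}")
            new = dict(obj)
            new[key] = value
            return new
        if not dataclasses.is_dataclass(obj) or key not in {f.name for f in dataclasses.fields(obj)}:
            raise KeyError(f"cannot resolve {key!r} while writing {path!r}")
        if len(parts) == 1:
            return replace(obj, **{key: value})
        return replace(obj, **{key: _set(getattr(obj, key), parts[1:])})

    parts = path.split(".")
    if parts[0] not in _ROOTS:
        raise KeyError(f"unknown parameter root in {path!r}")
    get_param(inputs, path)  # raise early on unresolvable paths
    return replace(inputs, **{parts[0]: _set(getattr(inputs, parts[0]), parts[1:])})


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _spec_to_dict(s: SurvivalSpec) -> dict:
    return {"family": s.family, "scale": s.scale, "shape": s.shape}


def _arm_to_dict(a: ArmParams) -> dict:
    d = {
        "name": a.name,
        "pfs": _spec_to_dict(a.pfs),
        "os": _spec_to_dict(a.os),
        "olaparib_cost_per_cycle": a.olaparib_cost_per_cycle,
        "bevacizumab_cost_per_cycle": a.bevacizumab_cost_per_cycle,
        "olaparib_max_cycles": a.olaparib_max_cycles,
        "bevacizumab_max_cycles": a.bevacizumab_max_cycles,
        "ae_risks": dict(a.ae_risks),
        "ae_management_cost": a.ae_management_cost,
        "second_line_proportion": a.second_line_proportion,
    }
    if a.utility_pfs is not None:
        d["utility_pfs"] = a.utility_pfs
    if a.utility_pd is not None:
        d["utility_pd"] = a.utility_pd
    return d


def inputs_to_dict(inputs: AnalysisInputs) -> dict:
    return {
        "subgroup": inputs.subgroup,
        "settings": dataclasses.asdict(inputs.settings),
        "patient": dataclasses.asdict(inputs.patient),
        "econ": {**dataclasses.asdict(inputs.econ),
                 "disutilities": dict(inputs.econ.disutilities)},
        "arms": {
            "intervention": _arm_to_dict(inputs.intervention),
            "comparator": _arm_to_dict(inputs.comparator),
        },
        "psa": [dataclasses.asdict(s) for s in inputs.psa_specs],
    }


def _require(mapping, key, context):
    if key not in mapping:
        raise FormatError(f"missing required field {key!r} in {context}")
    return mapping[key]


def dict_to_inputs(data: Mapping) -> AnalysisInputs:
    if not isinstance(data, Mapping):
        raise FormatError("parameter file must parse to a mapping at top level")
    try:
        settings = ModelSettings(**dict(data.get("settings", {})))
        patient = PatientProfile(**dict(data.get("patient", {})))
        econ = EconomicInputs(**dict(_require(data, "econ", "top level")))
        arms = _require(data, "arms", "top level")
        arm_objs = {}
        for role in ("intervention", "comparator"):
            raw = dict(_require(arms, role, "arms"))
            for endpoint in ("pfs", "os"):
                raw[endpoint] = SurvivalSpec(**dict(_require(raw, endpoint, f"arms.{role}")))
            arm_objs[role] = ArmParams(**raw)
        psa = tuple(PsaParameterSpec(**dict(s)) for s in data.get("psa", []))
    except FormatError:
        raise
    except TypeError as exc:
        raise FormatError(f"unexpected or missing field: {exc}") from exc
    return AnalysisInputs(
        subgroup=_require(data, "subgroup", "top level"),
        intervention=arm_objs["intervention"],
        comparator=arm_objs["comparator"],
        econ=econ,
        patient=patient,
        settings=settings,
        psa_specs=psa,
    )


def save_inputs(inputs: AnalysisInputs, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(inputs_to_dict(inputs), fh, sort_keys=False)


def load_inputs(path) -> AnalysisInputs:
    """Read and validate a structured parameter file.

    Parse failures raise :class:`FormatError`; invariant violations raise
    :class:`ValidationError` listing every failed check at once.
    """
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    inputs = dict_to_inputs(data)
    errors = [f for f in validate_inputs(inputs) if f.severity == "error"]
    if errors:
        raise ValidationError(errors)
    return inputs


def builtin_inputs(subgroup: str) -> AnalysisInputs:
    """The bundled fixture for one molecular subgroup.

    Fixture values are carried digit for digit as printed in the source
    tables, including the two HRD PFS rows whose shape is printed equal to
    the scale (flagged by :func:`validate_inputs` as almost certainly a
    typographical corruption).
    """
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}")
    ref = resources.files("oncocea").joinpath(f"fixtures/{subgroup}.yaml")
    with resources.as_file(ref) as p:
        return load_inputs(p)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check_prob(findings, value, label):
    if not 0.0 <= value <= 1.0:
        findings.append(Finding("error", f"{label} = {value} outside [0, 1]"))


def _check_cost(findings, value, label):
    if value < 0:
        findings.append(Finding("error", f"{label} = {value} is negative"))


def validate_inputs(inputs: AnalysisInputs) -> list[Finding]:
    """Invariant checks (errors) plus suspicious-value heuristics (warnings).

    Never raises and never mutates: findings are the return value.  Warnings
    cover parameter patterns known to indicate corrupted source values —
    a survival shape numerically equal to its scale, an implausibly small
    shape (< 0.1), and a PSA range that fails to bracket its mean.
    """
    f: list[Finding] = []
    econ = inputs.econ
    if inputs.subgroup not in SUBGROUPS:
        f.append(Finding("error", f"unknown subgroup {inputs.subgroup!r}"))
    _check_prob(f, econ.utility_pfs, "econ.utility_pfs")
    _check_prob(f, econ.utility_pd, "econ.utility_pd")
    if econ.utility_pd > econ.utility_pfs:
        f.append(Finding("error", "utility_pd exceeds utility_pfs"))
    for name, d in econ.disutilities.items():
        if d < 0:
            f.append(Finding("error", f"disutility {name} is negative"))
    for label in ("admin_cost_per_cycle", "lab_cost_per_cycle", "imaging_cost_per_cycle",
                  "brca_test_cost", "hrd_test_cost", "second_line_drug_cost_per_cycle",
                  "bsc_cost_per_cycle", "terminal_care_cost"):
        _check_cost(f, getattr(econ, label), f"econ.{label}")
    if not 0.0 <= econ.discount_rate_annual <= 1.0:
        f.append(Finding("error", "discount_rate_annual outside [0, 1]"))
    if econ.second_line_duration_cycles < 0:
        f.append(Finding("error", "second_line_duration_cycles is negative"))

    for role, arm in inputs.arms.items():
        _check_prob(f, arm.second_line_proportion, f"{role}.second_line_proportion")
        for name, r in arm.ae_risks.items():
            _check_prob(f, r, f"{role}.ae_risks.{name}")
        for label in ("olaparib_cost_per_cycle", "bevacizumab_cost_per_cycle",
                      "ae_management_cost"):
            _check_cost(f, getattr(arm, label), f"{role}.{label}")
        for cap in ("olaparib_max_cycles", "bevacizumab_max_cycles"):
            if getattr(arm, cap) < 0:
                f.append(Finding("error", f"{role}.{cap} is negative"))
        for endpoint in ("pfs", "os"):
            spec = getattr(arm, endpoint)
            if math.isclose(spec.shape, spec.scale, rel_tol=0.0, abs_tol=0.0):
                f.append(Finding(
                    "warning",
                    f"{role}.{endpoint} shape equals scale ({spec.shape}): "
                    "likely a corrupted printed value",
                ))
            if spec.shape < 0.1:
                f.append(Finding(
                    "warning",
                    f"{role}.{endpoint} shape {spec.shape} < 0.1 is implausible "
                    "for a fitted time-to-event law",
                ))

    for spec in inputs.psa_specs:
        label = f"psa[{spec.name}]"
        if not spec.low <= spec.mean <= spec.high:
            f.append(Finding("warning", f"{label} range does not bracket the mean"))
        if spec.family == "beta" and not (0.0 <= spec.low and spec.high <= 1.0):
            f.append(Finding("error", f"{label} beta range outside [0, 1]"))
        for path in spec.paths:
            try:
                get_param(inputs, path)
            except KeyError:
                f.append(Finding("error", f"{label} does not resolve to a parameter"))
    return f
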