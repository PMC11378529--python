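"""Six-area monoaminergic circuit model.

The state vector collects the average activation frequency (Hz) of six brain
areas — globus pallidus (GP), the two striatal medium-spiny populations
(StrD1, StrD2), the merged substantia nigra pars compacta / ventral tegmental
area complex (SNcVTA, dopamine source), the dorsal raphe nucleus (DRN,
serotonin source) and the locus coeruleus (LC, noradrenaline source).  Each
area obeys a first-order rate equation

    dy_a/dt = -y_a / tau_a  +/-  sum_s alpha_a^s y_s  (+ beta_SNcVTA^LC LC^2)
              + alpha_a^ext

with a leak toward rest, signed linear couplings along the anatomical
projections, a single quadratic term expressing the mixed
excitatory/inhibitory action of noradrenaline on SNcVTA, and a constant
external drive standing in for all unmodeled input.  In matrix form,

    dy/dt = A y + C (y o y) + b

where ``o`` is the Hadamard product, A carries the leaks (-1/tau on the
diagonal) and signed couplings, C has the single beta entry, and b the
external drives.

Coupling coefficients are stored unsigned (they are all positive rate
constants); the projection signs are fixed by the circuit diagram and live in
the matrix assembler.  Units: tau in s, alpha couplings in Hz, external
drives in Hz/s, beta dimensionless.

Lesioned and treated states of a subject are overlays: replacement values for
the free parameters of the lesioned area's equation only, applied on top of
the healthy (SHAM) parameter set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .constants import F_MAX_HZ

__all__ = [
    "AREAS",
    "AREA_INDEX",
    "COUPLING_SIGNS",
    "BETA_KEY",
    "PARAM_KEYS",
    "TAU_KEYS",
    "CONDITIONS",
    "LESIONS",
    "FITTED_CONDITIONS",
    "COMBINED_LESIONS",
    "TREATMENT_FREE",
    "FREE_PARAMS",
    "ModelValidationError",
    "ConditionError",
    "ParameterSet",
    "ModelMatrices",
    "SubjectModel",
    "alpha_key",
    "ext_key",
    "tau_key",
    "free_parameter_keys",
    "assemble_matrices",
    "rhs",
    "apply_condition",
    "is_physical",
    "dimensional_audit",
]

#: Fixed state ordering of the six modeled areas.
AREAS: tuple[str, ...] = ("GP", "StrD1", "StrD2", "SNcVTA", "DRN", "LC")
AREA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AREAS)}

#: Signed linear projections (target, source) -> sign.  Positive couplings
#: are excitatory, negative inhibitory; the coefficients themselves are
#: stored unsigned.
COUPLING_SIGNS: dict[tuple[str, str], int] = {
    ("GP", "StrD1"): -1,
    ("GP", "StrD2"): -1,
    ("GP", "DRN"): +1,
    ("StrD1", "SNcVTA"): +1,
    ("StrD1", "DRN"): +1,
    ("StrD2", "SNcVTA"): -1,
    ("StrD2", "DRN"): +1,
    ("SNcVTA", "DRN"): -1,
    ("SNcVTA", "LC"): -1,
    ("DRN", "SNcVTA"): -1,
    ("DRN", "LC"): +1,
    ("LC", "SNcVTA"): +1,
    ("LC", "DRN"): -1,
}

#: The single quadratic coupling: noradrenaline acting on SNcVTA.
BETA_EDGE: tuple[str, str] = ("SNcVTA", "LC")
BETA_KEY = "beta.SNcVTA.LC"


def alpha_key(target: str, source: str) -> str:
    return f"alpha.{target}.{source}"


def ext_key(area: str) -> str:
    return f"alpha.{area}.ext"


def tau_key(area: str) -> str:
    return f"tau.{area}"


def _equation_keys(area: str) -> tuple[str, ...]:
    keys = [alpha_key(area, s) for (t, s) in COUPLING_SIGNS if t == area]
    if area == BETA_EDGE[0]:
        keys.append(BETA_KEY)
    keys.append(ext_key(area))
    return tuple(keys)


#: Canonical ordering of the 20 rate parameters (equation by equation).
PARAM_KEYS: tuple[str, ...] = tuple(k for a in AREAS for k in _equation_keys(a))
TAU_KEYS: tuple[str, ...] = tuple(tau_key(a) for a in AREAS)
ALL_KEYS: tuple[str, ...] = PARAM_KEYS + TAU_KEYS

#: Condition labels.
LESIONS: tuple[str, ...] = ("LDA", "L5HT", "LNE")
FITTED_CONDITIONS: tuple[str, ...] = ("SHAM",) + LESIONS
COMBINED_LESIONS: dict[str, tuple[str, ...]] = {
    "LDA+L5HT": ("LDA", "L5HT"),
    "LDA+LNE": ("LDA", "LNE"),
}
EXPERIMENT_CONDITIONS: tuple[str, ...] = FITTED_CONDITIONS + tuple(COMBINED_LESIONS)
TREATMENT_BASE = "LDA"
TREATMENT_FREE: dict[str, tuple[str, ...]] = {
    "LDA+cLC": (ext_key("LC"),),
    "LDA+cDRN": (ext_key("DRN"),),
    "LDA+cCOMB": (ext_key("LC"), ext_key("DRN")),
}
CONDITIONS: tuple[str, ...] = EXPERIMENT_CONDITIONS + tuple(TREATMENT_FREE)

#: Free-parameter subsets per fitted condition.  SHAM frees every rate
#: parameter (20); each lesion frees exactly the lesioned area's equation.
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "SHAM": PARAM_KEYS,
    "LDA": _equation_keys("SNcVTA"),
    "L5HT": _equation_keys("DRN"),
    "LNE": _equation_keys("LC"),
}


class ModelValidationError(ValueError):
    """A parameter set or matrix violates the model invariants."""


class ConditionError(ValueError):
    """A condition label is unknown or its overlay is missing."""


def free_parameter_keys(condition: str) -> tuple[str, ...]:
    """Free-parameter keys optimized for ``condition`` (empty for combined)."""
    if condition in FREE_PARAMS:
        return FREE_PARAMS[condition]
    if condition in COMBINED_LESIONS:
        return ()
    if condition in TREATMENT_FREE:
        return TREATMENT_FREE[condition]
    raise ConditionError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class ParameterSet:
    """All rate parameters and time constants of one condition of one subject.

    ``values`` maps flat keys (``"alpha.GP.StrD1"``, ``"alpha.GP.ext"``,
    ``"beta.SNcVTA.LC"``, ``"tau.GP"``) to floats in the units stated in the
    module docstring.
    """

    values: Mapping[str, float]
    condition: str = "SHAM"

    def __post_init__(self) -> None:
        vals = {str(k): float(v) for k, v in dict(self.values).items()}
        missing = set(ALL_KEYS) - set(vals)
        extra = set(vals) - set(ALL_KEYS)
        if missing or extra:
            raise ModelValidationError(
                f"parameter keys mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        for k, v in vals.items():
            if not np.isfinite(v):
                raise ModelValidationError(f"{k} is not finite: {v}")
            if k.startswith("tau."):
                if v <= 0:
                    raise ModelValidationError(f"{k} must be > 0, got {v}")
            elif v < 0:
                raise ModelValidationError(f"{k} must be >= 0, got {v}")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(ALL_KEYS)

    def alpha(self, target: str, source: str) -> float:
        return self.values[alpha_key(target, source)]

    def ext(self, area: str) -> float:
        return self.values[ext_key(area)]

    @property
    def beta(self) -> float:
        return self.values[BETA_KEY]

    @property
    def tau(self) -> np.ndarray:
        """Time constants in seconds, in area order."""
        return np.array([self.values[tau_key(a)] for a in AREAS])

    def replace(self, overlay: Mapping[str, float], condition: str | None = None) -> "ParameterSet":
        """Return a copy with ``overlay`` rate parameters substituted.

        Time constants are not overlayable: lesions are assumed not to alter
        the neuron-type time constants.
        """
        bad = set(overlay) - set(PARAM_KEYS)
        if bad:
            raise ModelValidationError(f"cannot overlay keys {sorted(bad)}")
        vals = dict(self.values)
        vals.update({k: float(v) for k, v in overlay.items()})
        return ParameterSet(vals, condition or self.condition)

    @classmethod
    def from_components(
        cls,
        tau_s: Mapping[str, float],
        alphas: Mapping[tuple[str, str], float] | None = None,
        exts: Mapping[str, float] | None = None,
        beta: float = 0.0,
        condition: str = "SHAM",
    ) -> "ParameterSet":
        """Build a set from per-edge couplings, drives and time constants (s)."""
        alphas = dict(alphas or {})
        exts = dict(exts or {})
        vals: dict[str, float] = {BETA_KEY: beta}
        for edge in COUPLING_SIGNS:
            vals[alpha_key(*edge)] = alphas.pop(edge, 0.0)
        if alphas:
            raise ModelValidationError(f"not edges of the circuit: {sorted(alphas)}")
        for a in AREAS:
            vals[ext_key(a)] = exts.get(a, 0.0)
            vals[tau_key(a)] = tau_s[a]
        return cls(vals, condition)

    def to_dict(self) -> dict[str, float]:
        return dict(self.values)

    def to_json(self, path=None) -> str:
        doc = {"condition": self.condition, "values": self.to_dict()}
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "ParameterSet":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        doc = json.loads(text)
        return cls(doc["values"], doc.get("condition", "SHAM"))


@dataclass(frozen=True)
class ModelMatrices:
    """The (A, C, b) triple of the matrix form dy/dt = A y + C (y o y) + b."""

    A: np.ndarray
    C: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        C = np.asarray(self.C, dtype=float)
        b = np.asarray(self.b, dtype=float)
        n = len(AREAS)
        if A.shape != (n, n) or C.shape != (n, n) or b.shape != (n,):
            raise ModelValidationError("matrix shapes must be (6,6),(6,6),(6,)")
        if np.any(np.diag(A) >= 0):
            raise ModelValidationError("A diagonal must be strictly negative")
        if np.count_nonzero(C) > 1:
            raise ModelValidationError("C admits at most one nonzero entry")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "b", b)


def assemble_matrices(params: ParameterSet) -> ModelMatrices:
    """Assemble (A, C, b) from a parameter set, applying the circuit signs."""
    n = len(AREAS)
    A = np.zeros((n, n))
    C = np.zeros((n, n))
    b = np.zeros(n)
    tau = params.tau
    for i in range(n):
        A[i, i] = -1.0 / tau[i]
        b[i] = params.ext(AREAS[i])
    for (t, s), sign in COUPLING_SIGNS.items():
        A[AREA_INDEX[t], AREA_INDEX[s]] = sign * params.alpha(t, s)
    C[AREA_INDEX[BETA_EDGE[0]], AREA_INDEX[BETA_EDGE[1]]] = params.beta
    return ModelMatrices(A, C, b)


def rhs(y: np.ndarray, m: ModelMatrices) -> np.ndarray:
    """Time derivative A y + C (y o y) + b, in Hz/s."""
    y = np.asarray(y, dtype=float)
    return m.A @ y + m.C @ (y * y) + m.b


def is_physical(y: np.ndarray, fmax: float = F_MAX_HZ) -> bool:
    """A state is physically valid iff every rate lies in [0, fmax]."""
    y = np.asarray(y, dtype=float)
    return bool(np.all(np.isfinite(y)) and np.all(y >= 0.0) and np.all(y <= fmax))


@dataclass
class SubjectModel:
    """A subject: healthy base parameters plus per-condition overlays.

    Overlays hold replacement values only for the free parameters of the
    respective condition; combined lesions carry no overlay of their own and
    are built by sequential application of the atomic overlays.
    """

    subject_id: str
    base: ParameterSet
    overlays: dict[str, dict[str, float]] = field(default_factory=dict)

    def with_overlay(self, condition: str, overlay: Mapping[str, float]) -> "SubjectModel":
        allowed = free_parameter_keys(condition)
        if not allowed:
            raise ConditionError(
                f"{condition!r} has no free parameters; overlays are not allowed"
            )
        bad = set(overlay) - set(allowed)
        if bad:
            raise ModelValidationError(
                f"overlay keys {sorted(bad)} are not free parameters of {condition!r}"
            )
        new = dict(self.overlays)
        new[condition] = {k: float(v) for k, v in overlay.items()}
        return SubjectModel(self.subject_id, self.base, new)


def _overlay_chain(condition: str) -> tuple[str, ...]:
    if condition == "SHAM":
        return ()
    if condition in LESIONS:
        return (condition,)
    if condition in COMBINED_LESIONS:
        return COMBINED_LESIONS[condition]
    if condition in TREATMENT_FREE:
        return (TREATMENT_BASE, condition)
    raise ConditionError(f"unknown condition {condition!r}")


def apply_condition(subject: SubjectModel, condition: str) -> ParameterSet:
    """Parameter set of ``subject`` under ``condition``.

    Atomic lesions replace exactly their free parameters; combined conditions
    apply the relevant atomic overlays in order; treatments stack the
    stimulation overlay on top of the dopaminergic lesion.
    """
    params = subject.base
    for label in _overlay_chain(condition):
        try:
            overlay = subject.overlays[label]
        except KeyError:
            raise ConditionError(
                f"subject {subject.subject_id!r} has no overlay for {label!r} "
                f"(required by condition {condition!r})"
            ) from None
        params = params.replace(overlay)
    return ParameterSet(params.values, condition)


# Dimensional audit ---------------------------------------------------------

#: Unit of each quantity expressed as the exponent of seconds
#: (Hz = s^-1, Hz/s = s^-2, dimensionless = 0).
_SECONDS_EXPONENT = {"tau": 1, "alpha": -1, "ext": -2, "beta": 0, "state": -1}


def dimensional_audit(params: ParameterSet) -> None:
    """Verify that every term of every equation comes out in Hz/s.

    Raises :class:`ModelValidationError` if any term's unit deviates; this is
    a static check of the parameter unit conventions, independent of values.
    """
    target = -2  # Hz/s
    for a in AREAS:
        terms = {
            f"-{tau_key(a)}^-1 * {a}": -_SECONDS_EXPONENT["tau"] + _SECONDS_EXPONENT["state"],
            ext_key(a): _SECONDS_EXPONENT["ext"],
        }
        for (t, s) in COUPLING_SIGNS:
            if t == a:
                terms[alpha_key(t, s)] = _SECONDS_EXPONENT["alpha"] + _SECONDS_EXPONENT["state"]
        if a == BETA_EDGE[0]:
            terms[BETA_KEY] = _SECONDS_EXPONENT["beta"] + 2 * _SECONDS_EXPONENT["state"]
        for name, exponent in terms.items():
            if exponent != target:
                raise ModelValidationError(
                    f"term {name} of the {a} equation has unit s^{exponent}, "
                    f"expected Hz/s (s^{target})"
                )
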