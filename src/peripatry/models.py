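"""Registry of two-population diversification models.

Each model describes the history of a derived ("island", population 1) and an
ancestral ("mainland", population 2) population in coalescent units: sizes nu
relative to a reference effective size N_ref, times T in units of 2*N_ref
generations, and migration rates scaled by 2*N_ref. Models fall into four
categories:

* ``vicariance`` — the ancestral population splits into two descendants with
  no founder bottleneck (with or without continuous/ancient gene flow);
* ``founder`` — population 1 is founded by a fraction ``s`` (at most one half)
  of the ancestral population and then grows exponentially;
* ``old_founder`` — a founder event followed by a distinct later epoch, here
  secondary contact with asymmetric migration;
* ``secondary_contact`` — split, a period of strict isolation, then renewed
  migration, optionally with stepwise population-size changes.

Migration convention: ``m12`` is forward-in-time gene flow from population 1
into population 2 (and symmetrically for ``m21``), so that an excess of
``m12`` over ``m21`` reads as "more gene flow from the island into the
mainland".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import json
import math

__all__ = [
    "Epoch",
    "Demography",
    "ModelSpec",
    "registry",
    "get_model",
    "build_demography",
    "register_model",
]

# default box constraints, per parameter kind
SIZE_BOUNDS = (1e-3, 100.0)
TIME_BOUNDS = (1e-3, 10.0)
# log-space optimization needs a positive lower bound; 1e-3 in 2*N_ref units
# is demographically indistinguishable from zero migration at RAD sample sizes
MIG_BOUNDS = (1e-3, 20.0)
S_BOUNDS = (0.01, 0.5)

_SIZE_PARAMS = {"nuA", "nu1", "nu2", "nu1a", "nu2a", "nu1b", "nu2b"}
_TIME_PARAMS = {"T1", "T2", "T3"}
_MIG_PARAMS = {"m12", "m21", "m"}


def default_bounds(param: str) -> Tuple[float, float]:
    if param in _SIZE_PARAMS:
        return SIZE_BOUNDS
    if param in _TIME_PARAMS:
        return TIME_BOUNDS
    if param in _MIG_PARAMS:
        return MIG_BOUNDS
    if param == "s":
        return S_BOUNDS
    raise KeyError(f"unknown parameter {param!r}")


@dataclass(frozen=True)
class Epoch:
    """One piecewise interval of the post-split history (forward time).

    ``start_sizes``/``end_sizes`` are the deme sizes at the older and the more
    recent end of the interval; unequal values mean exponential interpolation.
    ``migration[i][j]`` is forward gene flow from deme i into deme j in
    2*N_ref-scaled units.
    """

    duration: float
    start_sizes: Tuple[float, float]
    end_sizes: Tuple[float, float]
    migration: Tuple[Tuple[float, float], Tuple[float, float]] = ((0.0, 0.0), (0.0, 0.0))

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("epoch duration must be positive")
        for sz in (*self.start_sizes, *self.end_sizes):
            if not sz > 0:
                raise ValueError("population sizes must stay positive")
        for row in self.migration:
            for m in row:
                if m < 0:
                    raise ValueError("migration rates must be non-negative")


@dataclass(frozen=True)
class Demography:
    """A concrete piecewise two-population history.

    ``epochs`` run forward in time, ``epochs[0]`` starting at the split of the
    root population (constant size ``root_size``). ``founding_fraction`` is
    set for founder models (the derived deme starts at ``s * root_size``) and
    ``None`` for vicariance-style splits.
    """

    root_size: float
    epochs: Tuple[Epoch, ...]
    founding_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.root_size > 0:
            raise ValueError("root size must be positive")
        if not self.epochs:
            raise ValueError("demography needs at least one post-split epoch")
        if self.founding_fraction is not None and not (0 < self.founding_fraction <= 0.5):
            raise ValueError("founding fraction must lie in (0, 0.5]")

    @property
    def total_duration(self) -> float:
        return sum(e.duration for e in self.epochs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "root_size": self.root_size,
                "founding_fraction": self.founding_fraction,
                "epochs": [
                    {
                        "duration": e.duration,
                        "start_sizes": list(e.start_sizes),
                        "end_sizes": list(e.end_sizes),
                        "migration": [list(r) for r in e.migration],
                    }
                    for e in self.epochs
                ],
            },
            indent=2,
        )


class BoundViolation(ValueError):
    """A parameter value lies outside its registered bounds."""


@dataclass(frozen=True)
class ModelSpec:
    name: str
    category: str
    param_names: Tuple[str, ...]
    builder: Callable[..., Demography]
    bounds: Mapping[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in {"vicariance", "founder", "old_founder", "secondary_contact"}:
            raise ValueError(f"unknown category {self.category!r}")
        filled = {p: self.bounds.get(p, default_bounds(p)) for p in self.param_names}
        object.__setattr__(self, "bounds", filled)
        for p, (lo, hi) in filled.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"bounds for {p} must be finite, positive, ordered")

    @property
    def k(self) -> int:
        return len(self.param_names)

    def validate(self, params: Mapping[str, float]) -> Dict[str, float]:
        extra = set(params) - set(self.param_names)
        if extra:
            raise ValueError(f"model {self.name} does not take parameter(s) {sorted(extra)}")
        missing = set(self.param_names) - set(params)
        if missing:
            raise ValueError(f"model {self.name} missing parameter(s) {sorted(missing)}")
        for p in self.param_names:
            lo, hi = self.bounds[p]
            v = float(params[p])
            if not (lo <= v <= hi):
                raise BoundViolation(f"{self.name}: {p}={v} outside [{lo}, {hi}]")
        return {p: float(params[p]) for p in self.param_names}

    def build(self, params: Mapping[str, float]) -> Demography:
        return self.builder(**self.validate(params))

    def midpoint(self) -> Dict[str, float]:
        """Geometric midpoint of the bounds, a guaranteed-valid parameter set."""
        return {p: math.sqrt(lo * hi) for p, (lo, hi) in self.bounds.items()}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "category": self.category,
            "param_names": list(self.param_names),
            "bounds": {p: list(b) for p, b in self.bounds.items()},
            "k": self.k,
        }


_REGISTRY: Dict[str, ModelSpec] = {}


def register_model(spec: ModelSpec) -> ModelSpec:
    if spec.name in _REGISTRY:
        raise ValueError(f"model {spec.name!r} already registered")
    _REGISTRY[spec.name] = spec
    return spec


def registry() -> List[ModelSpec]:
    """All registered models, in registration order."""
    return list(_REGISTRY.values())


def get_model(name: str) -> ModelSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"no model named {name!r}; known: {sorted(_REGISTRY)}") from None


def build_demography(name: str, params: Mapping[str, float]) -> Demography:
    """Translate a named model plus parameter vector into a Demography."""
    return get_model(name).build(params)


def _sym(m: float):
    return ((0.0, m), (m, 0.0))


def _asym(m12: float, m21: float):
    return ((0.0, m12), (m21, 0.0))


# --- vicariance / isolation-with-migration models -------------------------

def _no_mig(nu1, nu2, T1):
    return Demography(1.0, (Epoch(T1, (nu1, nu2), (nu1, nu2)),))


def _sym_mig(nu1, nu2, m, T1):
    return Demography(1.0, (Epoch(T1, (nu1, nu2), (nu1, nu2), _sym(m)),))


def _asym_mig(nu1, nu2, m12, m21, T1):
    return Demography(1.0, (Epoch(T1, (nu1, nu2), (nu1, nu2), _asym(m12, m21)),))


def _anc_sym_mig(nu1, nu2, m, T1, T2):
    sizes = (nu1, nu2)
    return Demography(1.0, (Epoch(T1, sizes, sizes, _sym(m)), Epoch(T2, sizes, sizes)))


def _anc_asym_mig(nu1, nu2, m12, m21, T1, T2):
    sizes = (nu1, nu2)
    return Demography(1.0, (Epoch(T1, sizes, sizes, _asym(m12, m21)), Epoch(T2, sizes, sizes)))


def _vic_no_mig(nuA, nu1, nu2, T1):
    return Demography(nuA, (Epoch(T1, (nu1, nu2), (nu1, nu2)),))


# --- secondary-contact models ---------------------------------------------

def _sec_contact_sym_mig(nu1, nu2, m, T1, T2):
    sizes = (nu1, nu2)
    return Demography(1.0, (Epoch(T1, sizes, sizes), Epoch(T2, sizes, sizes, _sym(m))))


def _sec_contact_asym_mig(nu1, nu2, m12, m21, T1, T2):
    sizes = (nu1, nu2)
    return Demography(1.0, (Epoch(T1, sizes, sizes), Epoch(T2, sizes, sizes, _asym(m12, m21))))


def _sec_contact_sym_mig_size(nu1a, nu2a, nu1b, nu2b, m, T1, T2):
    a, b = (nu1a, nu2a), (nu1b, nu2b)
    return Demography(1.0, (Epoch(T1, a, a), Epoch(T2, b, b, _sym(m))))


def _sec_contact_asym_mig_size(nu1a, nu2a, nu1b, nu2b, m12, m21, T1, T2):
    a, b = (nu1a, nu2a), (nu1b, nu2b)
    return Demography(1.0, (Epoch(T1, a, a), Epoch(T2, b, b, _asym(m12, m21))))


def _sec_contact_sym_mig_size_three_epoch(nu1a, nu2a, nu1b, nu2b, m, T1, T2, T3):
    a, b = (nu1a, nu2a), (nu1b, nu2b)
    return Demography(1.0, (Epoch(T1, a, a), Epoch(T2, b, b, _sym(m)), Epoch(T3, b, b)))


def _sec_contact_asym_mig_size_three_epoch(nu1a, nu2a, nu1b, nu2b, m12, m21, T1, T2, T3):
    a, b = (nu1a, nu2a), (nu1b, nu2b)
    return Demography(1.0, (Epoch(T1, a, a), Epoch(T2, b, b, _asym(m12, m21)), Epoch(T3, b, b)))


# --- founder models --------------------------------------------------------
# The derived deme is founded at s * nuA and grows exponentially to nu1
# within the first post-split epoch; the mainland takes size nu2 at the split.

def _founder_nomig(nuA, nu1, nu2, T1, s):
    return Demography(nuA, (Epoch(T1, (s * nuA, nu2), (nu1, nu2)),), founding_fraction=s)


def _founder_sym(nuA, nu1, nu2, m, T1, s):
    return Demography(nuA, (Epoch(T1, (s * nuA, nu2), (nu1, nu2), _sym(m)),), founding_fraction=s)


def _founder_asym(nuA, nu1, nu2, m12, m21, T1, s):
    return Demography(
        nuA, (Epoch(T1, (s * nuA, nu2), (nu1, nu2), _asym(m12, m21)),), founding_fraction=s
    )


def _founder_sec_contact_asym_two_epoch(nuA, nu1, nu2, m12, m21, T1, T2, s):
    # epoch 1: isolation with exponential growth of the founder deme;
    # epoch 2: constant sizes with asymmetric secondary contact
    return Demography(
        nuA,
        (
            Epoch(T1, (s * nuA, nu2), (nu1, nu2)),
            Epoch(T2, (nu1, nu2), (nu1, nu2), _asym(m12, m21)),
        ),
        founding_fraction=s,
    )


def _register_all() -> None:
    entries = [
        ("no_mig", "vicariance", ("nu1", "nu2", "T1"), _no_mig),
        ("sym_mig", "vicariance", ("nu1", "nu2", "m", "T1"), _sym_mig),
        ("asym_mig", "vicariance", ("nu1", "nu2", "m12", "m21", "T1"), _asym_mig),
        ("anc_sym_mig", "vicariance", ("nu1", "nu2", "m", "T1", "T2"), _anc_sym_mig),
        ("anc_asym_mig", "vicariance", ("nu1", "nu2", "m12", "m21", "T1", "T2"), _anc_asym_mig),
        ("vic_no_mig", "vicariance", ("nuA", "nu1", "nu2", "T1"), _vic_no_mig),
        ("sec_contact_sym_mig", "secondary_contact", ("nu1", "nu2", "m", "T1", "T2"), _sec_contact_sym_mig),
        ("sec_contact_asym_mig", "secondary_contact", ("nu1", "nu2", "m12", "m21", "T1", "T2"), _sec_contact_asym_mig),
        ("sec_contact_sym_mig_size", "secondary_contact", ("nu1a", "nu2a", "nu1b", "nu2b", "m", "T1", "T2"), _sec_contact_sym_mig_size),
        ("sec_contact_asym_mig_size", "secondary_contact", ("nu1a", "nu2a", "nu1b", "nu2b", "m12", "m21", "T1", "T2"), _sec_contact_asym_mig_size),
        ("sec_contact_sym_mig_size_three_epoch", "secondary_contact", ("nu1a", "nu2a", "nu1b", "nu2b", "m", "T1", "T2", "T3"), _sec_contact_sym_mig_size_three_epoch),
        ("sec_contact_asym_mig_size_three_epoch", "secondary_contact", ("nu1a", "nu2a", "nu1b", "nu2b", "m12", "m21", "T1", "T2", "T3"), _sec_contact_asym_mig_size_three_epoch),
        ("founder_nomig", "founder", ("nuA", "nu1", "nu2", "T1", "s"), _founder_nomig),
        ("founder_sym", "founder", ("nuA", "nu1", "nu2", "m", "T1", "s"), _founder_sym),
        ("founder_asym", "founder", ("nuA", "nu1", "nu2", "m12", "m21", "T1", "s"), _founder_asym),
        ("founder_sec_contact_asym_two_epoch", "old_founder", ("nuA", "nu1", "nu2", "m12", "m21", "T1", "T2", "s"), _founder_sec_contact_asym_two_epoch),
    ]
    for name, cat, params, fn in entries:
        register_model(ModelSpec(name, cat, params, fn))


_register_all()


def registry_json() -> str:
    return json.dumps([m.to_dict() for m in registry()], indent=2)
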