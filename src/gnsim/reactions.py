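"""Core domain types for delayed mass-action reaction systems.

A :class:`ReactionSystem` bundles a species population table, a list of
:class:`Reaction` objects and an optional list of pre-scheduled
:class:`WaitListEntry` injections.  Reactions follow delayed-SSA semantics:
reactants marked *catalytic* contribute to the propensity but are not
consumed (unless they re-appear as a delayed product, in which case they are
taken offline at firing time and re-released when the delay elapses), and
each product may carry its own delay distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "DelaySpec",
    "DelayParams",
    "RateParams",
    "Reactant",
    "Product",
    "Reaction",
    "WaitListEntry",
    "ReactionSystem",
]

DELAY_KINDS = ("none", "constant", "gaussian", "gamma", "exponential")

#: parameter names required for each delay kind
_DELAY_PARAMS = {
    "none": (),
    "constant": ("value",),
    "gaussian": ("mean", "sd"),
    "gamma": ("shape", "scale"),
    "exponential": ("rate",),
}

#: parameters that must be strictly positive
_STRICT_POSITIVE = {
    "gaussian": ("sd",),
    "gamma": ("shape", "scale"),
    "exponential": ("rate",),
}


@dataclass(frozen=True)
class DelaySpec:
    """Distribution from which a product's release delay is sampled."""

    kind: str = "none"
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in DELAY_KINDS:
            raise ValueError(f"unknown delay kind {self.kind!r}; expected one of {DELAY_KINDS}")
        required = _DELAY_PARAMS[self.kind]
        missing = [p for p in required if p not in self.params]
        if missing:
            raise ValueError(f"delay kind {self.kind!r} requires parameters {missing}")
        for name in required:
            value = float(self.params[name])
            if not math.isfinite(value):
                raise ValueError(f"delay parameter {name!r} must be finite, got {value}")
            if name in _STRICT_POSITIVE.get(self.kind, ()) and value <= 0:
                raise ValueError(f"delay parameter {name!r} must be > 0, got {value}")
        if self.kind == "constant" and float(self.params["value"]) < 0:
            raise ValueError("constant delay must be >= 0")
        # freeze params against later mutation
        object.__setattr__(self, "params", dict(self.params))

    # -- constructors ------------------------------------------------------
    @classmethod
    def none(cls) -> "DelaySpec":
        return cls("none")

    @classmethod
    def constant(cls, value: float) -> "DelaySpec":
        return cls("constant", {"value": float(value)})

    @classmethod
    def gaussian(cls, mean: float, sd: float) -> "DelaySpec":
        return cls("gaussian", {"mean": float(mean), "sd": float(sd)})

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "DelaySpec":
        return cls("gamma", {"shape": float(shape), "scale": float(scale)})

    @classmethod
    def exponential(cls, rate: float) -> "DelaySpec":
        return cls("exponential", {"rate": float(rate)})

    @property
    def is_zero(self) -> bool:
        """True when the delay is identically zero."""
        return self.kind == "none" or (
            self.kind == "constant" and float(self.params["value"]) == 0.0
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DelaySpec):
            return NotImplemented
        return self.kind == other.kind and dict(self.params) == dict(other.params)

    def __hash__(self) -> int:
        return hash((self.kind, tuple(sorted(self.params.items()))))


@dataclass(frozen=True)
class DelayParams:
    """Delay specifications attached by the network compiler.

    ``rna_delay`` delays the appearance of the RNA product of transcription,
    ``protein_delay`` the appearance of the protein product of translation,
    and ``promoter_delay`` the re-release of promoter forms after
    transcription initiation (occupancy during elongation).
    """

    rna_delay: DelaySpec = field(default_factory=DelaySpec.none)
    protein_delay: DelaySpec = field(default_factory=DelaySpec.none)
    promoter_delay: DelaySpec = field(default_factory=DelaySpec.none)


_RATE_FIELDS = (
    "transcription",
    "translation",
    "rna_degradation",
    "protein_degradation",
    "binding",
    "unbinding",
)


@dataclass(frozen=True)
class RateParams:
    """Scalar default rate constants, overridable per gene or per edge.

    ``per_gene`` maps a gene id to ``{rate_field: value}`` overrides for the
    gene-local rates (transcription, translation, degradations).  ``per_edge``
    maps an ``(regulator, target)`` pair to ``{"binding": v, "unbinding": v}``
    overrides.
    """

    transcription: float = 0.5
    translation: float = 0.1
    rna_degradation: float = 0.05
    protein_degradation: float = 0.05
    binding: float = 0.05
    unbinding: float = 0.5
    per_gene: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    per_edge: Mapping[tuple, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = float(getattr(self, name))
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"rate {name!r} must be finite and >= 0, got {value}")
        for overrides in self.per_gene.values():
            for key, value in overrides.items():
                if key not in _RATE_FIELDS:
                    raise ValueError(f"unknown rate field in per_gene override: {key!r}")
                if not math.isfinite(float(value)) or float(value) < 0:
                    raise ValueError(f"per-gene rate {key!r} must be finite and >= 0")
        for overrides in self.per_edge.values():
            for key, value in overrides.items():
                if key not in ("binding", "unbinding"):
                    raise ValueError(f"unknown rate field in per_edge override: {key!r}")
                if not math.isfinite(float(value)) or float(value) < 0:
                    raise ValueError(f"per-edge rate {key!r} must be finite and >= 0")

    def gene_rate(self, field_name: str, gene: str) -> float:
        override = self.per_gene.get(gene, {})
        return float(override.get(field_name, getattr(self, field_name)))

    def edge_rate(self, field_name: str, regulator: str, target: str) -> float:
        override = self.per_edge.get((regulator, target), {})
        return float(override.get(field_name, getattr(self, field_name)))


@dataclass(frozen=True)
class Reactant:
    species: str
    stoichiometry: int = 1
    catalyst: bool = False

    def __post_init__(self) -> None:
        if self.stoichiometry < 1:
            raise ValueError("reactant stoichiometry must be >= 1")


@dataclass(frozen=True)
class Product:
    species: str
    stoichiometry: int = 1
    delay: DelaySpec = field(default_factory=DelaySpec.none)

    def __post_init__(self) -> None:
        if self.stoichiometry < 1:
            raise ValueError("product stoichiometry must be >= 1")


@dataclass(frozen=True)
class Reaction:
    """A single mass-action reaction with optional per-product delays."""

    reactants: tuple[Reactant, ...]
    products: tuple[Product, ...]
    rate_constant: float
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if not self.reactants and not self.products:
            raise ValueError("reaction needs at least one reactant or product")
        if not math.isfinite(self.rate_constant) or self.rate_constant < 0:
            raise ValueError(f"rate constant must be finite and >= 0, got {self.rate_constant}")
        seen: set[str] = set()
        for r in self.reactants:
            if r.species in seen:
                raise ValueError(f"duplicate reactant species {r.species!r}; fold stoichiometry instead")
            seen.add(r.species)

    def species_names(self) -> set[str]:
        return {r.species for r in self.reactants} | {p.species for p in self.products}

    def signature(self) -> tuple:
        """Order-insensitive identity used for multiset comparison of systems."""
        return (
            tuple(sorted((r.species, r.stoichiometry, r.catalyst) for r in self.reactants)),
            tuple(
                sorted(
                    (p.species, p.stoichiometry, p.delay.kind, tuple(sorted(p.delay.params.items())))
                    for p in self.products
                )
            ),
            float(self.rate_constant),
        )


@dataclass(frozen=True)
class WaitListEntry:
    """A scheduled release of ``count`` molecules of ``species`` at ``release_time``."""

    species: str
    count: int
    release_time: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("wait-list count must be >= 1")
        if not math.isfinite(self.release_time) or self.release_time < 0:
            raise ValueError("wait-list release time must be finite and >= 0")


@dataclass
class ReactionSystem:
    """Species population table, reaction list and initial wait-list entries.

    ``gene_species`` optionally maps a gene id to its ``(rna, protein)``
    species names; it is filled in by the network compiler so that samplers
    can report per-gene expression rather than raw species counts.
    """

    species: dict[str, int]
    reactions: list[Reaction]
    waitlist: list[WaitListEntry] = field(default_factory=list)
    gene_species: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = dict(self.species)
        self.reactions = list(self.reactions)
        self.waitlist = list(self.waitlist)
        for name, count in self.species.items():
            if int(count) < 0:
                raise ValueError(f"initial count of {name!r} must be >= 0")
            self.species[name] = int(count)
        for rx in self.reactions:
            for sp in rx.species_names():
                if sp not in self.species:
                    raise ValueError(f"reaction references undeclared species {sp!r}")
        for entry in self.waitlist:
            if entry.species not in self.species:
                raise ValueError(f"wait-list references undeclared species {entry.species!r}")

    def signature(self) -> tuple:
        """Order-insensitive equivalence key (species counts + reaction multiset)."""
        return (
            tuple(sorted(self.species.items())),
            tuple(sorted(rx.signature() for rx in self.reactions)),
            tuple(sorted((w.species, w.count, w.release_time) for w in self.waitlist)),
        )


def species_table(names: Iterable[str], counts: Mapping[str, int] | None = None) -> dict[str, int]:
    """Build a population table with zero defaults for unnamed counts."""
    counts = counts or {}
    return {name: int(counts.get(name, 0)) for name in names}
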