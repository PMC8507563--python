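"""Particle species and scenario masks.

A field component is identified by the triple (A, Z, generation).  The
generation level distinguishes beam protons that have never undergone a
nuclear reaction (generation 0) from protons set in motion by nuclear
reactions or elastic hydrogen recoils (generation >= 1).  Generation is
tracked only for protons; every other species carries the sentinel
``ANY_GENERATION``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

from .errors import CatalogueError

#: Sentinel generation for species where generation is not tracked.
ANY_GENERATION = -1

MAX_Z = 17


@dataclass(frozen=True, order=True)
class ParticleType:
    """Identifier of a field component: mass number, charge, generation."""

    A: int
    Z: int
    generation: int = ANY_GENERATION

    def __post_init__(self) -> None:
        if self.A < 1:
            raise CatalogueError(f"mass number must be >= 1, got A={self.A}")
        if not 1 <= self.Z <= MAX_Z:
            raise CatalogueError(f"atomic number must be in [1, {MAX_Z}], got Z={self.Z}")
        if self.Z >= 2 and self.A < self.Z:
            raise CatalogueError(f"A >= Z required for Z >= 2, got A={self.A}, Z={self.Z}")
        if self.is_proton:
            if self.generation < 0:
                raise CatalogueError("proton generation must be >= 0")
        elif self.generation != ANY_GENERATION:
            raise CatalogueError(
                "generation is tracked only for protons (A=1, Z=1); "
                f"use ANY_GENERATION for {self.label}"
            )

    @property
    def is_proton(self) -> bool:
        return self.A == 1 and self.Z == 1

    @property
    def is_primary(self) -> bool:
        return self.is_proton and self.generation == 0

    @property
    def label(self) -> str:
        sym = _SYMBOLS.get(self.Z, f"Z{self.Z}")
        if self.is_proton:
            return f"p(gen{self.generation})"
        return f"{self.A}{sym}"


_SYMBOLS = {1: "H", 2: "He", 3: "Li", 4: "Be", 5: "B", 6: "C", 7: "N", 8: "O",
            9: "F", 10: "Ne", 11: "Na", 12: "Mg", 13: "Al", 14: "Si", 15: "P",
            16: "S", 17: "Cl"}

PRIMARY_PROTON = ParticleType(1, 1, 0)
SECONDARY_PROTON = ParticleType(1, 1, 1)

#: Default species catalogue of target fragments (non-primary components).
#: Protons of generation >= 1 are handled separately by the generator.
DEFAULT_FRAGMENTS: tuple[ParticleType, ...] = (
    ParticleType(2, 1),   # d
    ParticleType(3, 1),   # t
    ParticleType(3, 2),   # 3He
    ParticleType(4, 2),   # 4He
    ParticleType(6, 3),   # 6Li
    ParticleType(7, 3),   # 7Li
    ParticleType(9, 4),   # 9Be
    ParticleType(10, 5),  # 10B
    ParticleType(11, 5),  # 11B
    ParticleType(11, 6),  # 11C
    ParticleType(12, 6),  # 12C
    ParticleType(14, 7),  # 14N
    ParticleType(15, 8),  # 15O
    ParticleType(16, 8),  # 16O
)


@dataclass(frozen=True)
class ScenarioMask:
    """Named predicate over particle types defining an inclusion scenario."""

    name: str
    predicate: Callable[[ParticleType], bool] = field(compare=False)

    def __call__(self, ptype: ParticleType) -> bool:
        return self.predicate(ptype)

    def select(self, ptypes: Iterable[ParticleType]) -> list[ParticleType]:
        return [t for t in ptypes if self(t)]


PRIMARIES = ScenarioMask("primaries", lambda t: t.is_primary)
ALL_PROTONS = ScenarioMask("all_protons", lambda t: t.is_proton)
ALL_PARTICLES = ScenarioMask("all_particles", lambda t: True)

SCENARIOS = {m.name: m for m in (PRIMARIES, ALL_PROTONS, ALL_PARTICLES)}


def scenario_mask(name: str) -> ScenarioMask:
    """Look up one of the three inclusion scenarios by name."""
    try:
        return SCENARIOS[name]
    except KeyError:
        raise CatalogueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
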