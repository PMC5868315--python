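"""Declarative circuit specifications: a strand roster, two inputs and the
Boolean function the gate is declared to compute."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .core import Role, SpecError, Strand

#: canonical ordering of the four input states in truth tables and reports
INPUT_STATES: tuple[tuple[int, int], ...] = ((0, 0), (1, 0), (0, 1), (1, 1))


@dataclass(frozen=True)
class CircuitSpec:
    """One gate or multilevel circuit.

    ``strands`` is the non-input roster (DNAzyme subunits, the hairpin
    substrate, an optional template); ``inputs`` are the two input strands;
    ``declared_function`` lists the expected output bit for the input states
    (0,0), (1,0), (0,1), (1,1) in that order.  ``provenance`` is either
    ``"reference"`` (transcribed from the platform's published main-text
    designs) or ``"reconstructed"`` (rebuilt from the platform's reusable
    assembly patterns).
    """

    name: str
    strands: tuple[Strand, ...]
    inputs: tuple[Strand, Strand]
    declared_function: tuple[int, int, int, int]
    provenance: str = "reference"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.declared_function) != 4 or any(
            b not in (0, 1) for b in self.declared_function
        ):
            raise SpecError(
                f"circuit {self.name!r}: declared function must be 4 bits"
            )
        if len(self.inputs) != 2:
            raise SpecError(f"circuit {self.name!r}: exactly two inputs")
        names = [s.name for s in self.strands] + [s.name for s in self.inputs]
        if len(set(names)) != len(names):
            raise SpecError(f"circuit {self.name!r}: duplicate strand names")
        subs = [
            s
            for s in self.strands
            if s.ra_site is not None and s.caged_g4 is not None
        ]
        if len(subs) != 1:
            raise SpecError(
                f"circuit {self.name!r}: exactly one substrate strand must "
                f"carry both an rA site and a caged G4 (found {len(subs)})"
            )
        roster_roles = {
            d.role for s in self.strands for d in s.domains
        }
        if Role.CORE_I in roster_roles and Role.CORE_II not in roster_roles:
            raise SpecError(
                f"circuit {self.name!r}: core-I half present with no core-II "
                f"partner anywhere in the roster"
            )

    @property
    def substrate(self) -> Strand:
        return next(
            s
            for s in self.strands
            if s.ra_site is not None and s.caged_g4 is not None
        )

    def strand_by_name(self, name: str) -> Strand:
        for s in (*self.strands, *self.inputs):
            if s.name == name:
                return s
        raise KeyError(name)

    def without_substrate(self) -> "CircuitSpec":
        """Negative-control variant with the reporter hairpin removed.

        Bypasses the one-substrate invariant deliberately: the variant
        models a mixture missing the reporter, so validation is relaxed via
        object construction around ``__post_init__``.
        """
        sub = self.substrate.name
        new = object.__new__(CircuitSpec)
        for f, v in (
            ("name", self.name),
            ("strands", tuple(s for s in self.strands if s.name != sub)),
            ("inputs", self.inputs),
            ("declared_function", self.declared_function),
            ("provenance", self.provenance),
        ):
            object.__setattr__(new, f, v)
        return new

    def with_strand_replaced(self, name: str, strand: Strand) -> "CircuitSpec":
        strands = tuple(
            strand if s.name == name else s for s in self.strands
        )
        return replace(self, strands=strands)
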