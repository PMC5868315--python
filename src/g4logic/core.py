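"""Domain-level data model for DNA strand-displacement logic circuits.

The simulator works at the abstraction level customary in dynamic DNA
nanotechnology: a strand is an ordered 5'->3' list of *domains*, contiguous
segments that hybridize as indivisible units.  A domain ``x`` pairs only with
its complement ``x*`` (same name and length, opposite orientation flag).
Base-level detail (mismatches, bulges, nearest-neighbor energetics) is
deliberately out of scope; concrete sequences are optional decoration used
for sequence-design checks, never for reaction logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional


class SpecError(ValueError):
    """A strand or circuit definition violates a structural invariant."""


class Role(str, Enum):
    """Functional annotation of a domain.

    ``CORE_I``/``CORE_II`` are the two halves of the split Mg2+-dependent
    DNAzyme catalytic core; ``RECOGNITION_ARM`` binds the input/template
    scaffold; ``SUBSTRATE_ARM`` clamps the cleavable substrate;
    ``G4_SEGMENT`` is the G-rich peroxidase-mimicking sequence (its starred
    complement acts as the hairpin stem clamp that cages it).
    """

    TOEHOLD = "toehold"
    RECOGNITION_ARM = "recognition_arm"
    CORE_I = "catalytic_core_I"
    CORE_II = "catalytic_core_II"
    SUBSTRATE_ARM = "substrate_arm"
    G4_SEGMENT = "g4_segment"
    GENERIC = "generic"


#: default domain lengths (nt) by role, used when a circuit file omits them
DEFAULT_LENGTHS = {
    Role.TOEHOLD: 6,
    Role.RECOGNITION_ARM: 12,
    Role.SUBSTRATE_ARM: 8,
    Role.G4_SEGMENT: 17,
    Role.CORE_I: 8,
    Role.CORE_II: 7,
    Role.GENERIC: 12,
}


@dataclass(frozen=True)
class Domain:
    """A named, oriented DNA segment treated as one hybridization unit."""

    name: str
    length: int
    starred: bool = False
    role: Role = Role.GENERIC

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise SpecError(f"domain {self.name!r}: length must be positive")
        if not self.name or "*" in self.name:
            raise SpecError(f"invalid domain name {self.name!r}")

    @property
    def label(self) -> str:
        return self.name + ("*" if self.starred else "")

    def complement(self) -> "Domain":
        """The Watson-Crick partner: orientation flag toggled, rest kept."""
        return replace(self, starred=not self.starred)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


def complement(d: Domain) -> Domain:
    """Return the complementary domain (involution: ``complement`` twice is
    the identity)."""
    return d.complement()


def is_complementary(d1: Domain, d2: Domain) -> bool:
    """True iff the two domains can pair: same name and length, opposite
    orientation.  Symmetric and irreflexive."""
    return (
        d1.name == d2.name
        and d1.length == d2.length
        and d1.starred != d2.starred
    )


@dataclass(frozen=True)
class Strand:
    """A named single strand: an ordered 5'->3' tuple of domains.

    ``ra_site`` marks the single embedded ribonucleobase (the scissile
    position of the Mg2+-dependent DNAzyme substrate) as a zero-length
    marker sitting on the boundary *before* domain index ``ra_site``; it must
    lie strictly inside the strand.  ``caged_g4`` is an inclusive span of
    domain indices holding exactly one unstarred G4 segment, sequestered in a
    hairpin stem until cleavage frees it.
    """

    name: str
    domains: tuple[Domain, ...]
    sequence: Optional[str] = None
    ra_site: Optional[int] = None
    caged_g4: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.domains:
            raise SpecError(f"strand {self.name!r}: needs at least one domain")
        n = len(self.domains)
        if self.ra_site is not None and not (0 < self.ra_site < n):
            raise SpecError(
                f"strand {self.name!r}: rA site must lie strictly inside the "
                f"domain list (got boundary {self.ra_site} of {n})"
            )
        if self.caged_g4 is not None:
            lo, hi = self.caged_g4
            if not (0 <= lo <= hi < n):
                raise SpecError(
                    f"strand {self.name!r}: caged G4 span {self.caged_g4} "
                    f"out of range"
                )
            n_g4 = sum(
                1
                for d in self.domains[lo : hi + 1]
                if d.role is Role.G4_SEGMENT and not d.starred
            )
            if n_g4 != 1:
                raise SpecError(
                    f"strand {self.name!r}: caged G4 span must contain "
                    f"exactly one unstarred G4 segment (found {n_g4})"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise SpecError(
                f"strand {self.name!r}: sequence length {len(self.sequence)} "
                f"!= summed domain lengths {self.length}"
            )

    @property
    def length(self) -> int:
        return sum(d.length for d in self.domains)

    def domain_labels(self) -> list[str]:
        return [d.label for d in self.domains]

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.name}[{' '.join(self.domain_labels())}]"


# ---------------------------------------------------------------------------
# pairing utilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairingRun:
    """A maximal contiguous antiparallel pairing between two strands.

    Domains ``i .. i+k-1`` of the first strand pair with domains
    ``j .. j-k+1`` (descending) of the second strand.
    """

    start_a: int
    start_b: int
    n_domains: int
    paired_nt: int

    def a_indices(self) -> range:
        return range(self.start_a, self.start_a + self.n_domains)

    def b_indices(self) -> list[int]:
        return [self.start_b - t for t in range(self.n_domains)]


def _all_runs(
    doms_a: tuple[Domain, ...],
    doms_b: tuple[Domain, ...],
    free_a: Iterable[bool] | None = None,
    free_b: Iterable[bool] | None = None,
) -> list[PairingRun]:
    """All maximal antiparallel complementary runs between two domain lists,
    restricted to positions flagged free."""
    fa = list(free_a) if free_a is not None else [True] * len(doms_a)
    fb = list(free_b) if free_b is not None else [True] * len(doms_b)

    def ok(i: int, j: int) -> bool:
        return fa[i] and fb[j] and is_complementary(doms_a[i], doms_b[j])

    runs: list[PairingRun] = []
    for i in range(len(doms_a)):
        for j in range(len(doms_b)):
            if not ok(i, j):
                continue
            # maximal: not extendable backwards
            if i > 0 and j + 1 < len(doms_b) and ok(i - 1, j + 1):
                continue
            k = 0
            while i + k < len(doms_a) and j - k >= 0 and ok(i + k, j - k):
                k += 1
            nt = sum(doms_a[i + t].length for t in range(k))
            runs.append(PairingRun(i, j, k, nt))
    return runs


def _best_run_set(
    runs: list[PairingRun],
) -> tuple[list[PairingRun], int]:
    """Maximum-weight set of runs that do not reuse a domain on either
    strand (brute force; domain counts are tiny)."""
    best: tuple[int, list[PairingRun]] = (0, [])

    order = sorted(runs, key=lambda r: (r.start_a, r.start_b))

    def rec(idx: int, used_a: set, used_b: set,
            chosen: list[PairingRun], total: int) -> None:
        nonlocal best
        if total > best[0] or (total == best[0] and not best[1] and chosen):
            best = (total, list(chosen))
        for k in range(idx, len(order)):
            r = order[k]
            ra = set(r.a_indices())
            rb = set(r.b_indices())
            if ra & used_a or rb & used_b:
                continue
            chosen.append(r)
            rec(k + 1, used_a | ra, used_b | rb, chosen, total + r.paired_nt)
            chosen.pop()

    rec(0, set(), set(), [], 0)
    return best[1], best[0]


def max_pairing(s1: Strand, s2: Strand) -> tuple[list[PairingRun], int]:
    """Best non-overlapping set of maximal antiparallel complementary domain
    runs between two strands, with the total paired nt.

    Deterministic; symmetric in total paired nt.  Used both as a standalone
    query and by the reaction engine to rank hybridization candidates.
    """
    runs = _all_runs(s1.domains, s2.domains)
    return _best_run_set(runs)


# ---------------------------------------------------------------------------
# complexes
# ---------------------------------------------------------------------------

@dataclass
class StrandInstance:
    """One physical copy of a strand inside the reaction mixture.

    ``parent`` records provenance of cleavage fragments as
    ``(parent instance id, fragment index)``.
    """

    iid: int
    strand: Strand
    parent: Optional[tuple[int, int]] = None

    @property
    def name(self) -> str:
        return self.strand.name

    def __hash__(self) -> int:
        return hash(self.iid)


#: a bond endpoint: (strand instance id, domain index)
End = tuple[int, int]


def make_bond(a: End, b: End) -> tuple[End, End]:
    """Canonical (sorted) representation of an inter-domain bond."""
    if a == b:
        raise SpecError("bond endpoints must differ")
    return (a, b) if a <= b else (b, a)


@dataclass
class SpeciesComplex:
    """A connected assembly of strand instances (view object).

    Built on demand from the flat system state; invariant: the bond graph is
    connected unless the complex is a single free strand, and intra-strand
    bonds only join non-adjacent domains (hairpin stems).
    """

    instances: dict[int, StrandInstance] = field(default_factory=dict)
    bonds: set[tuple[End, End]] = field(default_factory=set)

    @property
    def strand_names(self) -> tuple[str, ...]:
        return tuple(sorted(i.name for i in self.instances.values()))

    def validate(self) -> None:
        for (ia, da), (ib, db) in self.bonds:
            if ia not in self.instances or ib not in self.instances:
                raise SpecError("bond endpoint outside complex")
            d1 = self.instances[ia].strand.domains[da]
            d2 = self.instances[ib].strand.domains[db]
            if not is_complementary(d1, d2):
                raise SpecError(
                    f"bond joins non-complementary domains {d1} / {d2}"
                )
            if ia == ib and abs(da - db) <= 1:
                raise SpecError("intra-strand bond between adjacent domains")
        # each domain in at most one bond
        seen: set[End] = set()
        for bond in self.bonds:
            for end in bond:
                if end in seen:
                    raise SpecError(f"domain {end} in more than one bond")
                seen.add(end)
        if len(self.instances) > 1:
            # connectivity over strand instances
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(self.instances)
            for (ia, _), (ib, _) in self.bonds:
                g.add_edge(ia, ib)
            if not nx.is_connected(g):
                raise SpecError("complex is not connected")
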