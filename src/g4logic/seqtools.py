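"""Synthetic sequence design and validation for circuit specifications.

The platform's physical oligo sequences are not part of this package; a
seeded generator assigns synthetic stand-in sequences to domain names under
simple composition constraints (GC window, homopolymer cap) and screens the
finished roster for unintended complementarity ("crosstalk") that would
violate the assumption that separated subunits cannot spontaneously
assemble.  The same machinery provides the randomized-circuit fixture
generator used by the enumeration property tests.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field, replace

from .circuit import CircuitSpec
from .core import Domain, Role, SpecError, Strand
from .designs import PATTERN_BUILDERS

#: synthetic placeholder for the peroxidase-mimicking G-quadruplex motif
#: (four G-tracts); the physical design uses its own published G4 sequence
DEFAULT_G4_MOTIF = "GGGTAGGGCGGGTTGGG"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceDesignError(RuntimeError):
    """Constraints could not be satisfied within the retry budget."""


@dataclass(frozen=True)
class SequenceConstraints:
    """Composition constraints for synthetic domain sequences.

    gc_min/gc_max: allowed GC fraction window per domain.
    forbidden_runs: maximum allowed homopolymer length (G-tracts inside the
        G4 motif are exempt -- they are the point of that segment).
    crosstalk_k: minimum unintended complementary stretch (nt) to report.
    seed: RNG seed; fully determines all generated sequences.
    """

    gc_min: float = 0.3
    gc_max: float = 0.7
    forbidden_runs: int = 4
    crosstalk_k: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise SpecError("need 0 <= gc_min <= gc_max <= 1")
        if self.crosstalk_k < 3:
            raise SpecError("crosstalk_k must be >= 3")
        if self.forbidden_runs < 1:
            raise SpecError("forbidden_runs must be >= 1")


@dataclass(frozen=True)
class CrosstalkHit:
    strand_a: str
    strand_b: str
    pos_a: int   # 0-based start on strand_a
    pos_b: int   # 0-based start (5'-most) of the complementary block on b
    length: int


@dataclass
class CrosstalkReport:
    hits: list[CrosstalkHit] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy iff crosstalk found
        return bool(self.hits)

    def max_length(self) -> int:
        return max((h.length for h in self.hits), default=0)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _gc(seq: str) -> float:
    return sum(1 for b in seq if b in "GC") / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _sample_domain(length: int, c: SequenceConstraints,
                   rng: random.Random, tries: int = 500) -> str:
    for _ in range(tries):
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        if not (c.gc_min <= _gc(seq) <= c.gc_max):
            continue
        if _max_run(seq) > c.forbidden_runs:
            continue
        return seq
    raise SequenceDesignError(
        f"no {length}-nt sequence satisfying GC in "
        f"[{c.gc_min}, {c.gc_max}] and homopolymers <= {c.forbidden_runs} "
        f"within {tries} draws"
    )


def _g4_motif(length: int, rng: random.Random) -> str:
    """A four-G-tract motif of the requested length (>= 15 nt)."""
    if length == len(DEFAULT_G4_MOTIF):
        return DEFAULT_G4_MOTIF
    if length < 15:
        raise SequenceDesignError(
            f"G4 segment needs >= 15 nt for four G3 tracts, got {length}"
        )
    spare = length - 12
    gaps = [1, 1, 1]
    for _ in range(spare - 3):
        gaps[rng.randrange(3)] += 1
    out = "GGG"
    for g in gaps:
        out += "".join(rng.choice("AT") for _ in range(g)) + "GGG"
    return out


def _base_domains(spec: CircuitSpec) -> dict[str, tuple[int, bool]]:
    """name -> (length, is_g4) over every domain occurrence; lengths must
    agree across occurrences."""
    table: dict[str, tuple[int, bool]] = {}
    for s in (*spec.strands, *spec.inputs):
        for d in s.domains:
            is_g4 = d.role is Role.G4_SEGMENT
            prev = table.get(d.name)
            if prev is not None and prev[0] != d.length:
                raise SpecError(
                    f"domain {d.name!r} used with conflicting lengths"
                )
            table[d.name] = (d.length, is_g4 or (prev[1] if prev else False))
    return table


def _attach(spec: CircuitSpec, seq_of: dict[str, str]) -> CircuitSpec:
    def strand_seq(s: Strand) -> str:
        out = []
        for d in s.domains:
            base = seq_of[d.name]
            out.append(revcomp(base) if d.starred else base)
        return "".join(out)

    return replace(
        spec,
        strands=tuple(replace(s, sequence=strand_seq(s)) for s in spec.strands),
        inputs=tuple(replace(s, sequence=strand_seq(s)) for s in spec.inputs),
    )


def generate_sequences(
    spec: CircuitSpec,
    constraints: SequenceConstraints | None = None,
    g4_motif: str | None = None,
    max_redraws: int = 500,
) -> CircuitSpec:
    """Assign one synthetic sequence per domain name; starred occurrences
    get the exact reverse complement.

    Design loop: draw every domain under the composition constraints, then
    iteratively redraw the domain most involved in unintended complementary
    stretches (crosstalk) until the scan is clean -- targeted redraws, since
    coincidental short complements are near-certain on a fresh roster and
    vanish quickly under local repair.  Bounded by ``max_redraws``; failure
    raises :class:`SequenceDesignError`.  Deterministic given the
    constraint seed.
    """
    c = constraints or SequenceConstraints()
    rng = random.Random(c.seed)
    table = _base_domains(spec)
    seq_of: dict[str, str] = {}
    for name in sorted(table):
        length, is_g4 = table[name]
        if is_g4:
            motif = g4_motif if g4_motif is not None else _g4_motif(
                length, rng
            )
            if len(motif) != length:
                raise SpecError(
                    f"G4 motif length {len(motif)} != domain length {length}"
                )
            seq_of[name] = motif
        else:
            seq_of[name] = _sample_domain(length, c, rng)
    report = None
    for _ in range(max_redraws):
        out = _attach(spec, seq_of)
        report = crosstalk_scan(out, c)
        if not report:
            return out
        votes: dict[str, int] = {}
        by_name = {s.name: s for s in (*out.strands, *out.inputs)}
        for h in report.hits:
            for sname, lo, ln in (
                (h.strand_a, h.pos_a, h.length),
                (h.strand_b, h.pos_b, h.length),
            ):
                for d, off in _domain_offsets(by_name[sname]):
                    overlaps = off < lo + ln and lo < off + d.length
                    if overlaps and not table[d.name][1]:  # g4 motif is fixed
                        votes[d.name] = votes.get(d.name, 0) + 1
        if not votes:
            break  # remaining crosstalk sits inside the immutable G4 motif
        worst = max(sorted(votes), key=lambda n: votes[n])
        seq_of[worst] = _sample_domain(table[worst][0], c, rng)
    raise SequenceDesignError(
        f"crosstalk >= {c.crosstalk_k} nt persisted after {max_redraws} "
        f"targeted redraws (worst stretch "
        f"{report.max_length() if report else '?'} nt)"
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _domain_offsets(s: Strand) -> list[tuple[Domain, int]]:
    out = []
    off = 0
    for d in s.domains:
        out.append((d, off))
        off += d.length
    return out


def check_complementarity(spec: CircuitSpec) -> dict[str, bool]:
    """Exact reverse-complement check per declared complementary domain name.

    For every domain name that occurs in both orientations anywhere in the
    circuit, every starred occurrence's subsequence must equal the reverse
    complement of every plain occurrence's.  Returns name -> pass.
    """
    occ: dict[tuple[str, bool], set[str]] = {}
    for s in (*spec.strands, *spec.inputs):
        if s.sequence is None:
            raise SpecError(f"strand {s.name!r} carries no sequence")
        for d, off in _domain_offsets(s):
            occ.setdefault((d.name, d.starred), set()).add(
                s.sequence[off : off + d.length]
            )
    verdict: dict[str, bool] = {}
    names = {n for n, _ in occ}
    for name in sorted(names):
        plain = occ.get((name, False), set())
        starred = occ.get((name, True), set())
        if not plain or not starred:
            continue  # never paired by design
        ok = (
            len(plain) == 1
            and len(starred) == 1
            and next(iter(starred)) == revcomp(next(iter(plain)))
        )
        verdict[name] = ok
    return verdict


def _declared_basepairs(s1: Strand, s2: Strand) -> set[tuple[int, int]]:
    """Base-pair positions (i on s1, j on s2) implied by declared
    domain-level complementarity between the two strands."""
    pairs: set[tuple[int, int]] = set()
    for d1, o1 in _domain_offsets(s1):
        for d2, o2 in _domain_offsets(s2):
            if d1.name == d2.name and d1.starred != d2.starred:
                L = d1.length
                for t in range(L):
                    pairs.add((o1 + t, o2 + L - 1 - t))
    return pairs


def _wc(b1: str, b2: str) -> bool:
    return b2 == b1.translate(_COMPLEMENT)


def crosstalk_scan(
    spec: CircuitSpec, constraints: SequenceConstraints | None = None
) -> CrosstalkReport:
    """Exhaustive scan for unintended complementary stretches.

    Brute force over every strand pair (including each strand against
    itself) and every antiparallel alignment; maximal complementary
    stretches of at least ``crosstalk_k`` nt are reported unless fully
    contained in a declared domain pairing.  Complete by construction.
    """
    c = constraints or SequenceConstraints()
    strands = [*spec.strands, *spec.inputs]
    for s in strands:
        if s.sequence is None:
            raise SpecError(f"strand {s.name!r} carries no sequence")
    report = CrosstalkReport()
    for a in range(len(strands)):
        for b in range(a, len(strands)):
            s1, s2 = strands[a], strands[b]
            q1, q2 = s1.sequence, s2.sequence
            declared = _declared_basepairs(s1, s2)
            n1, n2 = len(q1), len(q2)
            for i0 in range(n1):
                for j0 in range(n2 - 1, -1, -1):
                    if a == b and j0 <= i0:
                        continue
                    if not _wc(q1[i0], q2[j0]):
                        continue
                    # maximal: not extendable backwards
                    if (
                        i0 > 0
                        and j0 + 1 < n2
                        and not (a == b and j0 + 1 <= i0 - 1)
                        and _wc(q1[i0 - 1], q2[j0 + 1])
                    ):
                        continue
                    k = 0
                    while (
                        i0 + k < n1
                        and j0 - k >= 0
                        and not (a == b and j0 - k <= i0 + k)
                        and _wc(q1[i0 + k], q2[j0 - k])
                    ):
                        k += 1
                    if k < c.crosstalk_k:
                        continue
                    # only the undeclared portion counts: a stretch that
                    # merely extends an intended duplex by a couple of
                    # coincidental pairs is not a separate binding site
                    undeclared = [
                        (i0 + t, j0 - t) not in declared for t in range(k)
                    ]
                    t = 0
                    while t < k:
                        if not undeclared[t]:
                            t += 1
                            continue
                        t1 = t
                        while t1 < k and undeclared[t1]:
                            t1 += 1
                        seg = t1 - t
                        if seg >= c.crosstalk_k:
                            report.hits.append(
                                CrosstalkHit(
                                    strand_a=s1.name,
                                    strand_b=s2.name,
                                    pos_a=i0 + t,
                                    pos_b=j0 - (t1 - 1),
                                    length=seg,
                                )
                            )
                        t = t1
    report.hits.sort(
        key=lambda h: (h.strand_a, h.strand_b, h.pos_a, h.pos_b)
    )
    return report


# ---------------------------------------------------------------------------
# randomized circuit fixtures
# ---------------------------------------------------------------------------

_LENGTH_RANGES = {
    Role.TOEHOLD: (5, 7),
    Role.RECOGNITION_ARM: (10, 14),
    Role.SUBSTRATE_ARM: (7, 9),
    Role.CORE_I: (7, 9),
    Role.CORE_II: (7, 9),
    Role.GENERIC: (10, 14),
    Role.G4_SEGMENT: (17, 17),
}


def generate_random_circuit(pattern: str, seed: int) -> CircuitSpec:
    """A structurally valid random circuit following one of the three
    reusable assembly patterns, with randomized domain names and lengths.

    ``input_assembled`` circuits compute OR, ``cooperative`` AND, and
    ``template_disassembly`` NOR; the layout is the pattern's, everything
    nameable is randomized.  Deterministic per (pattern, seed).
    """
    try:
        builder = PATTERN_BUILDERS[pattern]
    except KeyError:
        raise SpecError(
            f"unknown pattern {pattern!r}; available: "
            + ", ".join(PATTERN_BUILDERS)
        ) from None
    rng = random.Random(("circuit", pattern, seed).__repr__())
    reference = builder()
    keys: dict[str, Role] = {}
    for s in (*reference.strands, *reference.inputs):
        for d in s.domains:
            keys.setdefault(d.name, d.role)
    names: dict[str, str] = {}
    used: set[str] = set()
    for key in sorted(keys):
        while True:
            token = "".join(rng.choice(string.ascii_lowercase)
                            for _ in range(4))
            if token not in used:
                used.add(token)
                names[key] = token
                break
    lengths = {
        key: rng.randint(*_LENGTH_RANGES[keys[key]]) for key in sorted(keys)
    }
    spec = builder(names=names, lengths=lengths)
    return replace(spec, name=f"{pattern}-{seed}")
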