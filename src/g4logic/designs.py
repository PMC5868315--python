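"""Parametrized builders for the gate library.

Every builder lays out one of the platform's assembly patterns:

* input-assembled DNAzyme: two subunits co-assemble on one input scaffold
  (the OR/XOR building block);
* cooperative two-input assembly: the inputs cross-hybridize via C/C' and
  each carries one subunit, juxtaposing the catalytic halves at the junction
  (the AND building block);
* template-assembled DNAzyme disassembled by inputs through toehold-mediated
  strand displacement (the NOR building block; toeholds E/H flank the
  template).

Builders take optional ``names``/``lengths`` overrides so the same layouts
also serve as the randomized-circuit fixture generator.  Domain lengths
default to common strand-displacement practice: 6 nt toeholds, 12 nt
recognition arms, 8 nt substrate arms, 8+7 nt catalytic core halves, 17 nt
G4 segment.
"""

from __future__ import annotations

from typing import Callable, Mapping, Optional

from .circuit import CircuitSpec
from .core import DEFAULT_LENGTHS, Domain, Role, Strand


class _Dom:
    """Domain factory with per-circuit name/length overrides."""

    def __init__(self, names: Optional[Mapping[str, str]] = None,
                 lengths: Optional[Mapping[str, int]] = None) -> None:
        self.names = dict(names or {})
        self.lengths = dict(lengths or {})

    def __call__(self, key: str, role: Role = Role.GENERIC,
                 star: bool = False, length: Optional[int] = None) -> Domain:
        return Domain(
            name=self.names.get(key, key),
            length=self.lengths.get(key, length or DEFAULT_LENGTHS[role]),
            starred=star,
            role=role,
        )


def _substrate(d: _Dom, name: str) -> Strand:
    """Hairpin reporter: caged G4 in the stem, rA in the loop.

    5'-[G4 segment | loop-left] rA [loop-right | G4 clamp]-3'; the clamp is
    the starred complement of the G4 segment, so the hairpin self-folds and
    cleavage at the rA releases the G4-bearing 5' fragment.
    """
    return Strand(
        name,
        (
            d("g4", Role.G4_SEGMENT),
            d("sL", Role.GENERIC, length=8),
            d("sR", Role.GENERIC, length=8),
            d("g4", Role.G4_SEGMENT, star=True),
        ),
        ra_site=2,
        caged_g4=(0, 0),
    )


def _sub_i(d: _Dom, name: str, arm_key: str, arm_star: bool = True) -> Strand:
    """Subunit carrying catalytic core half I:
    5'-[substrate arm | core I | recognition arm]-3'."""
    return Strand(
        name,
        (
            d("sL", Role.SUBSTRATE_ARM, star=True, length=8),
            d("cI", Role.CORE_I),
            d(arm_key, Role.RECOGNITION_ARM, star=arm_star),
        ),
    )


def _sub_ii(d: _Dom, name: str, arm_key: str, arm_star: bool = True) -> Strand:
    """Subunit carrying catalytic core half II:
    5'-[recognition arm | core II | substrate arm]-3'."""
    return Strand(
        name,
        (
            d(arm_key, Role.RECOGNITION_ARM, star=arm_star),
            d("cII", Role.CORE_II),
            d("sR", Role.SUBSTRATE_ARM, star=True, length=8),
        ),
    )


def _gen(d: _Dom, key: str, star: bool = False) -> Domain:
    return d(key, Role.GENERIC, star=star)


# ---------------------------------------------------------------------------
# main-text circuits
# ---------------------------------------------------------------------------

def build_xor(names=None, lengths=None) -> CircuitSpec:
    """XOR: two input-assembled DNAzymes on mutually complementary inputs.

    Either input alone scaffolds one DNAzyme; together the inputs form a
    full-length duplex (the largest possible pairing, so it wins) and no
    enzyme can assemble.  Each DNAzyme reads a disjoint half of the
    input duplex so that the two subunit sets stay orthogonal.
    """
    d = _Dom(names, lengths)
    input1 = Strand("input1", tuple(_gen(d, k) for k in "abcq"))
    input2 = Strand("input2", tuple(_gen(d, k, star=True) for k in "qcba"))
    return CircuitSpec(
        name="XOR",
        strands=(
            _sub_i(d, "DNA1", "a"),
            _sub_ii(d, "DNA2", "b"),
            _sub_i(d, "DNA3", "c", arm_star=False),
            _sub_ii(d, "DNA4", "q", arm_star=False),
            _substrate(d, "DNA5"),
        ),
        inputs=(input1, input2),
        declared_function=(0, 1, 1, 0),
    )


def build_or(names=None, lengths=None) -> CircuitSpec:
    """OR: one input-assembled DNAzyme per input, on orthogonal inputs."""
    d = _Dom(names, lengths)
    input1 = Strand(
        "input1", (d("t1", Role.TOEHOLD), _gen(d, "a"), _gen(d, "b"))
    )
    input2 = Strand(
        "input2", (d("t2", Role.TOEHOLD), _gen(d, "c"), _gen(d, "q"))
    )
    return CircuitSpec(
        name="OR",
        strands=(
            _sub_i(d, "DNA1", "a"),
            _sub_ii(d, "DNA2", "b"),
            _sub_i(d, "DNA3", "c"),
            _sub_ii(d, "DNA4", "q"),
            _substrate(d, "DNA5"),
        ),
        inputs=(input1, input2),
        declared_function=(0, 1, 1, 1),
    )


def build_and(names=None, lengths=None) -> CircuitSpec:
    """AND: cooperative two-input assembly.

    The inputs cross-hybridize via segments C/C'; only the assembled
    junction juxtaposes the two subunits bound on either input, giving a
    synergistically stabilized active DNAzyme.  One input alone binds its
    subunit but cannot activate it.
    """
    d = _Dom(names, lengths)
    input1 = Strand("input1", (_gen(d, "A"), _gen(d, "C")))
    input2 = Strand("input2", (_gen(d, "C", star=True), _gen(d, "B")))
    return CircuitSpec(
        name="AND",
        strands=(
            _sub_i(d, "DNA1", "A"),
            _sub_ii(d, "DNA2", "B"),
            _substrate(d, "DNA3"),
        ),
        inputs=(input1, input2),
        declared_function=(0, 0, 0, 1),
    )


def build_xor_and(names=None, lengths=None) -> CircuitSpec:
    """XOR + AND multilevel circuit (overall OR behavior).

    DNA1-DNA4 form the XOR layer on the complementary halves of the inputs.
    The inter-input duplex at (1,1) draws the dangling domains E and F
    together at the same duplex end, scaffolding a fifth/sixth subunit pair
    (DNA5/DNA6) into the AND layer's active DNAzyme.
    """
    d = _Dom(names, lengths)
    input1 = Strand("input1", (_gen(d, "E"), *(_gen(d, k) for k in "abcq")))
    input2 = Strand(
        "input2", (*(_gen(d, k, star=True) for k in "qcba"), _gen(d, "F"))
    )
    return CircuitSpec(
        name="XOR_AND",
        strands=(
            _sub_i(d, "DNA1", "a"),
            _sub_ii(d, "DNA2", "b"),
            _sub_i(d, "DNA3", "q", arm_star=False),
            _sub_ii(d, "DNA4", "c", arm_star=False),
            _sub_i(d, "DNA5", "E"),
            _sub_ii(d, "DNA6", "F"),
            _substrate(d, "DNA7"),
        ),
        inputs=(input1, input2),
        declared_function=(0, 1, 1, 1),
    )


def _template_xor(name: str, declared, provenance, names=None, lengths=None
                  ) -> CircuitSpec:
    """Shared layout: template-assembled DNAzyme (NOR layer) + two
    input-assembled DNAzymes (XOR layer), overall NAND behavior.

    The template DNA1 holds DNA6/DNA7 assembled and active at rest.  Each
    input carries a displacement tail (migration domain + toehold E or H)
    that strips one template subunit, plus a scaffold region read by the
    XOR-layer subunits; the scaffold regions of the two inputs are
    complementary, so at (1,1) the preferred inter-input duplex blocks the
    XOR layer while the still-free tails disassemble the template enzyme.
    """
    d = _Dom(names, lengths)
    template = Strand(
        "DNA1",
        (
            d("E", Role.TOEHOLD),
            _gen(d, "p"),
            _gen(d, "r"),
            d("H", Role.TOEHOLD),
        ),
    )
    input1 = Strand(
        "input1",
        (
            *(_gen(d, k) for k in "abcq"),
            _gen(d, "p", star=True),
            d("E", Role.TOEHOLD, star=True),
        ),
    )
    input2 = Strand(
        "input2",
        (
            d("H", Role.TOEHOLD, star=True),
            _gen(d, "r", star=True),
            *(_gen(d, k, star=True) for k in "qcba"),
        ),
    )
    return CircuitSpec(
        name=name,
        strands=(
            template,
            _sub_i(d, "DNA2", "a"),
            _sub_ii(d, "DNA3", "b"),
            _sub_i(d, "DNA4", "q", arm_star=False),
            _sub_ii(d, "DNA5", "c", arm_star=False),
            _sub_i(d, "DNA6", "p"),
            _sub_ii(d, "DNA7", "r"),
            _substrate(d, "DNA8"),
        ),
        inputs=(input1, input2),
        declared_function=declared,
        provenance=provenance,
    )


def build_xor_nor(names=None, lengths=None) -> CircuitSpec:
    """XOR + NOR multilevel circuit (overall NAND behavior)."""
    return _template_xor("XOR_NOR", (1, 1, 1, 0), "reference", names, lengths)


# ---------------------------------------------------------------------------
# reconstructed elementary gates (published only as supplementary designs;
# rebuilt here from the three reusable patterns above)
# ---------------------------------------------------------------------------

def build_nand(names=None, lengths=None) -> CircuitSpec:
    return _template_xor("NAND", (1, 1, 1, 0), "reconstructed", names,
                         lengths)


def build_nor(names=None, lengths=None) -> CircuitSpec:
    """NOR: bare template-disassembly pattern; either input strips one
    subunit off the template enzyme."""
    d = _Dom(names, lengths)
    template = Strand(
        "DNA1",
        (
            d("E", Role.TOEHOLD),
            _gen(d, "p"),
            _gen(d, "r"),
            d("H", Role.TOEHOLD),
        ),
    )
    input1 = Strand(
        "input1", (_gen(d, "p", star=True), d("E", Role.TOEHOLD, star=True))
    )
    input2 = Strand(
        "input2", (d("H", Role.TOEHOLD, star=True), _gen(d, "r", star=True))
    )
    return CircuitSpec(
        name="NOR",
        strands=(
            template,
            _sub_i(d, "DNA2", "p"),
            _sub_ii(d, "DNA3", "r"),
            _substrate(d, "DNA4"),
        ),
        inputs=(input1, input2),
        declared_function=(1, 0, 0, 0),
        provenance="reconstructed",
    )


def build_inhibit(names=None, lengths=None) -> CircuitSpec:
    """INHIBIT (input1 AND NOT input2): input1 scaffolds the enzyme;
    input2 is input1's full complement and sequesters it."""
    d = _Dom(names, lengths)
    input1 = Strand("input1", (_gen(d, "a"), _gen(d, "b")))
    input2 = Strand(
        "input2", (_gen(d, "b", star=True), _gen(d, "a", star=True))
    )
    return CircuitSpec(
        name="INHIBIT",
        strands=(
            _sub_i(d, "DNA1", "a"),
            _sub_ii(d, "DNA2", "b"),
            _substrate(d, "DNA3"),
        ),
        inputs=(input1, input2),
        declared_function=(0, 1, 0, 0),
        provenance="reconstructed",
    )


def build_implication(names=None, lengths=None) -> CircuitSpec:
    """IMPLICATION (NOT input1 OR input2): a template enzyme active at rest
    that input1 disassembles, plus an input2-assembled enzyme."""
    d = _Dom(names, lengths)
    template = Strand(
        "DNA1", (d("E", Role.TOEHOLD), _gen(d, "p"), _gen(d, "r"))
    )
    input1 = Strand(
        "input1", (_gen(d, "p", star=True), d("E", Role.TOEHOLD, star=True))
    )
    input2 = Strand("input2", (_gen(d, "m"), _gen(d, "n")))
    return CircuitSpec(
        name="IMPLICATION",
        strands=(
            template,
            _sub_i(d, "DNA2", "p"),
            _sub_ii(d, "DNA3", "r"),
            _sub_i(d, "DNA4", "m"),
            _sub_ii(d, "DNA5", "n"),
            _substrate(d, "DNA6"),
        ),
        inputs=(input1, input2),
        declared_function=(1, 0, 1, 1),
        provenance="reconstructed",
    )


def build_xnor(names=None, lengths=None) -> CircuitSpec:
    """XNOR: template enzyme active at rest, disassembled by either input;
    at (1,1) the inter-input duplex juxtaposes dangling domains G and F
    that scaffold a fresh subunit pair."""
    d = _Dom(names, lengths)
    template = Strand(
        "DNA1",
        (
            d("E", Role.TOEHOLD),
            _gen(d, "p"),
            _gen(d, "r"),
            d("H", Role.TOEHOLD),
        ),
    )
    input1 = Strand(
        "input1",
        (
            _gen(d, "G"),
            _gen(d, "m"),
            _gen(d, "p", star=True),
            d("E", Role.TOEHOLD, star=True),
        ),
    )
    input2 = Strand(
        "input2",
        (
            d("H", Role.TOEHOLD, star=True),
            _gen(d, "r", star=True),
            _gen(d, "m", star=True),
            _gen(d, "F"),
        ),
    )
    return CircuitSpec(
        name="XNOR",
        strands=(
            template,
            _sub_i(d, "DNA2", "p"),
            _sub_ii(d, "DNA3", "r"),
            _sub_i(d, "DNA4", "G"),
            _sub_ii(d, "DNA5", "F"),
            _substrate(d, "DNA6"),
        ),
        inputs=(input1, input2),
        declared_function=(1, 0, 0, 1),
        provenance="reconstructed",
    )


BUILDERS: dict[str, Callable[..., CircuitSpec]] = {
    "XOR": build_xor,
    "OR": build_or,
    "AND": build_and,
    "XNOR": build_xnor,
    "NAND": build_nand,
    "NOR": build_nor,
    "INHIBIT": build_inhibit,
    "IMPLICATION": build_implication,
    "XOR_AND": build_xor_and,
    "XOR_NOR": build_xor_nor,
}

#: the three reusable assembly patterns, as randomized-fixture templates
PATTERN_BUILDERS: dict[str, Callable[..., CircuitSpec]] = {
    "input_assembled": build_or,
    "cooperative": build_and,
    "template_disassembly": build_nor,
}
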