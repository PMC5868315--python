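# Methods

## Scope and abstraction level

`g4logic` models split-DNAzyme logic circuits at the *domain* level: a
strand is an ordered 5'→3' list of named segments that hybridize as
indivisible antiparallel units, and `x` pairs only with `x*` (same name and
length, opposite orientation). This is the abstraction at which such gates
are designed and communicated; base-level detail (mismatches, bulges,
nearest-neighbor thermodynamics, pseudoknot geometry) is out of scope.
Concrete sequences exist in the package only as synthetic, seeded stand-ins
used for sequence-level lint (reverse-complement checks, crosstalk
screening) and FASTA export — never for reaction logic.

## Endpoint semantics

The platform's observable is a color after a fixed incubation, and no rate
constants are available, so the engine computes *endpoints*, not kinetics.
Two rules change connectivity:

**R1 (hybridization).** All candidate pairings between strand instances are
scored by total paired nucleotides over currently free domains (the best
non-overlapping set of maximal antiparallel runs per strand pair); the
highest-scoring candidate is applied first, ties broken by sorted strand
names then instance ids. This single priority reproduces "preferred
inter-input hybridization": a full-length input1:input2 duplex (48 nt in the
XOR-family designs) always outcompetes any 12-nt input:subunit arm pairing.
Candidates are considered between any two strand instances, including two
instances already in one complex — necessary so that, e.g., the second input
of the XOR+NOR circuit can still bind the template toehold after the
inter-input duplex has merged everything into one complex (and so endpoints
are invariant under input relabeling).

**R2 (toehold-mediated displacement).** An invader already bound adjacent to
a duplex held by an incumbent migrates through it, transferring bonds.
Because R1 has priority and binds any free complementary pair, the anchoring
toehold bond is always formed by R1; the migration itself conserves paired
nucleotides, and the logged Δ of a displacement is the anchoring domain
length — the net gain of the overall displacement transaction and its
thermodynamic bias. Only *complete* displacements are applied (the invader
must take over every bond the incumbent holds on the target): partial
takeovers between equal invaders are reversible fraying with no net driver,
and excluding them removes ping-pong nonterminating exchanges.
Zero-toehold exchange is disallowed. Termination: R1 strictly increases
total paired nucleotides (bounded by total content); R2 strictly decreases
the number of strands holding bonds on contested helices and cannot be
undone without a fresh anchor; a step cap (default 10⁴ applications) guards
the loop regardless.

**Two-phase initialization.** `run_gate` first anneals the roster without
inputs (hybridization/displacement to fixpoint), then adds the present
inputs at one copy each and re-runs. This mirrors the bench protocol, where
gate components are prepared before inputs are supplied, and it is load-
bearing for the template gates: the template-assembled DNAzyme must exist
*before* an input arrives, otherwise the input would simply hybridize onto
the naked template and no displacement event would ever occur.

## Activity, cleavage, release

**R3 (detection).** A split DNAzyme is active iff an unpaired core-I domain
and an unpaired core-II domain on two different subunits are juxtaposed:
each core's flanking *recognition arm* is bound, and the two scaffold
positions are adjacent — consecutive domains of one scaffold strand, or
positions flanking the junction bond of two scaffold strands that are
directly cross-hybridized (the cooperative two-input geometry of the AND
gate and of the E/F- and G/F-scaffolded subunit pairs in the multilevel
circuits). Substrate arms are excluded from this criterion: substrate
binding alone never activates an enzyme. The criterion does not model arm
orientation (which way a core faces along the scaffold); all shipped and
generated designs are laid out so that adjacency implies correct facing,
but adversarial hand-built complexes could in principle over-count.

**R4 (cleavage).** Catalytic turnover is collapsed to all-or-none: if at
least one active DNAzyme exists and the Mg²⁺ flag is set, every substrate
copy is cleaved at its embedded ribonucleotide. The strand splits into 5'
and 3' fragments; bonds move with their domains; fragment provenance is
recorded so nucleotide content is conserved exactly.

**R5 (release).** On cleavage the stem joining the two fragments — now an
unclamped bimolecular duplex flanking a nick — dissociates, and the G-rich
strand folds into its quadruplex. Each cleaved substrate whose caged-G4
span survives intact and unpaired on one fragment contributes one active
reporter. No hybridization pass runs after cleavage: at domain level the
freed clamp could re-bind the G4 segment, whereas physically the quadruplex
fold (hemin-stabilized) wins; the rule order hybridize/displace → detect →
cleave → release encodes that.

## Readout model

Released fraction maps to absorbance linearly:
`A₆₅₀ = a_bg + (a_max − a_bg)·f` with defaults `a_bg = 0.02`, `a_max = 1.0`.
The platform specifies only the two endpoint states and the decision rule,
so the linear form is calibrated to the threshold, not to reported bar
heights. Binarization is strict: output 1 iff `A₆₅₀ > 0.1`; exactly 0.1
reads 0. Hemin, TMB and H₂O₂ are boolean preconditions (any missing
cofactor pins the signal at background); their concentrations are out of
scope. With defaults, any released fraction ≥ (0.1−0.02)/0.98 ≈ 0.0816
reads 1 — endpoint fractions are 0 or 1, far from the crossing. An optional
`leak` parameter (default 0) adds a fixed background cleaved fraction; it is
off because the modeled platform shows clean negative states.

## Gate designs

The five main circuits follow their published layouts; domain names from the
original schematics are kept where the text names them (C/C' in AND, E/F in
XOR+AND, toeholds E/H in XOR+NOR). Where schematics leave freedom, domain
lengths default to common strand-displacement practice: toeholds 6 nt,
recognition arms 12 nt, substrate arms 8 nt (short arms reflect
catalytic-turnover designs and keep substrate clamping below recognition
priority), catalytic core halves 8+7 nt, G4 segment 17 nt.

One structural choice is the package's own: XOR-family inputs carry a
**four-domain** complementary scaffold region, each DNAzyme reading a
disjoint half. With the minimal toehold+two-arm input, the arms recognizing
input2 are complements of the arms recognizing input1, so the two subunit
sets pair with *each other* at rest and poison the gate under endpoint
semantics; disjoint halves make the subunit sets mutually orthogonal while
preserving the full-length inter-input duplex. XOR+NOR inputs additionally
carry a two-domain displacement tail (migration domain + toehold complement)
that stays single-stranded inside the inter-input duplex, so at (1,1) the
duplex blocks the XOR layer while both tails still disassemble the template
enzyme — both effects the mechanism requires.

The five elementary gates published only as supplementary designs (XNOR,
NAND, NOR, INHIBIT, IMPLICATION) are *reconstructed* from the three reusable
patterns — input-assembled DNAzyme, cooperative two-input assembly, and
template assembly disassembled by displacement — and are validated
functionally (truth tables, mechanism properties), not structurally; their
spec files carry `provenance: reconstructed`.

Inputs are presence-only at one copy each (stoichiometric with the roster);
excess-stoichiometry effects are out of scope.

## Synthetic sequence design

`generate_sequences` assigns one random sequence per domain name (GC
fraction within [0.3, 0.7], homopolymers ≤ 4 nt; the G4 segment uses a fixed
four-G-tract placeholder motif, exempt from the homopolymer cap), with
starred domains as exact reverse complements. Coincidental short
complements are near-certain on a fresh roster, so the designer then
iteratively redraws the domain most involved in unintended complementary
stretches ≥ `crosstalk_k` (default 6 nt) until the exhaustive crosstalk scan
is clean, bounded at 500 redraws; in practice the library rosters converge
within ~10. The scan counts only the *undeclared* portion of a stretch: a
couple of coincidental pairs extending an intended duplex are not a separate
binding site. Everything is driven by one seed; a seed fully determines the
roster.

The randomized-circuit generator re-instantiates the three assembly patterns
with random domain names and lengths (toeholds 5–7 nt, arms 10–14 nt,
substrate arms 7–9 nt, cores 7–9 nt) and is the fixture source for the
termination/conservation/determinism property suites (100 seeds, all four
input states each — small enough to run in seconds, large enough to exercise
every rule path).

## What passing tests do and do not show

The simulator reproduces the platform's Boolean surface — all ten truth
tables, the threshold rule, the mechanistic signatures (inter-input duplex
at XOR(1,1), two enzymes at OR(1,1), intact template enzyme at XOR+NOR(0,0),
displacement at toehold E at XOR+NOR(1,0)) — and the negative controls
(no Mg²⁺, no substrate, no hemin ⇒ no signal). It does not predict
absorbance magnitudes, kinetics, temperature/pH/ionic-strength dependence,
leak rates of real oligo batches, or behavior in serum; synthetic sequences
share only the declared complementarity structure with any physical
implementation.

## Reports and reproducibility

Every run is deterministic; reports (rule logs, truth tables, crosstalk
tables) are TSV with an embedded manifest (tool version, circuit, inputs,
seed, config). Timestamps are opt-in and excluded by default so that
identical runs produce byte-identical files.
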