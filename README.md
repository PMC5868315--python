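# g4logic

Domain-level simulator of enzyme-free, label-free DNA logic gates built from
split Mg²⁺-dependent DNAzymes and read out colorimetrically through a caged
G-quadruplex.

## The system being modeled

A class of molecular computing platforms encodes Boolean logic directly in
DNA hybridization. The computing element is a **split DNAzyme**: an
Mg²⁺-dependent deoxyribozyme divided into two inactive subunits carrying the
catalytic-core halves I and II. Input strands guide the subunits'
recognition arms onto a shared scaffold (an input, a cross-hybridized input
pair, or a pre-assembled template), juxtaposing the core halves into an
active enzyme. The active DNAzyme cleaves a hairpin substrate at its single
embedded ribonucleotide (rA); the hairpin's stem cages a G-rich
peroxidase-mimicking sequence, so cleavage releases an active
**G-quadruplex** that, with hemin, catalyzes TMB oxidation by H₂O₂ and turns
the solution blue. Absorbance at λ = 650 nm strictly above the threshold
0.1 reads "1"; otherwise "0". Gates are *disassembled* as well as
assembled: inputs can strip a template-bound enzyme by toehold-mediated
strand displacement, giving NOT-like behavior.

`g4logic` reproduces this platform in silico for researchers designing or
verifying such circuits. It ships ten circuits: the elementary two-input
gates XOR, OR, AND, XNOR, NAND, NOR, INHIBIT and IMPLICATION, plus two
multilevel circuits — XOR+AND (overall OR behavior) and XOR+NOR (overall
NAND behavior) — and verifies each against its declared truth table.

## The model

Strands are ordered 5'→3' lists of *domains*; domain `x` pairs only with
`x*`. A deterministic rule engine evolves a mixture to its endpoint:

- **R1 hybridize** — among all candidate pairings over free domains, the one
  forming the most paired nucleotides is applied first (ties broken
  lexicographically). This "longest duplex first" priority realizes
  preferred inter-input hybridization without free-energy computation.
- **R2 toehold displacement** — an invader anchored next to a contested
  duplex takes over the incumbent's entire block; the anchoring toehold is
  the transaction's net thermodynamic gain.
- **R3 detect** — a DNAzyme is active iff core-I and core-II halves on two
  subunits are juxtaposed by recognition arms bound at adjacent scaffold
  positions (or flanking the junction bond of two cross-hybridized
  scaffolds).
- **R4 cleave** — any active DNAzyme with Mg²⁺ present cleaves every
  substrate copy at the rA (catalytic turnover, all-or-none endpoint).
- **R5 release** — each cleaved substrate whose caged-G4 span survives
  unpaired on a fragment yields one active reporter.

The released fraction maps linearly to A₆₅₀ between a background (0.02) and
a saturating absorbance (1.0), then binarizes at the strict 0.1 threshold.
See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```bash
$ g4logic simulate --circuit XOR --inputs 1,0
circuit	XOR
inputs	1,0
fraction_released	1
a650	1
output_bit	1
color	blue
```

With only input1 present, the XOR gate's DNA1/DNA2 subunits assemble on the
input scaffold, the substrate hairpin is cleaved, the whole reporter pool is
released (`fraction_released 1`), the modeled absorbance 1.0 exceeds the 0.1
threshold, and the solution reads blue = logical 1. The full library check:

```bash
$ g4logic truth-table --circuit all
...
10/10 circuits match declared functions
```

Python API equivalent:

```python
from g4logic import get_circuit, run_gate

res = run_gate(get_circuit("XOR_NOR"), (1, 0))
print(res.output_bit)            # 1
print([a.detail for a in res.log if a.rule == "R2"])
# ['displace DNA6#5 from DNA1#0 via toehold E']
```

Other commands: `g4logic design --circuit AND --seed 7` writes a synthetic
FASTA roster screened for crosstalk; `g4logic validate FILE` lints a circuit
spec; `g4logic config --show` prints defaults. Circuit files live under
`src/g4logic/circuits/` (schema in `src/g4logic/schemas/`).

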