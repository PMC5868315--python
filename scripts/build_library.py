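"""Regenerate the packaged circuit files under src/g4logic/circuits/ from
the builders in g4logic.designs.  Run from the repository root."""

from pathlib import Path

from g4logic.circuit_io import save_circuit
from g4logic.designs import BUILDERS

OUT = Path(__file__).resolve().parent.parent / "src" / "g4logic" / "circuits"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, builder in BUILDERS.items():
        path = save_circuit(builder(), OUT / f"{name}.yaml")
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
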