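"""Serialization: circuit spec files (YAML/JSON), FASTA rosters, TSV reports.

Circuit file format (``format: g4logic-circuit/1``): strands are lists of
domain tokens ``name[*][/role][:length]`` in 5'->3' order, e.g.
``sL*/substrate_arm:8``.  Roles default to ``generic`` and lengths to the
role default.  The rA cleavage marker is the index of the domain boundary
it sits on; the caged-G4 span is an inclusive ``[start, end]`` index pair.
A machine-readable JSON Schema for the format ships under
``g4logic/schemas/circuit.schema.json``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import metadata, resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .circuit import CircuitSpec
from .core import DEFAULT_LENGTHS, Domain, Role, SpecError, Strand
from .enumeration import RuleApplication

FORMAT_TAG = "g4logic-circuit/1"

_ROLE_BY_VALUE = {r.value: r for r in Role}


def package_version() -> str:
    try:
        return metadata.version("g4logic")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


# ---------------------------------------------------------------------------
# domain tokens
# ---------------------------------------------------------------------------

def domain_to_token(d: Domain) -> str:
    tok = d.name + ("*" if d.starred else "")
    if d.role is not Role.GENERIC:
        tok += f"/{d.role.value}"
    tok += f":{d.length}"
    return tok


def token_to_domain(tok: str) -> Domain:
    body, _, length_s = tok.partition(":")
    name_part, _, role_s = body.partition("/")
    starred = name_part.endswith("*")
    name = name_part[:-1] if starred else name_part
    role = _ROLE_BY_VALUE.get(role_s or "generic")
    if role is None:
        raise SpecError(f"unknown role {role_s!r} in token {tok!r}")
    if length_s:
        try:
            length = int(length_s)
        except ValueError:
            raise SpecError(f"bad length in token {tok!r}") from None
    else:
        length = DEFAULT_LENGTHS[role]
    return Domain(name=name, length=length, starred=starred, role=role)


def _strand_to_dict(s: Strand) -> dict:
    d: dict = {"name": s.name, "domains": [domain_to_token(x) for x in s.domains]}
    if s.ra_site is not None:
        d["ra_site"] = s.ra_site
    if s.caged_g4 is not None:
        d["caged_g4"] = list(s.caged_g4)
    if s.sequence is not None:
        d["sequence"] = s.sequence
    return d


def _strand_from_dict(d: dict) -> Strand:
    try:
        return Strand(
            name=d["name"],
            domains=tuple(token_to_domain(t) for t in d["domains"]),
            sequence=d.get("sequence"),
            ra_site=d.get("ra_site"),
            caged_g4=tuple(d["caged_g4"]) if d.get("caged_g4") else None,
        )
    except KeyError as e:
        raise SpecError(f"strand entry missing key {e}") from None


def circuit_to_dict(spec: CircuitSpec) -> dict:
    return {
        "format": FORMAT_TAG,
        "name": spec.name,
        "provenance": spec.provenance,
        "declared_function": list(spec.declared_function),
        "strands": [_strand_to_dict(s) for s in spec.strands],
        "inputs": [_strand_to_dict(s) for s in spec.inputs],
    }


def circuit_from_dict(data: dict) -> CircuitSpec:
    if data.get("format") != FORMAT_TAG:
        raise SpecError(
            f"unsupported circuit format {data.get('format')!r}; "
            f"expected {FORMAT_TAG!r}"
        )
    for key in ("name", "declared_function", "strands", "inputs"):
        if key not in data:
            raise SpecError(f"circuit file missing key {key!r}")
    return CircuitSpec(
        name=data["name"],
        strands=tuple(_strand_from_dict(s) for s in data["strands"]),
        inputs=tuple(_strand_from_dict(s) for s in data["inputs"]),
        declared_function=tuple(data["declared_function"]),
        provenance=data.get("provenance", "reference"),
    )


def save_circuit(spec: CircuitSpec, path: str | Path) -> Path:
    path = Path(path)
    data = circuit_to_dict(spec)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(
            yaml.safe_dump(data, sort_keys=False, default_flow_style=None)
        )
    return path


def load_circuit(path: str | Path) -> CircuitSpec:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SpecError(f"{path}: not a circuit spec document")
    return circuit_from_dict(data)


def packaged_circuit(name: str) -> CircuitSpec:
    """Load one of the circuit files shipped with the package."""
    ref = resources.files("g4logic").joinpath(f"circuits/{name}.yaml")
    if not ref.is_file():
        raise SpecError(f"no packaged circuit file for {name!r}")
    return circuit_from_dict(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _fasta_record(s: Strand) -> SeqRecord:
    if s.sequence is None:
        raise SpecError(f"strand {s.name!r} carries no sequence")
    seq = s.sequence
    desc = "domains=" + ",".join(s.domain_labels())
    if s.ra_site is not None:
        cut = sum(d.length for d in s.domains[: s.ra_site])
        # single ribonucleotide marked lowercase at the cleavage boundary
        seq = seq[:cut] + "a" + seq[cut:]
        desc += f" rA_after_nt={cut}"
    if s.caged_g4 is not None:
        desc += f" caged_g4_domains={s.caged_g4[0]}-{s.caged_g4[1]}"
    return SeqRecord(Seq(seq), id=s.name, description=desc)


def write_fasta(spec: CircuitSpec, path: str | Path) -> Path:
    """One record per strand (roster first, then inputs), 5'->3'.

    The substrate's embedded ribonucleotide is exported as a lowercase ``a``
    inserted at its boundary (annotated in the description line), so the
    chimeric base survives the plain-DNA alphabet.
    """
    path = Path(path)
    records = [_fasta_record(s) for s in (*spec.strands, *spec.inputs)]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunManifest:
    """Provenance block embedded atop every written report."""

    tool: str = "g4logic"
    version: str = field(default_factory=package_version)
    circuit: str = ""
    inputs: str = ""
    seed: Optional[int] = None
    config: str = ""
    timestamp: Optional[str] = None  # opt-in: breaks byte-reproducibility

    def comment_lines(self) -> list[str]:
        pairs = [
            ("tool", self.tool),
            ("version", self.version),
            ("circuit", self.circuit),
            ("inputs", self.inputs),
            ("seed", self.seed),
            ("config", self.config),
            ("timestamp", self.timestamp),
        ]
        return [f"# {k}: {v}" for k, v in pairs if v not in ("", None)]


def _write_tsv(df: pd.DataFrame, path: Path,
               manifest: Optional[RunManifest]) -> Path:
    with open(path, "w") as fh:
        if manifest is not None:
            fh.write("\n".join(manifest.comment_lines()) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def write_rule_log(log: Iterable[RuleApplication], path: str | Path,
                   manifest: Optional[RunManifest] = None) -> Path:
    rows = [
        {
            "step": a.step,
            "phase": a.phase,
            "rule": a.rule,
            "participants": ";".join(a.participants),
            "detail": a.detail,
            "delta_nt": a.delta_nt,
        }
        for a in log
    ]
    cols = ["step", "phase", "rule", "participants", "detail", "delta_nt"]
    return _write_tsv(pd.DataFrame(rows, columns=cols), Path(path), manifest)


def write_truth_table(report, path: str | Path,
                      manifest: Optional[RunManifest] = None) -> Path:
    return _write_tsv(report.to_dataframe(), Path(path), manifest)


def write_crosstalk(report, path: str | Path,
                    manifest: Optional[RunManifest] = None) -> Path:
    rows = [asdict(h) for h in report.hits]
    cols = ["strand_a", "strand_b", "pos_a", "pos_b", "length"]
    return _write_tsv(pd.DataFrame(rows, columns=cols), Path(path), manifest)
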