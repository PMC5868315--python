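"""Gate library: truth tables, mechanism assertions, negative controls."""

from dataclasses import replace

import pytest

from g4logic.circuit import INPUT_STATES
from g4logic.core import Domain, Role, Strand
from g4logic.enumeration import EnumerationConfig
from g4logic.gates import (
    UnknownCircuitError,
    available_circuits,
    get_circuit,
    run_gate,
    truth_table,
    verify_library,
)
from g4logic.readout import ReadoutConfig

from conftest import ALL_CIRCUITS, SYMMETRIC_CIRCUITS

DECLARED = {
    "XOR": (0, 1, 1, 0),
    "OR": (0, 1, 1, 1),
    "AND": (0, 0, 0, 1),
    "XNOR": (1, 0, 0, 1),
    "NAND": (1, 1, 1, 0),
    "NOR": (1, 0, 0, 0),
    "INHIBIT": (0, 1, 0, 0),
    "IMPLICATION": (1, 0, 1, 1),
    "XOR_AND": (0, 1, 1, 1),   # the combined circuit behaves as OR
    "XOR_NOR": (1, 1, 1, 0),   # the combined circuit behaves as NAND
}


@pytest.mark.parametrize("name", ALL_CIRCUITS)
def test_truth_tables_match_declared_functions(name):
    rep = truth_table(get_circuit(name))
    assert rep.observed_bits() == DECLARED[name]
    assert rep.passed


def test_library_lookup_and_rosters():
    assert set(available_circuits()) == set(ALL_CIRCUITS)
    assert {s.name for s in get_circuit("AND").strands} == {
        "DNA1", "DNA2", "DNA3",
    }
    assert len(get_circuit("XOR").strands) == 5
    assert len(get_circuit("OR").strands) == 5
    assert len(get_circuit("XOR_AND").strands) == 7
    roster = {s.name for s in get_circuit("XOR_NOR").strands}
    assert roster == {f"DNA{i}" for i in range(1, 9)}  # incl. template DNA1
    with pytest.raises(UnknownCircuitError) as err:
        get_circuit("FOO")
    assert "XOR" in str(err.value)  # error lists what is available


class TestMechanism:
    def test_xor_both_inputs_form_interinput_duplex_and_no_enzyme(self):
        res = run_gate(get_circuit("XOR"), (1, 1))
        first_react = next(a for a in res.log if a.phase == "react")
        assert first_react.rule == "R1"
        assert {p.split("#")[0] for p in first_react.participants} == {
            "input1", "input2",
        }
        duplexes = [
            c for c in res.state.complexes()
            if set(c.strand_names) == {"input1", "input2"}
        ]
        assert len(duplexes) == 1
        assert res.active_sites == []

    def test_or_both_inputs_two_active_dnazymes(self):
        res = run_gate(get_circuit("OR"), (1, 1))
        pairs = {
            (s.core_i.split("#")[0], s.core_ii.split("#")[0])
            for s in res.active_sites
        }
        assert pairs == {("DNA1", "DNA2"), ("DNA3", "DNA4")}

    def test_xor_and_enzyme_at_11_comes_from_dna5_dna6(self):
        res = run_gate(get_circuit("XOR_AND"), (1, 1))
        subunits = {
            s.core_i.split("#")[0] for s in res.active_sites
        } | {s.core_ii.split("#")[0] for s in res.active_sites}
        assert subunits == {"DNA5", "DNA6"}
        assert not subunits & {"DNA1", "DNA2", "DNA3", "DNA4"}

    def test_xor_nor_resting_state_keeps_template_enzyme_intact(self):
        res = run_gate(get_circuit("XOR_NOR"), (0, 0))
        assert len(res.active_sites) == 1
        site = res.active_sites[0]
        assert site.core_i.startswith("DNA6")
        assert site.core_ii.startswith("DNA7")
        assert all(s.startswith("DNA1") for s in site.scaffolds)
        assert not [a for a in res.log if a.rule == "R2"]

    def test_xor_nor_single_input_displaces_at_toehold_E(self):
        res = run_gate(get_circuit("XOR_NOR"), (1, 0))
        events = [a for a in res.log if a.rule == "R2"]
        assert len(events) == 1
        assert "toehold E" in events[0].detail
        assert events[0].participants[0].startswith("input1")
        assert events[0].participants[2].startswith("DNA6")

    def test_xor_nor_both_inputs_disassemble_both_template_subunits(self):
        res = run_gate(get_circuit("XOR_NOR"), (1, 1))
        toeholds = {
            a.detail.split("toehold ")[1] for a in res.log if a.rule == "R2"
        }
        assert toeholds == {"E", "H"}
        assert res.active_sites == []


class TestNegativeControls:
    @pytest.mark.parametrize("name", ALL_CIRCUITS)
    def test_without_magnesium_every_output_is_zero(self, name):
        cfg = EnumerationConfig(mg_present=False)
        bits = tuple(
            run_gate(get_circuit(name), s, enum_cfg=cfg).output_bit
            for s in INPUT_STATES
        )
        assert bits == (0, 0, 0, 0)

    @pytest.mark.parametrize("name", ALL_CIRCUITS)
    def test_without_substrate_every_output_is_zero(self, name):
        spec = get_circuit(name).without_substrate()
        bits = tuple(
            run_gate(spec, s).output_bit for s in INPUT_STATES
        )
        assert bits == (0, 0, 0, 0)

    def test_without_hemin_signal_stays_at_background(self):
        cfg = ReadoutConfig(hemin_present=False)
        res = run_gate(get_circuit("XOR"), (1, 0), readout_cfg=cfg)
        assert res.readout.a650 == cfg.a_background
        assert res.output_bit == 0

    def test_mutated_recognition_arm_breaks_and_gate(self):
        spec = get_circuit("AND")
        dna2 = spec.strand_by_name("DNA2")
        # point the recognition arm at a domain nothing carries
        broken_arm = Domain("zz", 12, starred=True,
                            role=Role.RECOGNITION_ARM)
        mutated = Strand("DNA2", (broken_arm, *dna2.domains[1:]))
        bad = spec.with_strand_replaced("DNA2", mutated)
        rep = truth_table(bad)
        assert not rep.passed
        assert rep.observed_bits()[3] == 0  # fails exactly at (1,1)
        assert rep.observed_bits()[:3] == (0, 0, 0)


def test_verify_library_all_pass_and_empty_selection_warns():
    summary = verify_library()
    assert summary.passed
    assert summary.n_pass == len(ALL_CIRCUITS)
    assert summary.summary_line() == "10/10 circuits match declared functions"
    with pytest.warns(UserWarning):
        empty = verify_library(names=())
    assert empty.passed and empty.reports == {}


@pytest.mark.parametrize("name", SYMMETRIC_CIRCUITS)
def test_input_order_invariance_for_symmetric_gates(name):
    """Swapping which strand is called input1/input2 must not change any
    endpoint of a symmetric gate."""
    spec = get_circuit(name)
    swapped = replace(spec, inputs=(spec.inputs[1], spec.inputs[0]))
    for (i1, i2) in INPUT_STATES:
        a = run_gate(spec, (i1, i2))
        b = run_gate(swapped, (i2, i1))
        assert a.output_bit == b.output_bit
        assert sorted(c.strand_names for c in a.state.complexes()) == sorted(
            c.strand_names for c in b.state.complexes()
        )


def test_runs_replay_byte_identically():
    for name in ("XOR", "XOR_NOR"):
        spec = get_circuit(name)
        a = run_gate(spec, (1, 1))
        b = run_gate(spec, (1, 1))
        assert a.log == b.log
        assert a.readout == b.readout
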