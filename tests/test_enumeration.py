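"""Rule engine: hybridization priority, displacement, detection, cleavage,
release, and global invariants on randomized circuits."""

import pytest

from g4logic.core import Domain, Role, SpecError, Strand
from g4logic.enumeration import (
    EnumerationConfig,
    SystemState,
    enumerate_to_fixpoint,
    hybridize_displace_fixpoint,
    rule_R1_hybridize,
    rule_R2_toehold_displace,
    _split_strand,
)
from g4logic.gates import get_circuit, run_gate, build_initial_state
from g4logic.seqtools import generate_random_circuit

from conftest import ALL_CIRCUITS


def _d(name, length=12, star=False, role=Role.GENERIC):
    return Domain(name, length, star, role)


class TestHybridization:
    def test_longest_duplex_wins_over_partial_binding(self):
        """Hand-derived endpoint: with a full complement and a one-domain
        binder both available, the full duplex forms and the short binder
        stays free."""
        x = Strand("X", (_d("m"), _d("n")))
        y = Strand("Y", (_d("n", star=True), _d("m", star=True)))
        z = Strand("Z", (_d("m", star=True),))
        state = SystemState()
        for s in (x, y, z):
            state.add_strand(s)
        enumerate_to_fixpoint(state)
        comps = {c.strand_names for c in state.complexes()}
        assert comps == {("X", "Y"), ("Z",)}
        first = state.log[0]
        assert first.rule == "R1" and first.delta_nt == 24

    def test_no_complementary_pair_yields_no_application(self):
        state = SystemState()
        state.add_strand(Strand("A", (_d("m"),)))
        state.add_strand(Strand("B", (_d("n"),)))
        assert rule_R1_hybridize(state) is None

    def test_r1_deltas_strictly_increase_total_paired_nt(self):
        spec = get_circuit("XOR_NOR")
        res = run_gate(spec, (1, 1))
        r1_deltas = [a.delta_nt for a in res.log if a.rule == "R1"]
        assert r1_deltas and all(d > 0 for d in r1_deltas)
        assert all(
            a.delta_nt > 0 for a in res.log if a.rule == "R2"
        )
        # displacement conserves paired nt, so the endpoint total is the sum
        # of the hybridization gains plus the self-folded hairpin stem
        stem_nt = spec.substrate.domains[0].length
        assert res.state.total_paired_nt() == sum(r1_deltas) + stem_nt

    def test_hairpin_self_folds_at_construction(self):
        sub = get_circuit("AND").substrate
        state = SystemState()
        iid = state.add_strand(sub)
        # stem: G4 segment paired with its clamp, loop free
        assert not state.is_free((iid, 0))
        assert state.partner[(iid, 0)] == (iid, 3)
        assert state.is_free((iid, 1)) and state.is_free((iid, 2))


class TestDisplacement:
    @staticmethod
    def _toy_state():
        """Target T = [toehold t | m], incumbent X = [m*] pre-annealed,
        invader V = [m*, t*] added afterwards."""
        t = Strand("T", (_d("t", 6, role=Role.TOEHOLD), _d("m")))
        x = Strand("X", (_d("m", star=True),))
        v = Strand("V", (_d("m", star=True), _d("t", 6, star=True,
                                                role=Role.TOEHOLD)))
        state = SystemState()
        it = state.add_strand(t)
        ix = state.add_strand(x)
        hybridize_displace_fixpoint(state, EnumerationConfig())
        iv = state.add_strand(v)
        return state, it, ix, iv

    def test_single_step_displacement_hand_enumerated(self):
        """Hand-derived product set: V takes both target domains, X ends
        fully unbound as its own complex."""
        state, it, ix, iv = self._toy_state()
        enumerate_to_fixpoint(state)
        assert state.partner[(it, 0)] == (iv, 1)
        assert state.partner[(it, 1)] == (iv, 0)
        assert state.is_free((ix, 0))
        comps = {c.strand_names for c in state.complexes()}
        assert comps == {("T", "V"), ("X",)}
        r2 = [a for a in state.log if a.rule == "R2"]
        assert len(r2) == 1
        assert r2[0].delta_nt == 6  # the anchoring toehold length
        assert "toehold t" in r2[0].detail

    def test_no_free_toehold_no_displacement(self):
        t = Strand("T", (_d("m"),))
        x = Strand("X", (_d("m", star=True),))
        v = Strand("V", (_d("m", star=True),))
        state = SystemState()
        state.add_strand(t)
        state.add_strand(x)
        hybridize_displace_fixpoint(state, EnumerationConfig())
        state.add_strand(v)
        assert rule_R1_hybridize(state) is None
        assert rule_R2_toehold_displace(state) is None

    def test_partial_takeover_is_rejected(self):
        """An invader too short to evict the incumbent completely must not
        fire (prevents ping-pong exchanges)."""
        t = Strand("T", (_d("t", 6, role=Role.TOEHOLD), _d("m"), _d("n")))
        x = Strand("X", (_d("n", star=True), _d("m", star=True)))
        v = Strand("V", (_d("m", star=True), _d("t", 6, star=True)))
        state = SystemState()
        it = state.add_strand(t)
        ix = state.add_strand(x)
        hybridize_displace_fixpoint(state, EnumerationConfig())
        iv = state.add_strand(v)
        enumerate_to_fixpoint(state)
        # V anchors at the toehold but cannot displace X's two-domain block
        assert state.partner[(it, 0)] == (iv, 1)
        assert state.partner[(it, 1)] == (ix, 1)
        assert not [a for a in state.log if a.rule == "R2"]


class TestDetectionCleavageRelease:
    def test_active_site_counts_across_and_or_states(self):
        and_spec = get_circuit("AND")
        assert len(run_gate(and_spec, (1, 1)).active_sites) == 1
        assert len(run_gate(and_spec, (1, 0)).active_sites) == 0
        assert len(run_gate(and_spec, (0, 1)).active_sites) == 0
        # one DNAzyme per input scaffold
        assert len(run_gate(get_circuit("OR"), (1, 1)).active_sites) == 2

    def test_cleavage_requires_magnesium(self):
        res = run_gate(
            get_circuit("AND"), (1, 1),
            enum_cfg=EnumerationConfig(mg_present=False),
        )
        assert len(res.active_sites) == 1  # assembly still happens
        assert res.state.released_g4 == 0
        assert res.output_bit == 0

    def test_no_active_site_no_cleavage(self):
        res = run_gate(get_circuit("AND"), (0, 0))
        assert res.state.cleaved_records == []
        assert res.state.released_g4 == 0

    def test_split_requires_ra_site(self):
        with pytest.raises(SpecError):
            _split_strand(Strand("s", (_d("a"), _d("b"))))

    @pytest.mark.parametrize("copies", [1, 2, 3, 4, 5])
    def test_release_is_linear_in_substrate_copies(self, copies):
        res = run_gate(get_circuit("AND"), (1, 1), substrate_count=copies)
        assert res.state.total_substrate == copies
        assert res.state.released_g4 == copies
        assert res.readout.fraction_released == 1.0

    def test_leak_adds_background_fraction(self):
        res = run_gate(
            get_circuit("AND"), (0, 0),
            enum_cfg=EnumerationConfig(leak=0.05),
        )
        assert res.readout.fraction_released == pytest.approx(0.05)
        assert res.output_bit == 0  # below the 0.082 crossing


class TestRandomCircuitInvariants:
    PATTERNS = ("input_assembled", "cooperative", "template_disassembly")

    def test_termination_conservation_determinism_100_seeds(self):
        """Every randomized circuit reaches a fixpoint under the step cap,
        conserves nucleotide content, and replays identically."""
        for seed in range(100):
            pattern = self.PATTERNS[seed % 3]
            spec = generate_random_circuit(pattern, seed)
            for input_state in ((0, 0), (1, 0), (0, 1), (1, 1)):
                state = build_initial_state(spec, input_state)
                before = state.nucleotide_census()
                enumerate_to_fixpoint(state)  # raises StepCapExceeded if not
                assert state.nucleotide_census() == before
                replay = build_initial_state(spec, input_state)
                enumerate_to_fixpoint(replay)
                assert replay.log == state.log

    @pytest.mark.parametrize("pattern,expected", [
        ("input_assembled", (0, 1, 1, 1)),
        ("cooperative", (0, 0, 0, 1)),
        ("template_disassembly", (1, 0, 0, 0)),
    ])
    def test_patterns_compute_their_boolean_functions(self, pattern, expected):
        from g4logic.gates import truth_table

        for seed in (0, 11, 23):
            spec = generate_random_circuit(pattern, seed)
            assert truth_table(spec).observed_bits() == expected

    def test_complex_invariants_hold_at_endpoints(self):
        for name in ALL_CIRCUITS:
            res = run_gate(get_circuit(name), (1, 1))
            for cx in res.state.complexes():
                cx.validate()
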