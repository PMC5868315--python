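"""Deterministic endpoint rule engine for DNAzyme logic circuits.

The engine evolves a mixture of strands to its endpoint species set with
five rules, mirroring how these gates operate in the test tube:

R1  hybridize      -- form the highest-scoring set of complementary domain
                      bonds between two strand instances ("longest total
                      duplex first"; this priority realizes preferred
                      inter-input hybridization without free energies).
R2  toehold displace -- an invader anchored next to a duplex migrates through
                      it and evicts the incumbent strand.
R3  detect         -- count catalytically active split DNAzymes: a core-I and
                      a core-II half juxtaposed by recognition arms bound at
                      adjacent scaffold positions (or at positions flanking
                      the junction bond of two cross-hybridized scaffolds).
R4  cleave         -- any active DNAzyme, with Mg2+ present, cleaves every
                      substrate copy at its embedded ribonucleotide
                      (catalytic turnover collapsed to all-or-none).
R5  release        -- each cleaved substrate whose caged G4 span survives
                      intact and unpaired on one fragment yields one active
                      G-quadruplex reporter.

Endpoint (thermodynamic-style) semantics, not kinetics: the platform reports
colors after a fixed incubation and no rate constants exist, so only the
final species set matters.  Every step is deterministic given the tie-break
ordering, which makes runs byte-for-byte reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .core import (
    Domain,
    End,
    PairingRun,
    Role,
    SpecError,
    SpeciesComplex,
    Strand,
    StrandInstance,
    _all_runs,
    _best_run_set,
    is_complementary,
    make_bond,
)


class TopologyError(RuntimeError):
    """A displacement was attempted across a malformed (non-contiguous)
    contested duplex."""


class StepCapExceeded(RuntimeError):
    """Internal guard: the rule loop did not reach a fixpoint within the
    configured application cap."""


@dataclass
class EnumerationConfig:
    """Knobs of the reaction engine.

    mg_present: Mg2+ cofactor flag; without it no cleavage occurs.
    step_cap:   hard bound on rule applications (termination guard).
    leak:       background cleaved fraction added to the readout (0 by
                default; the platform shows clean negative states).
    """

    mg_present: bool = True
    step_cap: int = 10_000
    leak: float = 0.0


@dataclass(frozen=True)
class RuleApplication:
    """One entry of the audit log."""

    step: int
    rule: str
    participants: tuple[str, ...]
    detail: str
    delta_nt: int
    phase: str = "react"


@dataclass(frozen=True)
class ActiveSite:
    """A catalytically competent split-DNAzyme assembly."""

    core_i: str   # "name#iid" of the subunit carrying core half I
    core_ii: str  # "name#iid" of the subunit carrying core half II
    scaffolds: tuple[str, ...]


def _tag(inst: StrandInstance) -> str:
    return f"{inst.name}#{inst.iid}"


class SystemState:
    """Flat mixture state: strand instances plus domain-level bonds.

    Complexes are connected components of the bond graph, computed on
    demand.  Strand content is conserved: cleavage fragments carry a
    ``parent`` pointer back to the instance they came from.
    """

    def __init__(self) -> None:
        self.instances: dict[int, StrandInstance] = {}
        self.partner: dict[End, End] = {}
        self._next_iid = 0
        self.total_substrate = 0
        self.cleaved_records: list[tuple[int, str, int]] = []
        self.active_sites: list[ActiveSite] = []
        self.released_g4 = 0
        self.log: list[RuleApplication] = []
        self._phase = "react"

    # -- construction ------------------------------------------------------

    def add_strand(self, strand: Strand, fold: bool = True) -> int:
        iid = self._next_iid
        self._next_iid += 1
        self.instances[iid] = StrandInstance(iid=iid, strand=strand)
        if strand.ra_site is not None:
            self.total_substrate += 1
        if fold:
            self._fold_hairpin(iid)
        return iid

    def _fold_hairpin(self, iid: int) -> None:
        """Bind self-complementary non-adjacent domain pairs (hairpin stems),
        as formed during annealing of a unimolecular structure."""
        doms = self.instances[iid].strand.domains
        n = len(doms)
        for i in range(n):
            for j in range(i + 2, n):
                if (
                    is_complementary(doms[i], doms[j])
                    and (iid, i) not in self.partner
                    and (iid, j) not in self.partner
                ):
                    self._bind((iid, i), (iid, j))

    # -- bond bookkeeping --------------------------------------------------

    def _bind(self, a: End, b: End) -> None:
        if a in self.partner or b in self.partner:
            raise SpecError(f"domain already bound: {a} / {b}")
        self.partner[a] = b
        self.partner[b] = a

    def _unbind(self, a: End) -> None:
        b = self.partner.pop(a)
        del self.partner[b]

    def is_free(self, end: End) -> bool:
        return end not in self.partner

    def bonds(self) -> set[tuple[End, End]]:
        return {make_bond(a, b) for a, b in self.partner.items()}

    def total_paired_nt(self) -> int:
        total = 0
        for a, b in self.partner.items():
            if a <= b:
                total += self.instances[a[0]].strand.domains[a[1]].length
        return total

    # -- views -------------------------------------------------------------

    def complexes(self) -> list[SpeciesComplex]:
        g = nx.Graph()
        g.add_nodes_from(self.instances)
        for (ia, _), (ib, _) in self.bonds():
            g.add_edge(ia, ib)
        out = []
        for comp in nx.connected_components(g):
            cx = SpeciesComplex(
                instances={i: self.instances[i] for i in comp},
                bonds={
                    bond
                    for bond in self.bonds()
                    if bond[0][0] in comp and bond[1][0] in comp
                },
            )
            out.append(cx)
        out.sort(key=lambda c: (c.strand_names, min(c.instances)))
        return out

    def nucleotide_census(self) -> dict[str, int]:
        """Total nt per original strand (fragments credited to the parent
        they were cut from); used by the conservation invariant."""
        census: dict[str, int] = {}
        for inst in self.instances.values():
            name = self._root_name(inst)
            census[name] = census.get(name, 0) + inst.strand.length
        return census

    def _root_name(self, inst: StrandInstance) -> str:
        return inst.strand.name.split(".", 1)[0] if inst.parent else inst.strand.name

    def _log(self, rule: str, participants: tuple[str, ...], detail: str,
             delta: int) -> RuleApplication:
        app = RuleApplication(
            step=len(self.log),
            rule=rule,
            participants=participants,
            detail=detail,
            delta_nt=delta,
            phase=self._phase,
        )
        self.log.append(app)
        return app


# ---------------------------------------------------------------------------
# R1: hybridization
# ---------------------------------------------------------------------------

def _r1_candidates(state: SystemState):
    """All pairwise hybridization candidates over free domains, with the
    deterministic ranking key (max paired nt first, then lexicographic)."""
    iids = sorted(state.instances)
    for x in range(len(iids)):
        for y in range(x + 1, len(iids)):
            ia, ib = iids[x], iids[y]
            sa = state.instances[ia].strand
            sb = state.instances[ib].strand
            free_a = [state.is_free((ia, k)) for k in range(len(sa.domains))]
            free_b = [state.is_free((ib, k)) for k in range(len(sb.domains))]
            runs = _all_runs(sa.domains, sb.domains, free_a, free_b)
            if not runs:
                continue
            chosen, total = _best_run_set(runs)
            if total <= 0:
                continue
            key = (
                -total,
                tuple(sorted((sa.name, sb.name))),
                (ia, ib),
                tuple(sorted((r.start_a, r.start_b) for r in chosen)),
            )
            yield key, (ia, ib, chosen, total)


def rule_R1_hybridize(state: SystemState) -> Optional[RuleApplication]:
    """Apply the single best hybridization candidate, if any.

    Among all pairs of strand instances, the candidate forming the most
    paired nucleotides wins (ties broken by sorted strand names, then
    instance ids).  Returns the log entry or ``None`` if no pair of free
    complementary domains exists.
    """
    best = min(_r1_candidates(state), default=None, key=lambda kv: kv[0])
    if best is None:
        return None
    ia, ib, runs, total = best[1]
    for r in runs:
        for t in range(r.n_domains):
            state._bind((ia, r.start_a + t), (ib, r.start_b - t))
    na = _tag(state.instances[ia])
    nb = _tag(state.instances[ib])
    labels = ",".join(
        state.instances[ia].strand.domains[r.start_a + t].label
        for r in runs
        for t in range(r.n_domains)
    )
    return state._log("R1", (na, nb), f"hybridize {labels}", total)


# ---------------------------------------------------------------------------
# R2: toehold-mediated strand displacement
# ---------------------------------------------------------------------------

def _r2_candidates(state: SystemState):
    """Displacement candidates: an anchored invader next to a contested
    duplex it can take over completely."""
    for (v, i), (t, j) in sorted(state.partner.items()):
        v_inst = state.instances[v]
        t_inst = state.instances[t]
        v_dom = v_inst.strand.domains
        t_dom = t_inst.strand.domains
        for d in (+1, -1):
            j2, i2 = j + d, i - d  # antiparallel geometry
            if not (0 <= j2 < len(t_dom) and 0 <= i2 < len(v_dom)):
                continue
            holder = state.partner.get((t, j2))
            if holder is None or holder[0] == v:
                continue
            x = holder[0]
            if x == t:
                continue  # hairpin stem of the target itself: not displaceable here
            if not state.is_free((v, i2)):
                continue
            if not is_complementary(v_dom[i2], t_dom[j2]):
                continue
            # walk the whole contested block held by incumbent x
            transfers: list[tuple[int, int]] = []  # (target idx, invader idx)
            jj, ii = j2, i2
            ok = True
            while True:
                transfers.append((jj, ii))
                jj2, ii2 = jj + d, ii - d
                nxt = state.partner.get((t, jj2)) if 0 <= jj2 < len(t_dom) else None
                if nxt is None or nxt[0] != x:
                    break
                if not (0 <= ii2 < len(v_dom)) or not state.is_free((v, ii2)):
                    ok = False
                    break
                if not is_complementary(v_dom[ii2], t_dom[jj2]):
                    ok = False
                    break
                jj, ii = jj2, ii2
            if not ok:
                continue  # invader cannot take the block completely
            # complete displacement only: incumbent must hold nothing else on t
            incumbent_on_t = {
                jt
                for (tt, jt), (xx, _) in
                ((k, vv) for k, vv in state.partner.items() if k[0] == t)
                if xx == x
            }
            if incumbent_on_t != {jt for jt, _ in transfers}:
                continue
            anchor_len = v_dom[i].length
            yield (
                (v_inst.name, v, t_inst.name, t, j, d),
                (v, t, x, i, transfers, anchor_len),
            )


def rule_R2_toehold_displace(state: SystemState) -> Optional[RuleApplication]:
    """Apply one complete toehold-mediated displacement, if any.

    The invader must already be anchored (rule R1 binds free toeholds, as
    the higher-priority rule) adjacent to a contiguous duplex held by an
    incumbent, and must be able to take over the incumbent's entire block;
    the logged delta is the anchoring domain length -- the net gain of the
    displacement transaction, which guarantees forward bias.
    """
    best = min(_r2_candidates(state), default=None, key=lambda kv: kv[0])
    if best is None:
        return None
    v, t, x, i_anchor, transfers, anchor_len = best[1]
    for jj, ii in transfers:
        state._unbind((t, jj))
        state._bind((v, ii), (t, jj))
    inv = _tag(state.instances[v])
    tgt = _tag(state.instances[t])
    inc = _tag(state.instances[x])
    toehold = state.instances[v].strand.domains[i_anchor]
    return state._log(
        "R2",
        (inv, tgt, inc),
        f"displace {inc} from {tgt} via toehold {toehold.name}",
        anchor_len,
    )


# ---------------------------------------------------------------------------
# R3: active split-DNAzyme detection
# ---------------------------------------------------------------------------

def _bound_arm_partners(state: SystemState, core_role: Role):
    """(instance, partner end) for every unpaired catalytic-core half of the
    given role whose flanking recognition arm is bound."""
    hits = []
    for iid in sorted(state.instances):
        doms = state.instances[iid].strand.domains
        for k, d in enumerate(doms):
            if d.role is not core_role:
                continue
            if not state.is_free((iid, k)):
                continue
            for adj in (k - 1, k + 1):
                if not (0 <= adj < len(doms)):
                    continue
                if doms[adj].role is not Role.RECOGNITION_ARM:
                    continue
                partner = state.partner.get((iid, adj))
                if partner is not None:
                    hits.append((iid, partner))
    return hits


def rule_R3_detect_active_dnazymes(state: SystemState) -> list[ActiveSite]:
    """Count catalytically active DNAzymes and record their locations.

    A split DNAzyme is active iff a core-I half on one strand and a core-II
    half on another are juxtaposed: each core's flanking recognition arm is
    bound, and the two scaffold positions are adjacent -- either consecutive
    domains of one scaffold strand, or positions flanking a junction bond
    between two scaffold strands that are cross-hybridized to each other
    (the cooperative two-input geometry).  A separated subunit can never
    assemble into an active enzyme.
    """
    sites: list[ActiveSite] = []
    seen: set[tuple[int, int]] = set()
    cores_i = _bound_arm_partners(state, Role.CORE_I)
    cores_ii = _bound_arm_partners(state, Role.CORE_II)
    for xi, (s_iid, i) in cores_i:
        for yi, (t_iid, j) in cores_ii:
            if xi == yi or (xi, yi) in seen:
                continue
            juxtaposed = False
            if s_iid == t_iid and abs(i - j) == 1:
                juxtaposed = True
            elif s_iid != t_iid:
                for (a, da), (b, db) in state.bonds():
                    pa, pb = (a, da), (b, db)
                    for (u, du), (w, dw) in ((pa, pb), (pb, pa)):
                        if (
                            u == s_iid
                            and w == t_iid
                            and abs(du - i) == 1
                            and abs(dw - j) == 1
                        ):
                            juxtaposed = True
                if xi in (s_iid, t_iid) or yi in (s_iid, t_iid):
                    juxtaposed = False  # a subunit cannot scaffold itself
            if juxtaposed:
                seen.add((xi, yi))
                scaffolds = tuple(
                    sorted(
                        {
                            _tag(state.instances[s_iid]),
                            _tag(state.instances[t_iid]),
                        }
                    )
                )
                sites.append(
                    ActiveSite(
                        core_i=_tag(state.instances[xi]),
                        core_ii=_tag(state.instances[yi]),
                        scaffolds=scaffolds,
                    )
                )
    sites.sort(key=lambda s: (s.core_i, s.core_ii))
    state.active_sites = sites
    state._log(
        "R3",
        tuple(f"{s.core_i}+{s.core_ii}" for s in sites) or ("none",),
        f"{len(sites)} active DNAzyme(s)",
        0,
    )
    return sites


# ---------------------------------------------------------------------------
# R4: substrate cleavage
# ---------------------------------------------------------------------------

def _split_strand(strand: Strand) -> tuple[Strand, Strand]:
    r = strand.ra_site
    if r is None:
        raise SpecError(f"strand {strand.name!r} has no rA site to cleave")

    def span_in(lo: int, hi: int, off: int) -> Optional[tuple[int, int]]:
        if strand.caged_g4 is None:
            return None
        a, b = strand.caged_g4
        if lo <= a and b < hi:
            return (a - off, b - off)
        return None

    seq = strand.sequence
    cut_nt = sum(d.length for d in strand.domains[:r])
    five = Strand(
        name=f"{strand.name}.5p",
        domains=strand.domains[:r],
        sequence=seq[:cut_nt] if seq else None,
        caged_g4=span_in(0, r, 0),
    )
    three = Strand(
        name=f"{strand.name}.3p",
        domains=strand.domains[r:],
        sequence=seq[cut_nt:] if seq else None,
        caged_g4=span_in(r, len(strand.domains), r),
    )
    return five, three


def rule_R4_cleave(state: SystemState,
                   cfg: EnumerationConfig) -> Optional[RuleApplication]:
    """Endpoint catalytic-turnover cleavage.

    If at least one active DNAzyme exists and Mg2+ is present, every
    substrate copy (strand carrying an rA site) is cleaved at the
    ribonucleotide: the strand splits into its 5' and 3' fragments, bonds
    move with their domains, and the now-bimolecular hairpin stem between
    the two fragments melts apart.  A single active enzyme suffices -- the
    platform treats any active DNAzyme as producing full signal.
    """
    if not state.active_sites or not cfg.mg_present:
        return None
    targets = [
        iid
        for iid in sorted(state.instances)
        if state.instances[iid].strand.ra_site is not None
    ]
    if not targets:
        return None
    cut_names = []
    for iid in targets:
        inst = state.instances[iid]
        five, three = _split_strand(inst.strand)
        r = inst.strand.ra_site
        f_iid = state._next_iid
        state._next_iid += 2
        t_iid = f_iid + 1
        state.instances[f_iid] = StrandInstance(f_iid, five, parent=(iid, 0))
        state.instances[t_iid] = StrandInstance(t_iid, three, parent=(iid, 1))
        def moved(end: End) -> End:
            ii, dd = end
            if ii != iid:
                return end
            return (f_iid, dd) if dd < r else (t_iid, dd - r)

        touched = {
            make_bond(a, b)
            for a, b in state.partner.items()
            if a[0] == iid or b[0] == iid
        }
        for a, b in touched:
            state._unbind(a)
            na, nb = moved(a), moved(b)
            # the stem joining the two fragments is now an unclamped
            # bimolecular duplex flanking a nick: it dissociates, releasing
            # the G4-bearing strand; all other bonds move with their domains
            if {na[0], nb[0]} != {f_iid, t_iid}:
                state._bind(na, nb)
        del state.instances[iid]
        state.cleaved_records.append((iid, inst.strand.name, r))
        cut_names.append(_tag(inst))
    return state._log(
        "R4",
        tuple(cut_names),
        f"cleave {len(cut_names)} substrate(s) at rA",
        0,
    )


# ---------------------------------------------------------------------------
# R5: G-quadruplex release
# ---------------------------------------------------------------------------

def rule_R5_release_g4(state: SystemState) -> int:
    """Count released, active G-quadruplex reporters.

    A cleavage fragment contributes one active G4 iff it carries the intact
    caged-G4 span with every span domain unpaired (free to fold into the
    peroxidase-mimicking quadruplex).  Intact hairpins contribute zero: the
    stem clamp keeps the G4 caged.
    """
    released = 0
    for iid in sorted(state.instances):
        inst = state.instances[iid]
        if inst.parent is None or inst.strand.caged_g4 is None:
            continue
        lo, hi = inst.strand.caged_g4
        if all(state.is_free((iid, k)) for k in range(lo, hi + 1)):
            released += 1
    state.released_g4 = released
    state._log("R5", (), f"release {released} G-quadruplex(es)", 0)
    return released


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def hybridize_displace_fixpoint(state: SystemState,
                                cfg: EnumerationConfig) -> None:
    """Apply R1 (priority) and R2 until neither applies.

    Terminates: every R1 application strictly increases total paired nt
    (bounded by the total nucleotide content) and R2 applies only complete,
    anchored displacements; ``step_cap`` guards the loop regardless.
    """
    steps = 0
    while True:
        app = rule_R1_hybridize(state) or rule_R2_toehold_displace(state)
        if app is None:
            return
        steps += 1
        if steps > cfg.step_cap:
            raise StepCapExceeded(
                f"no fixpoint within {cfg.step_cap} rule applications"
            )


def enumerate_to_fixpoint(
    state: SystemState, cfg: EnumerationConfig | None = None
) -> SystemState:
    """Run the full rule schedule: R1/R2 to fixpoint, then R3 -> R4 -> R5.

    Fully deterministic given the tie-break ordering; the ordered rule log
    accumulates on ``state.log``.
    """
    cfg = cfg or EnumerationConfig()
    hybridize_displace_fixpoint(state, cfg)
    rule_R3_detect_active_dnazymes(state)
    rule_R4_cleave(state, cfg)
    rule_R5_release_g4(state)
    return state
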