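"""Programmatic construction of worked examples and randomized timelines.

This module is the package's entire data supply: canonical multi-phase
process documents (human childbirth; a run of uterine contractions whose
context states carry the oxytocin requirement; a primary-tooth-eruption
developmental timeline), anomaly injectors that perturb a document by
exact instant shifting, and a seeded generator of random multi-phase
processes with ground-truth anomaly lists for recovery testing.

Injection works purely arithmetically: inserting ``length`` time units at
a pivot boundary shifts every later instant by exactly that amount, so
all boundary coincidences — on which the continuation semantics rests —
are preserved mechanically, and the injected document revalidates without
re-solving any constraints.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Optional, Sequence, Union

from .errors import InjectionError, StructuralError
from .model import (
    AnomalyFinding,
    Continuant,
    ContinuantType,
    Continuation,
    ContinuationSignature,
    ContinuationType,
    Dependency,
    Document,
    EventInstance,
    Participation,
    StateAtom,
    StateOfAffairs,
    StateType,
    proper_subevents,
)
from .semantics import continuation_set
from .temporal import Interval, TemporalExtent, as_instant, InstantLike

#: Default oxytocin atom: part of every contraction context state.
OXYTOCIN_SUFFICIENT = StateAtom("maternal_blood", "oxytocin_concentration",
                                "sufficient")


# ---------------------------------------------------------------------------
# shared construction helpers
# ---------------------------------------------------------------------------

def _auto_deps(proc: EventInstance, life: TemporalExtent) -> frozenset[Dependency]:
    """Dependency set derived from the process's participant records: the
    continuation depends on every participant whose participation window
    shares an instant with its life-time."""
    return frozenset(
        Dependency(p.participant, p.generic) for p in proc.participants
        if any(ep.intersects(p.interval) for ep in life.episodes))


@dataclass(frozen=True)
class _Phase:
    id: str
    duration: Fraction
    initial: str
    final: str
    rest: bool = False


def _linear_chain(doc: Document, proc: EventInstance, start: Fraction,
                  phases: Sequence[_Phase], pre_state: str,
                  onset_ctype: str, boundary_ctypes: Sequence[str]) -> None:
    """Attach a chain of directly succeeding phases to ``proc``.

    Creates the phase events, an instantaneous onset boundary nested in the
    first phase (so that the onset continuation has a completed subevent),
    and the transition continuations.  A phase flagged ``rest`` (an episode
    of no change: initial state equals final state) is covered by a single
    rest continuation spanning it, with canonical duration equal to the
    phase length, instead of two instantaneous boundary continuations.
    """
    if not phases:
        raise InjectionError("a process chain needs at least one phase")
    for ph in phases:
        if ph.duration <= 0:
            raise InjectionError(f"phase {ph.id!r}: non-positive duration")
    if phases[0].rest or phases[-1].rest:
        raise InjectionError("a rest phase cannot open or close the chain")
    for a, b in zip(phases, phases[1:]):
        if a.rest and b.rest:
            raise InjectionError("adjacent rest phases are not supported")

    t = start
    bounds: list[Fraction] = [t]
    for ph in phases:
        doc.add(EventInstance(
            id=ph.id, extent=TemporalExtent.single(t, t + ph.duration),
            parent=proc.id, initial_state=ph.initial, final_state=ph.final))
        t += ph.duration
        bounds.append(t)

    onset_id = f"{proc.id}.onset_boundary"
    doc.add(EventInstance(
        id=onset_id, extent=TemporalExtent.single(start, start),
        parent=phases[0].id, initial_state=pre_state, final_state=phases[0].initial))
    life = TemporalExtent.single(start, start)
    doc.add(Continuation(
        id=f"{proc.id}.k_onset", life_time=life, context_state=phases[0].initial,
        completed_subevent=onset_id, succeeding_subevent=phases[0].id,
        ctype=onset_ctype, dependencies=_auto_deps(proc, life)))

    i = 0
    while i < len(phases) - 1:
        here, nxt = phases[i], phases[i + 1]
        ctype = boundary_ctypes[i]
        if nxt.rest:
            # one rest continuation spans the latency-like phase
            life = TemporalExtent.single(bounds[i + 1], bounds[i + 2])
            doc.add(Continuation(
                id=f"{proc.id}.k{i + 1}", life_time=life,
                context_state=here.final, completed_subevent=here.id,
                succeeding_subevent=phases[i + 2].id, ctype=ctype,
                dependencies=_auto_deps(proc, life),
                canonical_duration=nxt.duration))
            i += 2
        else:
            life = TemporalExtent.single(bounds[i + 1], bounds[i + 1])
            doc.add(Continuation(
                id=f"{proc.id}.k{i + 1}", life_time=life,
                context_state=here.final, completed_subevent=here.id,
                succeeding_subevent=nxt.id, ctype=ctype,
                dependencies=_auto_deps(proc, life)))
            i += 1


def signature_from_document(doc: Document, event: str, sig_id: str
                            ) -> ContinuationSignature:
    """Read the continuation signature off a canonical instance document.

    Continuation types are ordered by first appearance of their instances
    in the event's continuation set (ties broken by subevent nesting depth
    of the completed subevent, then lexically); the final-state type's
    templates are the exact atoms of the event's final state.
    """
    e = doc.event(event)
    if e.final_state is None:
        raise StructuralError(f"event {event!r} has no final state")
    ks = continuation_set(doc, e)
    keys: dict[str, tuple] = {}
    for kid in sorted(ks.members):
        k = doc.continuation(kid)
        key = (k.life_time.start, doc.depth(k.completed_subevent), k.ctype)
        if k.ctype not in keys or key < keys[k.ctype]:
            keys[k.ctype] = key
    ordered = sorted(keys, key=lambda t: keys[t])
    registry = {t: doc.continuation_types.get(t, ContinuationType(t))
                for t in ordered}
    final_type = StateType(id=f"{sig_id}.final",
                           templates=doc.state(e.final_state).atoms)
    return ContinuationSignature(id=sig_id, ordered_types=tuple(ordered),
                                 final_state_type=final_type,
                                 type_registry=registry)


# ---------------------------------------------------------------------------
# childbirth
# ---------------------------------------------------------------------------

def build_childbirth(phase_durations: Sequence[InstantLike] = (5, 3, 1),
                     contractions: int = 0,
                     contraction_durations: Optional[Sequence[InstantLike]] = None,
                     ) -> tuple[Document, ContinuationSignature]:
    """The canonical childbirth document and its signature.

    Three phases in direct succession — dilation, fetal expulsion and
    placental expulsion — with mother and child participating throughout
    and the placenta in the third phase.  The dilation-complete context
    state bundles complete cervical dilation with the fetal head engaged
    below the ischial spines; the final state locates both child and
    placenta outside the maternal body.

    With ``contractions > 0`` a run of uterine contractions is nested
    strictly inside the dilation phase, so that the continuation set also
    contains the contraction-level continuations and subprocess/
    superprocess level sensitivity can be exercised.
    """
    d1, d2, d3 = (as_instant(d) for d in phase_durations)
    if min(d1, d2, d3) <= 0:
        raise InjectionError("phase durations must be positive")
    T = d1 + d2 + d3
    doc = Document(unit="hour")
    for cid, label in (("mother", "the mother"), ("child", "the child"),
                       ("placenta", "the placenta"), ("cervix", "the cervix")):
        doc.add(Continuant(id=cid, label=label))

    def st(sid: str, *atoms: tuple) -> None:
        doc.add(StateOfAffairs(id=sid, atoms=frozenset(
            StateAtom(*a) for a in atoms)))

    st("s_prelabour", ("mother", "labour", "not_started"))
    st("s_labour_onset", ("cervix", "dilation", "beginning"),
       ("child", "location", "uterus"))
    st("s_dilation_complete", ("cervix", "dilation", "complete"),
       ("child", "station", "below_ischial_spines"),
       ("child", "location", "uterus"))
    st("s_fetus_delivered", ("child", "location", "outside_maternal_body"),
       ("placenta", "location", "uterus"))
    st("s_birth_complete", ("child", "location", "outside_maternal_body"),
       ("placenta", "location", "outside_maternal_body"))

    for tid, label in (("cb.onset", "childbirth onset"),
                       ("cb.dilation-complete", "cervix completely dilated"),
                       ("cb.fetus-delivered", "fetus delivered")):
        doc.add(ContinuationType(id=tid, label=label))

    birth = EventInstance(
        id="childbirth", extent=TemporalExtent.single(0, T),
        participants=(
            Participation("mother", Interval(Fraction(0), T)),
            Participation("child", Interval(Fraction(0), T)),
            Participation("placenta", Interval(d1 + d2, T)),
        ),
        initial_state="s_prelabour", final_state="s_birth_complete")
    doc.add(birth)
    _linear_chain(
        doc, birth, Fraction(0),
        phases=[
            _Phase("dilation", d1, "s_labour_onset", "s_dilation_complete"),
            _Phase("fetal_expulsion", d2, "s_dilation_complete",
                   "s_fetus_delivered"),
            _Phase("placental_expulsion", d3, "s_fetus_delivered",
                   "s_birth_complete"),
        ],
        pre_state="s_prelabour", onset_ctype="cb.onset",
        boundary_ctypes=["cb.dilation-complete", "cb.fetus-delivered"])

    if contractions:
        if contraction_durations is None:
            period = d1 / (2 * contractions)
            contraction_durations = (period / 4, period / 4, period / 2)
        _contraction_run(doc, parent="dilation", origin=d1 / 4,
                         n=contractions, phase_durations=contraction_durations,
                         oxytocin_atom=OXYTOCIN_SUFFICIENT, prefix="ctr")

    doc.validate_or_raise()
    sig = signature_from_document(doc, "childbirth", "sig.childbirth")
    return doc, sig


def build_truncated_childbirth(phase_durations: Sequence[InstantLike] = (5, 3),
                               ) -> tuple[Document, ContinuationSignature]:
    """A childbirth token missing the placental-expulsion phase, paired
    with the *full* childbirth signature.

    The truncation removes the fetus-delivered continuation (its succeeding
    subevent no longer exists), so the document cannot instantiate the full
    signature — aborted or incomplete process parts fall outside what
    continuation signatures can subsume.
    """
    d1, d2 = (as_instant(d) for d in phase_durations)
    full_doc, sig = build_childbirth((d1, d2, 1))
    doc = Document(unit="hour")
    for c in full_doc.continuants.values():
        doc.add(c)
    for s in full_doc.states.values():
        doc.add(s)
    for ct in full_doc.continuation_types.values():
        doc.add(ct)
    T = d1 + d2
    birth = EventInstance(
        id="childbirth", extent=TemporalExtent.single(0, T),
        participants=(Participation("mother", Interval(Fraction(0), T)),
                      Participation("child", Interval(Fraction(0), T))),
        initial_state="s_prelabour", final_state="s_fetus_delivered")
    doc.add(birth)
    _linear_chain(
        doc, birth, Fraction(0),
        phases=[
            _Phase("dilation", d1, "s_labour_onset", "s_dilation_complete"),
            _Phase("fetal_expulsion", d2, "s_dilation_complete",
                   "s_fetus_delivered"),
        ],
        pre_state="s_prelabour", onset_ctype="cb.onset",
        boundary_ctypes=["cb.dilation-complete"])
    doc.validate_or_raise()
    return doc, sig


# ---------------------------------------------------------------------------
# uterine contractions
# ---------------------------------------------------------------------------

def _contraction_run(doc: Document, parent: Optional[str], origin: Fraction,
                     n: int, phase_durations: Sequence[InstantLike],
                     oxytocin_atom: StateAtom, prefix: str = "ctr",
                     rest_grid: Optional[InstantLike] = None) -> str:
    pc, pr, pl = (as_instant(d) for d in phase_durations)
    if min(pc, pr, pl) <= 0:
        raise InjectionError("phase durations must be positive")
    if n < 1:
        raise InjectionError("need at least one contraction")
    period = pc + pr + pl
    T = origin + n * period

    for cid, label in (("mother", "the mother"), ("uterus", "the uterus"),
                       (oxytocin_atom.bearer, "oxytocin-bearing medium")):
        if cid not in doc.continuants:
            doc.add(Continuant(id=cid, label=label))

    s_pre = f"{prefix}.s_prelabour"
    s_rest = f"{prefix}.s_resting"
    s_cont = f"{prefix}.s_contracted"
    s_done = f"{prefix}.s_ceased"
    if s_pre not in doc.states:
        doc.add(StateOfAffairs(id=s_pre, atoms=frozenset(
            {StateAtom("uterus", "labour_contractions", "not_started")})))
        doc.add(StateOfAffairs(id=s_rest, atoms=frozenset(
            {StateAtom("uterus", "tone", "relaxed"), oxytocin_atom})))
        doc.add(StateOfAffairs(id=s_cont, atoms=frozenset(
            {StateAtom("uterus", "tone", "contracted"), oxytocin_atom})))
        doc.add(StateOfAffairs(id=s_done, atoms=frozenset(
            {StateAtom("uterus", "contraction_pattern", "ceased")})))
    for tid, label in ((f"{prefix}.onset", "contraction run onset"),
                       (f"{prefix}.peak", "contraction peak reached"),
                       (f"{prefix}.rest", "inter-contraction rest")):
        if tid not in doc.continuation_types:
            doc.add(ContinuationType(id=tid, label=label))

    run_id = f"{prefix}.run"
    run = EventInstance(
        id=run_id, extent=TemporalExtent.single(origin, T), parent=parent,
        participants=(Participation("mother", Interval(origin, T)),
                      Participation("uterus", Interval(origin, T))),
        initial_state=s_pre, final_state=s_done,
        made_of_process="uterine contracting")
    doc.add(run)
    doc.add(EventInstance(
        id=f"{run_id}.onset_boundary",
        extent=TemporalExtent.single(origin, origin), parent=run_id,
        initial_state=s_pre, final_state=s_rest))
    doc.add(EventInstance(
        id=f"{run_id}.end_boundary", extent=TemporalExtent.single(T, T),
        parent=run_id, initial_state=s_rest, final_state=s_done))

    def cphase(i: int) -> str:
        return f"{run_id}.c{i}.contracting"

    for i in range(1, n + 1):
        o = origin + (i - 1) * period
        doc.add(EventInstance(
            id=f"{run_id}.c{i}", extent=TemporalExtent.single(o, o + period),
            parent=run_id, initial_state=s_rest, final_state=s_rest))
        doc.add(EventInstance(
            id=cphase(i), extent=TemporalExtent.single(o, o + pc),
            parent=f"{run_id}.c{i}", initial_state=s_rest, final_state=s_cont))
        doc.add(EventInstance(
            id=f"{run_id}.c{i}.relaxing",
            extent=TemporalExtent.single(o + pc, o + pc + pr),
            parent=f"{run_id}.c{i}", initial_state=s_cont, final_state=s_rest))
        doc.add(EventInstance(
            id=f"{run_id}.c{i}.latency",
            extent=TemporalExtent.single(o + pc + pr, o + period),
            parent=f"{run_id}.c{i}", initial_state=s_rest, final_state=s_rest))

    life = TemporalExtent.single(origin, origin)
    doc.add(Continuation(
        id=f"{run_id}.k_onset", life_time=life, context_state=s_rest,
        completed_subevent=f"{run_id}.onset_boundary",
        succeeding_subevent=f"{run_id}.c1", ctype=f"{prefix}.onset",
        dependencies=_auto_deps(run, life)))
    for i in range(1, n + 1):
        o = origin + (i - 1) * period
        life = TemporalExtent.single(o + pc, o + pc)
        doc.add(Continuation(
            id=f"{run_id}.c{i}.k_peak", life_time=life, context_state=s_cont,
            completed_subevent=cphase(i),
            succeeding_subevent=f"{run_id}.c{i}.relaxing",
            ctype=f"{prefix}.peak", dependencies=_auto_deps(run, life)))
        succ = f"{run_id}.c{i + 1}" if i < n else f"{run_id}.end_boundary"
        if rest_grid is None:
            life = TemporalExtent.single(o + pc + pr, o + period)
            doc.add(Continuation(
                id=f"{run_id}.c{i}.k_rest", life_time=life,
                context_state=s_rest,
                completed_subevent=f"{run_id}.c{i}.relaxing",
                succeeding_subevent=succ, ctype=f"{prefix}.rest",
                dependencies=_auto_deps(run, life), canonical_duration=pl))
        else:
            _rest_grid_cells(doc, run, run_id, i, o + pc + pr, pl,
                             as_instant(rest_grid), s_rest, succ, prefix)
    return run_id


def _rest_grid_cells(doc: Document, run: EventInstance, run_id: str, i: int,
                     lat_start: Fraction, pl: Fraction, delta: Fraction,
                     s_rest: str, succ: str, prefix: str) -> None:
    """Expand a latency phase into a δ-grid of minimal rest periods, each
    pair of neighbours bridged by an instantaneous rest continuation — the
    stress-testing expansion of the single spanning rest continuation."""
    if delta <= 0 or (pl / delta).denominator != 1:
        raise InjectionError(
            f"rest grid step {delta} must positively divide the latency {pl}")
    m = int(pl / delta)
    lat_id = f"{run_id}.c{i}.latency"
    cells = []
    for q in range(1, m + 1):
        cid = f"{lat_id}.cell{q}"
        doc.add(EventInstance(
            id=cid, extent=TemporalExtent.single(
                lat_start + (q - 1) * delta, lat_start + q * delta),
            parent=lat_id, initial_state=s_rest, final_state=s_rest))
        cells.append(cid)
    hops = ([f"{run_id}.c{i}.relaxing"] + cells, cells + [succ])
    for q, (completed, succeeding) in enumerate(zip(*hops)):
        t = lat_start + q * delta
        life = TemporalExtent.single(t, t)
        doc.add(Continuation(
            id=f"{lat_id}.k_grid{q}", life_time=life, context_state=s_rest,
            completed_subevent=completed, succeeding_subevent=succeeding,
            ctype=f"{prefix}.rest", dependencies=_auto_deps(run, life)))


def build_contraction_run(n: int = 3,
                          phase_durations: Sequence[InstantLike] = (1, 1, 2),
                          oxytocin_atom: StateAtom = OXYTOCIN_SUFFICIENT,
                          rest_grid: Optional[InstantLike] = None,
                          ) -> tuple[Document, ContinuationSignature]:
    """A run of ``n`` uterine contractions and its signature.

    Every contraction consists of a contraction phase, a relaxation phase
    and a latency phase; the latency, being an episode of rest rather than
    change, is covered by a rest continuation whose canonical duration is
    the latency length (``rest_grid`` expands it to a grid of minimal rest
    periods instead).  All context states include the oxytocin atom: a
    sufficient oxytocin concentration is a prerequisite of continuing, so
    an oxytocin drop extinguishes the continuation and the resulting gap
    counts as an interruption once an oxytocin-restoring event fills it.
    """
    doc = Document(unit="minute")
    run_id = _contraction_run(doc, parent=None, origin=Fraction(0), n=n,
                              phase_durations=phase_durations,
                              oxytocin_atom=oxytocin_atom,
                              rest_grid=rest_grid)
    doc.validate_or_raise()
    sig = signature_from_document(doc, run_id, "sig.contraction_run")
    return doc, sig


# ---------------------------------------------------------------------------
# tooth eruption toy timeline
# ---------------------------------------------------------------------------

def build_tooth_eruption(phase_durations: Sequence[InstantLike] = (30, 4, 8),
                         ) -> tuple[Document, ContinuationSignature]:
    """A developmental timeline with a primary-tooth-eruption subprocess.

    Jaw maturation, eruption and settling into occlusion in direct
    succession: injecting a delay after the maturation phase and mapping
    the finding to phenotype terms annotates the eruption subprocess as
    delayed — the delayed-eruption-of-primary-teeth pattern.
    """
    d1, d2, d3 = (as_instant(d) for d in phase_durations)
    if min(d1, d2, d3) <= 0:
        raise InjectionError("phase durations must be positive")
    T = d1 + d2 + d3
    doc = Document(unit="month")
    for cid in ("infant", "jaw", "tooth"):
        doc.add(Continuant(id=cid, label=cid))
    doc.add(StateOfAffairs(id="s_neonatal", atoms=frozenset(
        {StateAtom("infant", "dentition", "none")})))
    doc.add(StateOfAffairs(id="s_growth_begun", atoms=frozenset(
        {StateAtom("jaw", "growth", "ongoing"),
         StateAtom("tooth", "position", "in_alveolus")})))
    doc.add(StateOfAffairs(id="s_eruption_due", atoms=frozenset(
        {StateAtom("jaw", "development", "ready"),
         StateAtom("tooth", "position", "in_alveolus")})))
    doc.add(StateOfAffairs(id="s_erupted", atoms=frozenset(
        {StateAtom("tooth", "position", "erupted")})))
    doc.add(StateOfAffairs(id="s_occlusion", atoms=frozenset(
        {StateAtom("tooth", "position", "in_occlusion")})))
    for tid in ("te.onset", "te.eruption-due", "te.erupted"):
        doc.add(ContinuationType(id=tid))
    dev = EventInstance(
        id="dentition_development", extent=TemporalExtent.single(0, T),
        participants=(Participation("infant", Interval(Fraction(0), T)),
                      Participation("jaw", Interval(Fraction(0), T)),
                      Participation("tooth", Interval(Fraction(0), T))),
        initial_state="s_neonatal", final_state="s_occlusion")
    doc.add(dev)
    _linear_chain(
        doc, dev, Fraction(0),
        phases=[
            _Phase("jaw_maturation", d1, "s_growth_begun", "s_eruption_due"),
            _Phase("tooth_eruption", d2, "s_eruption_due", "s_erupted"),
            _Phase("occlusal_settling", d3, "s_erupted", "s_occlusion"),
        ],
        pre_state="s_neonatal", onset_ctype="te.onset",
        boundary_ctypes=["te.eruption-due", "te.erupted"])
    doc.validate_or_raise()
    sig = signature_from_document(doc, "dentition_development", "sig.dentition")
    return doc, sig


# ---------------------------------------------------------------------------
# anomaly injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterrupterSpec:
    """Blueprint for the foreign event inserted into an interruption gap.

    ``final_atoms`` default to the flanking continuation's context state —
    the interrupter *restores* the prerequisites of continuing.  Supplying
    different atoms (e.g. with the oxytocin atom removed) produces a
    negative control whose gap stays unconfirmed.
    """

    id: str
    label: str = ""
    initial_atoms: frozenset[StateAtom] = frozenset()
    final_atoms: Optional[frozenset[StateAtom]] = None


def _shift_interval(iv: Interval, pivot: Fraction, L: Fraction) -> Interval:
    """Per-endpoint rule for records not tied to the pivot: instants after
    the pivot move; an interval starting exactly at the pivot moves iff it
    extends beyond it (it belongs to the successor side)."""
    a = iv.start + L if (iv.start > pivot or
                         (iv.start == pivot and iv.end > pivot)) else iv.start
    b = iv.end + L if iv.end > pivot else iv.end
    return Interval(a, b)


def _flex_interval(iv: Interval, pivot: Fraction, L: Fraction) -> Interval:
    """Rule for ancestors of the successor side: intervals wholly at or
    after the pivot shift; intervals reaching the pivot stretch to absorb
    the inserted time."""
    if iv.start >= pivot:
        return iv.shift(L)
    if iv.end < pivot:
        return iv
    return Interval(iv.start, iv.end + L)


def _retime(doc: Document, pivot: Fraction, L: Fraction, k: Continuation,
            successor_root: str, split_event: Optional[str] = None) -> Document:
    """Insert ``L`` units of time at ``pivot``.

    The subtree under ``successor_root`` shifts wholly; its proper
    ancestors absorb the inserted time (they remain in effect), except that
    ``split_event`` — the event being interrupted — gets a gap instead of
    stretching.  The pivot continuation ``k`` either extends its life-time
    across the insertion (delay) or splits into flanking episodes around it
    (interruption, when ``split_event`` is given).
    """
    new = doc.clone()
    sub_ids = {successor_root} | {
        ev.id for ev in proper_subevents(doc, successor_root)}
    anc_ids = set(doc.ancestors(successor_root))
    if split_event is not None and split_event not in anc_ids:
        raise InjectionError(
            f"{split_event!r} is not an ancestor of the succeeding subevent")
    interrupting = split_event is not None

    for ev in doc.events.values():
        if ev.id in sub_ids:
            extent = ev.extent.shift(L)
            parts = tuple(replace(p, interval=p.interval.shift(L))
                          for p in ev.participants)
        elif ev.id == split_event:
            eps: list[Interval] = []
            for e in ev.extent.episodes:
                if e.end < pivot:
                    eps.append(e)
                elif e.start > pivot:
                    eps.append(e.shift(L))
                else:
                    eps.append(Interval(e.start, pivot))
                    eps.append(Interval(pivot + L, e.end + L))
            extent = TemporalExtent(tuple(eps))
            parts = tuple(replace(p, interval=_flex_interval(p.interval, pivot, L))
                          for p in ev.participants)
        elif ev.id in anc_ids:
            extent = TemporalExtent(tuple(
                _flex_interval(e, pivot, L) for e in ev.extent.episodes))
            parts = tuple(replace(p, interval=_flex_interval(p.interval, pivot, L))
                          for p in ev.participants)
        else:
            extent = TemporalExtent(tuple(
                _shift_interval(e, pivot, L) for e in ev.extent.episodes))
            parts = tuple(replace(p, interval=_shift_interval(p.interval, pivot, L))
                          for p in ev.participants)
        new.replace_event(replace(ev, extent=extent, participants=parts))

    for cont in doc.continuations.values():
        if cont.id == k.id:
            eps = []
            for e in cont.life_time.episodes:
                if interrupting:
                    if e.end < pivot:
                        eps.append(e)
                    elif e.start > pivot:
                        eps.append(e.shift(L))
                    else:
                        eps.append(Interval(e.start, pivot))
                        eps.append(Interval(pivot + L, e.end + L))
                else:
                    if e.end == pivot:
                        eps.append(Interval(e.start, pivot + L))
                    elif e.start > pivot:
                        eps.append(e.shift(L))
                    else:
                        eps.append(e)
            life = TemporalExtent(tuple(eps))
        else:
            life = TemporalExtent(tuple(
                _shift_interval(e, pivot, L) for e in cont.life_time.episodes))
        new.replace_continuation(replace(cont, life_time=life))
    return new


def _delay_target(doc: Document, after_subevent: str) -> tuple[Continuation, Fraction]:
    """Resolve the continuation evidencing a delay injected after a
    subevent, and the pivot instant (the right boundary of that
    continuation's life-time)."""
    sub = doc.event(after_subevent)
    boundary = sub.extent.end
    k = next((c for c in sorted(doc.continuations.values(), key=lambda c: c.id)
              if c.completed_subevent == after_subevent), None)
    if k is None:
        k = next((c for c in sorted(doc.continuations.values(),
                                    key=lambda c: c.id)
                  if any(ep.end == boundary for ep in c.life_time.episodes)),
                 None)
    if k is None:
        raise InjectionError(
            f"cannot delay after {after_subevent!r}: no succeeding "
            f"continuation (event-final boundary)")
    return k, k.life_time.end


def inject_delay(doc: Document, after_subevent: str,
                 length: InstantLike) -> Document:
    """Insert a delay of ``length`` after a subevent.

    The continuation bridging the boundary keeps existing for ``length``
    extra units (its life-time episode extends), everything later shifts,
    and every enclosing event stretches to absorb the inserted time —
    delays are parts of the processes they delay.  The result revalidates.
    """
    L = as_instant(length)
    if L < 0:
        raise InjectionError("delay length must be non-negative")
    if L == 0:
        return doc.clone()
    k, pivot = _delay_target(doc, after_subevent)
    succ_tree = {ev.id for ev in proper_subevents(doc, k.succeeding_subevent)}
    if k.completed_subevent in succ_tree or \
            k.completed_subevent == k.succeeding_subevent:
        raise InjectionError(
            "cannot delay at a process onset: the completed boundary is "
            "nested inside the succeeding subevent")
    new = _retime(doc, pivot, L, k, k.succeeding_subevent)
    new.validate_or_raise()
    return new


def inject_interruption(doc: Document, at_subevent_boundary: str,
                        length: InstantLike,
                        interrupter: Optional[InterrupterSpec] = None,
                        ) -> Document:
    """Open an interruption gap of ``length`` at a subevent's right
    boundary.

    The parent of ``at_subevent_boundary`` is the interrupted event: its
    extent becomes scattered (the gap is excluded — interruptions do not
    contribute to the duration), the continuation flanking the boundary
    splits its life-time into episodes around the gap while remaining one
    and the same record, and events above the interrupted one stretch (the
    superprocess is still in effect).  If an :class:`InterrupterSpec` is
    given, the interrupting event is inserted into the gap, by default with
    a final state that restores the flanking context state.
    """
    L = as_instant(length)
    if L <= 0:
        raise InjectionError("interruption length must be positive")
    sub = doc.event(at_subevent_boundary)
    if sub.parent is None:
        raise InjectionError(
            f"{at_subevent_boundary!r} has no parent to interrupt")
    target = doc.event(sub.parent)
    pivot = sub.extent.end
    if not (target.extent.start < pivot < target.extent.end):
        raise InjectionError(
            "cannot interrupt at the event's own start or end boundary")

    flank = None
    for c in sorted(doc.continuations.values(), key=lambda c: c.id):
        touches = any(ep.end == pivot or ep.start == pivot
                      for ep in c.life_time.episodes)
        if touches and target.id in ([c.succeeding_subevent]
                                     + doc.ancestors(c.succeeding_subevent)):
            flank = c
            if c.completed_subevent == at_subevent_boundary:
                break
    if flank is None:
        raise InjectionError(
            f"no continuation flanks the boundary of {at_subevent_boundary!r}")

    new = _retime(doc, pivot, L, flank, flank.succeeding_subevent,
                  split_event=target.id)
    if interrupter is not None:
        atoms_final = interrupter.final_atoms
        if atoms_final is None:
            atoms_final = doc.state(flank.context_state).atoms
        s_pre = StateOfAffairs(id=f"{interrupter.id}.s_initial",
                               atoms=interrupter.initial_atoms)
        s_post = StateOfAffairs(id=f"{interrupter.id}.s_final",
                                atoms=atoms_final)
        new.add(s_pre)
        new.add(s_post)
        new.add(EventInstance(
            id=interrupter.id,
            extent=TemporalExtent.single(pivot, pivot + L), parent=None,
            initial_state=s_pre.id, final_state=s_post.id,
            made_of_process=interrupter.label or None))
    new.validate_or_raise()
    return new


# ---------------------------------------------------------------------------
# seeded random processes with ground truth
# ---------------------------------------------------------------------------

def random_process(seed: int, k_phases: int = 5,
                   anomaly_spec: Sequence[tuple[str, int, InstantLike]] = (),
                   ) -> tuple[Document, list[AnomalyFinding]]:
    """A deterministic random multi-phase process with injected anomalies.

    The base document is a linear chain of ``k_phases`` phases with random
    rational durations, one to three participants (possibly one generic,
    type-level participant), and, for longer chains, possibly one interior
    rest phase covered by a rest continuation.  ``anomaly_spec`` entries
    ``(kind, position, length)`` inject a delay or interruption at the
    boundary after phase ``position`` (1-based); interruptions insert an
    auto-generated restoring interrupter.  Returns the perturbed document
    and the ground-truth findings, in final coordinates, for recovery
    comparison.  The same seed yields byte-identical documents.
    """
    if k_phases < 2:
        raise InjectionError("need at least two phases")
    rng = random.Random(seed)
    durations = [Fraction(rng.randint(1, 6), rng.choice((1, 2, 3)))
                 for _ in range(k_phases)]
    rest_j = -1
    if k_phases >= 4 and rng.random() < 0.5:
        rest_j = rng.randint(2, k_phases - 1)

    doc = Document(unit="tick")
    doc.add(ContinuantType(id="helper_kind", label="exchangeable helper"))
    doc.add(Continuant(id="subject", label="process subject"))
    n_extra = rng.randint(0, 2)
    for i in range(n_extra):
        doc.add(Continuant(id=f"participant{i}", label=f"participant {i}"))
    generic = rng.random() < 0.4

    doc.add(StateOfAffairs(id="s_pre", atoms=frozenset(
        {StateAtom("subject", "stage", "pending")})))
    state_ids = []
    for i in range(k_phases + 1):
        if i == rest_j:  # rest phase: no change, reuse the entry state
            state_ids.append(state_ids[-1])
            continue
        sid = f"s{i}"
        doc.add(StateOfAffairs(id=sid, atoms=frozenset(
            {StateAtom("subject", "stage", f"stage_{i}")})))
        state_ids.append(sid)

    doc.add(ContinuationType(id="rp.onset"))
    for i in range(1, k_phases):
        doc.add(ContinuationType(id=f"rp.t{i}"))

    T = sum(durations, Fraction(0))
    parts = [Participation("subject", Interval(Fraction(0), T))]
    parts += [Participation(f"participant{i}", Interval(Fraction(0), T))
              for i in range(n_extra)]
    if generic:
        parts.append(Participation("helper_kind", Interval(Fraction(0), T),
                                   generic=True))
    proc = EventInstance(
        id="proc", extent=TemporalExtent.single(0, T),
        participants=tuple(parts), initial_state="s_pre",
        final_state=state_ids[k_phases])
    doc.add(proc)
    _linear_chain(
        doc, proc, Fraction(0),
        phases=[_Phase(f"p{i}", durations[i - 1], state_ids[i - 1],
                       state_ids[i], rest=(i == rest_j))
                for i in range(1, k_phases + 1)],
        pre_state="s_pre", onset_ctype="rp.onset",
        boundary_ctypes=[f"rp.t{i}" for i in range(1, k_phases)])
    doc.validate_or_raise()

    spec = sorted(anomaly_spec, key=lambda a: a[1])
    positions = [a[1] for a in spec]
    if len(set(positions)) != len(positions):
        raise InjectionError("overlapping injections: duplicate positions")
    if any(not 1 <= p <= k_phases - 1 for p in positions):
        raise InjectionError(
            f"injection positions must be interior boundaries 1..{k_phases - 1}")

    truth: list[AnomalyFinding] = []
    used_pivots: set[Fraction] = set()
    for kind, pos, length in spec:
        L = as_instant(length)
        if kind == "delay":
            k, pivot = _delay_target(doc, f"p{pos}")
            if pivot in used_pivots:
                raise InjectionError("overlapping injections at one boundary")
            used_pivots.add(pivot)
            doc = inject_delay(doc, f"p{pos}", L)
            truth.append(AnomalyFinding(
                kind="delay", episode=Interval(pivot, pivot + L),
                evidencing_continuation=k.id, affected_event="proc"))
        elif kind == "interruption":
            pivot = doc.event(f"p{pos}").extent.end
            if pivot in used_pivots:
                raise InjectionError("overlapping injections at one boundary")
            used_pivots.add(pivot)
            doc = inject_interruption(doc, f"p{pos}", L,
                                      InterrupterSpec(id=f"intr{pos}"))
            truth.append(AnomalyFinding(
                kind="interruption", episode=Interval(pivot, pivot + L),
                evidencing_continuation=None, affected_event="proc"))
        else:
            raise InjectionError(f"unknown anomaly kind {kind!r}")
    return doc, truth
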