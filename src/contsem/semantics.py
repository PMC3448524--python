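"""Clause-by-clause checkers for the continuation-semantic definitions.

Each checker returns a :class:`ClauseReport` whose keys are stable clause
ids ("D1.2", "D5.3", ...) so that callers — and tests — can assert exactly
which clause of a definition failed, not merely that something did.

The checked definitions, informally:

* **D1** (is a continuation of): a continuation is a dependent continuant
  whose life-time starts at the right boundary of a completed subevent,
  ends at the left boundary of the succeeding subevent, depends on every
  participant of the event while both are in effect, and whose context
  state is simultaneously the final state of the completed and the initial
  state of the succeeding subevent.
* **D2** (continuation set): all continuations of the event, plus those of
  all proper subevents, recursively.
* **D3** (event description): the continuation set paired with the event's
  final state.
* **D4** (continuation signature): an ordered list of continuation types
  plus a final-state type, witnessed by at least one existing event.
* **D5** (instantiation): the final state instantiates the final-state
  type, every continuation in the set instantiates some type of the
  signature, every type has an instance — and the temporal order of first
  appearance respects the signature order (event types are strictly
  linear).

"Every timepoint t" quantifications are evaluated by exact interval
intersection: all the sets involved are finite unions of closed rational
intervals, so interval arithmetic decides the dense quantifier without
sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Union

from .errors import ResolutionError, StructuralError
from .model import (
    Continuation,
    ContinuationSet,
    ContinuationSignature,
    Document,
    EventDescription,
    EventInstance,
    proper_subevents,
    state_instance_of,
)


@dataclass
class ClauseReport:
    """Per-clause verdicts for one definitional check.

    ``clauses`` maps clause ids to True/False or ``None`` for clauses that
    could not be decided (e.g. a signature's existence clause with no
    witness supplied).  ``overall`` is lenient towards undecided clauses —
    they are flagged, not failed; ``conclusive`` says whether every clause
    was actually decided.
    """

    definition: str
    subject: str
    object: Optional[str] = None
    clauses: dict[str, Optional[bool]] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def set(self, clause: str, verdict: Optional[bool], note: str = "") -> None:
        self.clauses[clause] = verdict
        if note:
            self.notes[clause] = note

    @property
    def overall(self) -> bool:
        return all(v is not False for v in self.clauses.values())

    @property
    def conclusive(self) -> bool:
        return all(v is not None for v in self.clauses.values())

    @property
    def failed(self) -> list[str]:
        return [c for c, v in self.clauses.items() if v is False]

    @property
    def undecided(self) -> list[str]:
        return [c for c, v in self.clauses.items() if v is None]

    def to_dict(self) -> dict:
        return {
            "definition": self.definition,
            "subject": self.subject,
            "object": self.object,
            "clauses": dict(self.clauses),
            "notes": dict(self.notes),
            "overall": self.overall,
        }


def _dependency_covers(doc: Document, k: Continuation, participant: str,
                       generic_participation: bool) -> bool:
    for dep in k.dependencies:
        if dep.target == participant:
            return True
        if dep.generic and doc.bearer_has_type(participant, dep.target):
            return True
        if generic_participation and dep.generic and dep.target == participant:
            return True  # pragma: no cover - covered by first branch
    return False


def is_continuation_of(doc: Document, k: Union[str, Continuation],
                       event: Union[str, EventInstance],
                       transitive: bool = True) -> ClauseReport:
    """Evaluate the five clauses of the continuation definition.

    Clause ids: D1.1 (continuant record), D1.2 (dependence on every
    participant while coexisting with the event), D1.3 (life-time starts at
    a completed subevent's right boundary), D1.4a (context state is that
    subevent's final state), D1.4b (life-time ends at a succeeding
    subevent's left boundary whose initial state is the context state).
    """
    k = doc.continuation(k) if isinstance(k, str) else k
    e = doc.event(event) if isinstance(event, str) else event
    rep = ClauseReport("D1", subject=k.id, object=e.id)

    # D1.1 — the record is a (dependent) continuant.
    rep.set("D1.1", k.id in doc.continuations)

    # D1.2 — for every instant at which e is in effect and k exists,
    # every participant of e at that instant is in k's dependency set.
    ok = True
    for p in e.participants:
        # exists t with: e in effect at t, k exists at t, p participates at t
        shared = any(
            max(ea.start, p.interval.start, el.start) <=
            min(ea.end, p.interval.end, el.end)
            for ea in e.extent.episodes for el in k.life_time.episodes)
        if shared and not _dependency_covers(doc, k, p.participant, p.generic):
            ok = False
            rep.notes.setdefault(
                "D1.2", f"participant {p.participant!r} not in dependency set")
    rep.set("D1.2", ok)

    # D1.3 / D1.4a — a completed subevent whose right boundary coincides
    # with the life-time's left boundary; among such candidates, one whose
    # final state is the context state.
    left = k.life_time.start
    right = k.life_time.end
    candidates = [s for s in proper_subevents(doc, e, transitive=transitive)
                  if s.extent.end == left]
    rep.set("D1.3", bool(candidates),
            "" if candidates else
            f"no proper subevent ends at {left} (life-time left boundary)")
    if candidates:
        ctx_ok = any(
            s.final_state is not None and
            doc.state(s.final_state).atoms == doc.state(k.context_state).atoms
            for s in candidates)
        rep.set("D1.4a", ctx_ok,
                "" if ctx_ok else
                "no coinciding subevent's final state equals the context state")
    else:
        rep.set("D1.4a", False, "vacuously fails: no clause-3 candidate")

    # D1.4b — a succeeding subevent starting at the life-time's right
    # boundary whose initial state is the context state.
    succ = [s for s in proper_subevents(doc, e, transitive=transitive)
            if s.extent.start == right]
    succ_ok = any(
        s.initial_state is not None and
        doc.state(s.initial_state).atoms == doc.state(k.context_state).atoms
        for s in succ)
    rep.set("D1.4b", succ_ok,
            "" if succ_ok else
            f"no proper subevent starts at {right} with the context state "
            f"as initial state")
    return rep


def continuation_set(doc: Document, event: Union[str, EventInstance],
                     transitive: bool = True) -> ContinuationSet:
    """All declared continuations that pass the continuation definition for
    the event, unioned with the continuation sets of all direct subevents,
    recursively.  The recursion makes membership independent of whether the
    subevent relation itself is taken to be transitive."""
    e = doc.event(event) if isinstance(event, str) else event
    members: set[str] = set()
    for k in doc.continuations.values():
        if is_continuation_of(doc, k, e, transitive=transitive).overall:
            members.add(k.id)
    for child in doc.children(e.id):
        members |= continuation_set(doc, child, transitive=transitive).members
    return ContinuationSet(event=e.id, members=frozenset(members))


def event_description(doc: Document, event: Union[str, EventInstance],
                      transitive: bool = True) -> EventDescription:
    """Pair the continuation set with the event's final state."""
    e = doc.event(event) if isinstance(event, str) else event
    if e.final_state is None:
        raise StructuralError(f"event {e.id!r} has no final state")
    return EventDescription(
        continuation_set=continuation_set(doc, e, transitive=transitive),
        final_state=e.final_state)


def _matches_type(doc: Document, sig: ContinuationSignature,
                  k: Continuation, type_id: str) -> bool:
    if k.ctype != type_id:
        return False
    ct = sig.ctype(type_id)
    if ct.context_state_type is not None:
        st = doc.state_types.get(ct.context_state_type)
        if st is None:
            raise ResolutionError(
                f"signature {sig.id}: unknown state type "
                f"{ct.context_state_type!r}")
        return state_instance_of(doc, k.context_state, st)
    return True


def _first_appearance(doc: Document, kids: list[str]) -> Fraction:
    return min(doc.continuation(kid).life_time.start for kid in kids)


def instantiates(doc: Document, event: Union[str, EventInstance],
                 sig: ContinuationSignature,
                 transitive: bool = True) -> ClauseReport:
    """Does the event instantiate the event type given by the signature?

    Clause ids: D5.1 (final state instantiates the final-state type), D5.2
    (every continuation in the set instantiates some signature type), D5.3
    (every signature type has an instance in the set), D5.order (the first
    appearances of matched continuations are non-decreasing along the
    signature — strict linearity of event types).
    """
    e = doc.event(event) if isinstance(event, str) else event
    rep = ClauseReport("D5", subject=e.id, object=sig.id)
    if e.final_state is None:
        rep.set("D5.1", False, "event has no final state")
        rep.set("D5.2", False)
        rep.set("D5.3", False)
        rep.set("D5.order", False)
        return rep

    rep.set("D5.1",
            state_instance_of(doc, e.final_state, sig.final_state_type))

    ks = continuation_set(doc, e, transitive=transitive)
    matched: dict[str, list[str]] = {t: [] for t in sig.ordered_types}
    unmatched: list[str] = []
    for kid in sorted(ks.members):
        k = doc.continuation(kid)
        hits = [t for t in sig.ordered_types if _matches_type(doc, sig, k, t)]
        for t in hits:
            matched[t].append(kid)
        if not hits:
            unmatched.append(kid)
    rep.set("D5.2", not unmatched,
            "" if not unmatched else
            f"continuations with no signature type: {', '.join(unmatched)}")
    missing = [t for t in sig.ordered_types if not matched[t]]
    rep.set("D5.3", not missing,
            "" if not missing else
            f"signature types with no instance: {', '.join(missing)}")

    if missing:
        rep.set("D5.order", False, "cannot order with uninstantiated types")
    else:
        firsts = [_first_appearance(doc, matched[t]) for t in sig.ordered_types]
        ordered = all(a <= b for a, b in zip(firsts, firsts[1:]))
        rep.set("D5.order", ordered,
                "" if ordered else
                "first appearances do not follow the signature order")
    return rep


def signature_wellformed(doc: Document, sig: ContinuationSignature,
                         witness: Optional[Union[str, EventInstance]] = None,
                         transitive: bool = True) -> ClauseReport:
    """Well-formedness of a continuation signature.

    Clause ids: D4.1 (non-empty ordered type list), D4.2 (valid final-state
    type), D4.3 (an existing event witnesses the signature — its event
    description instantiates it), D4.3b (the instantiation map sends each
    witness continuation to *exactly one* signature type; an ambiguous
    continuation is a signature defect, not something to resolve silently).
    With no witness supplied, D4.3/D4.3b are reported as undecided rather
    than failed.
    """
    rep = ClauseReport("D4", subject=sig.id,
                       object=None if witness is None else
                       (witness if isinstance(witness, str) else witness.id))
    rep.set("D4.1", bool(sig.ordered_types),
            "" if sig.ordered_types else "empty ordered type list")
    rep.set("D4.2", isinstance(sig.final_state_type.templates, frozenset))

    if witness is None:
        rep.set("D4.3", None, "no witness event supplied")
        rep.set("D4.3b", None, "no witness event supplied")
        return rep

    e = doc.event(witness) if isinstance(witness, str) else witness
    inst = instantiates(doc, e, sig, transitive=transitive)
    rep.set("D4.3", inst.overall,
            "" if inst.overall else
            f"witness fails clauses: {', '.join(inst.failed)}")

    ambiguous: list[str] = []
    for kid in sorted(continuation_set(doc, e, transitive=transitive).members):
        k = doc.continuation(kid)
        hits = [t for t in sig.ordered_types if _matches_type(doc, sig, k, t)]
        if len(hits) > 1:
            ambiguous.append(kid)
    rep.set("D4.3b", not ambiguous,
            "" if not ambiguous else
            f"continuations matching several types: {', '.join(ambiguous)}")
    return rep
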