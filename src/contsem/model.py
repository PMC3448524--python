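"""The ontological vocabulary.

Continuants, qualities bundled into states of affairs, events with
subevent trees and participant records, continuations (the dependent
continuants that act as interfaces between subevents), and the class-level
counterparts: state types and continuation signatures.

A :class:`Document` is the unit of exchange: a closed world of identifiers
in which every reference must resolve.  Semantic evaluation of the
definitional clauses lives in :mod:`contsem.semantics`; this module only
enforces structural well-formedness, so that deliberately clause-violating
documents (negative controls) can still be represented.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Union

from .errors import ResolutionError, StructuralError
from .temporal import Interval, TemporalExtent, as_instant

#: Wildcard marker usable in any field of a state-atom template.
WILDCARD = "*"

AtomValue = Union[str, int]


@dataclass(frozen=True)
class ContinuantType:
    """A class of continuants, the target of generic dependence."""

    id: str
    label: str = ""


@dataclass(frozen=True)
class Continuant:
    """An entity wholly present at every instant of its existence.

    ``kind`` distinguishes independent continuants (organisms, organs,
    molecules) from dependent ones; continuations themselves are dependent
    continuants but get their own record type because they carry temporal
    and relational structure.
    """

    id: str
    label: str = ""
    kind: str = "independent"  # "independent" | "dependent"
    types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("independent", "dependent"):
            raise StructuralError(f"continuant {self.id}: bad kind {self.kind!r}")
        object.__setattr__(self, "types", tuple(self.types))


@dataclass(frozen=True)
class StateAtom:
    """One ``(bearer, quality, value)`` fact, e.g. (cervix, dilation, complete).

    In a template (inside a :class:`StateType`) any field may be the
    wildcard ``"*"`` and the bearer may name a continuant type instead of
    an individual.
    """

    bearer: str
    quality: str
    value: AtomValue


@dataclass(frozen=True)
class StateOfAffairs:
    """A finite complex of atoms; identity is set equality of the atoms.

    This is the identity criterion everything else leans on: a state
    restored after an interruption *is* the context state again exactly
    when the atom sets are equal.
    """

    id: str
    atoms: frozenset[StateAtom]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", frozenset(self.atoms))


@dataclass(frozen=True)
class StateType:
    """A set of atom templates; a state instantiates it iff every template
    is matched by at least one atom."""

    id: str
    templates: frozenset[StateAtom]

    def __post_init__(self) -> None:
        object.__setattr__(self, "templates", frozenset(self.templates))


@dataclass(frozen=True)
class Participation:
    """A participant record: ``participant`` (continuant or continuant-type
    id) takes part in the event throughout ``interval``.  ``generic`` marks
    type-level participation, where any instance of the type will do."""

    participant: str
    interval: Interval
    generic: bool = False


@dataclass(frozen=True)
class EventInstance:
    """An occurrent with a (possibly scattered) temporal extent.

    Subevent structure is encoded through ``parent`` pointers and must form
    a forest; every subevent's extent is contained in its parent's extent.
    Delays are parts of the event they delay (inside the extent) whereas
    interruptions are foreign events filling gaps of the extent — the
    extent itself is therefore the single source of truth for duration.
    """

    id: str
    extent: TemporalExtent
    parent: Optional[str] = None
    participants: tuple[Participation, ...] = ()
    initial_state: Optional[str] = None
    final_state: Optional[str] = None
    made_of_process: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "participants", tuple(self.participants))
        if self.extent.is_null:
            raise StructuralError(f"event {self.id}: null extent")


@dataclass(frozen=True)
class Dependency:
    """An entry of a continuation's dependency set; ``generic`` means any
    instance of the named type sustains the continuation (the replaced
    chess pawn)."""

    target: str
    generic: bool = False


@dataclass(frozen=True)
class Continuation:
    """A dependent continuant that bridges two subevents.

    Its *context state* is simultaneously the final state of the completed
    subevent and the initial state of the succeeding one; the continuation
    exists exactly as long as that state (and all its dependencies)
    persist.  The life-time may have several episodes: a continuation
    vanishes during an interruption and reappears — numerically the same
    record — once the context state is restored.

    ``canonical_duration`` is the life-time the continuation has in the
    canonical course of events: 0 for instantaneous phase transitions,
    positive for rest continuations that continue an essential latency
    phase.  Any life-time episode in excess of it is delay material.
    """

    id: str
    life_time: TemporalExtent
    context_state: str
    completed_subevent: str
    succeeding_subevent: str
    ctype: str
    dependencies: frozenset[Dependency] = frozenset()
    canonical_duration: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dependencies", frozenset(self.dependencies))
        object.__setattr__(self, "canonical_duration",
                           as_instant(self.canonical_duration))
        if self.life_time.is_null:
            raise StructuralError(f"continuation {self.id}: null life-time")
        if self.canonical_duration < 0:
            raise StructuralError(
                f"continuation {self.id}: negative canonical duration")


@dataclass(frozen=True)
class ContinuationType:
    """A class of continuations.  Types are opaque labels; optionally a
    state type constrains what the context states of instances must look
    like."""

    id: str
    label: str = ""
    context_state_type: Optional[str] = None


@dataclass(frozen=True)
class ContinuationSignature:
    """The class-level fingerprint of an event type: an ordered list of
    continuation types plus a final-state type.  The order is the canonical
    temporal order of first appearance; event types described this way are
    strictly linear."""

    id: str
    ordered_types: tuple[str, ...]
    final_state_type: StateType
    type_registry: dict[str, ContinuationType] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ordered_types", tuple(self.ordered_types))
        if len(set(self.ordered_types)) != len(self.ordered_types):
            raise StructuralError(
                f"signature {self.id}: duplicate continuation types in Σ")

    def ctype(self, type_id: str) -> ContinuationType:
        return self.type_registry.get(type_id, ContinuationType(type_id))


@dataclass(frozen=True)
class ContinuationSet:
    """All continuations of an event together with those of its proper
    subevents, recursively."""

    event: str
    members: frozenset[str]


@dataclass(frozen=True)
class EventDescription:
    """The instance-level fingerprint: continuation set plus final state."""

    continuation_set: ContinuationSet
    final_state: str


@dataclass(frozen=True)
class AnomalyFinding:
    """A classified structural anomaly.

    ``kind`` is one of ``delay`` (inside the affected event's extent,
    contributes to its duration), ``interruption`` (a foreign event filling
    a gap, excluded from the duration) or ``gap`` (an interruption-shaped
    hole with no confirming interrupter).  ``justification`` lists the
    satisfied clause labels ("D6.2a", "D7.2d-iii", ...).
    """

    kind: str  # "delay" | "interruption" | "gap"
    episode: Interval
    evidencing_continuation: Optional[str]
    affected_event: str
    justification: tuple[str, ...] = ()
    term: Optional[str] = None
    annotation_target: Optional[str] = None
    unconfirmed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("delay", "interruption", "gap"):
            raise StructuralError(f"bad anomaly kind {self.kind!r}")
        object.__setattr__(self, "justification", tuple(self.justification))


@dataclass(frozen=True)
class Issue:
    """One validation problem: a machine code, a path into the document and
    a human-readable message."""

    code: str
    path: str
    message: str

    def __str__(self) -> str:
        return f"{self.code} at {self.path}: {self.message}"


@dataclass
class Document:
    """A self-contained instance document.

    Registries are keyed by id; insertion order is irrelevant because
    serialization sorts by id.  ``unit`` is an optional label for the
    abstract time unit, carried into reports but never interpreted.
    """

    continuants: dict[str, Continuant] = field(default_factory=dict)
    continuant_types: dict[str, ContinuantType] = field(default_factory=dict)
    states: dict[str, StateOfAffairs] = field(default_factory=dict)
    state_types: dict[str, StateType] = field(default_factory=dict)
    continuation_types: dict[str, ContinuationType] = field(default_factory=dict)
    events: dict[str, EventInstance] = field(default_factory=dict)
    continuations: dict[str, Continuation] = field(default_factory=dict)
    unit: Optional[str] = None

    # -- registry helpers ------------------------------------------------

    def add(self, obj) -> None:
        registry = {
            Continuant: self.continuants,
            ContinuantType: self.continuant_types,
            StateOfAffairs: self.states,
            StateType: self.state_types,
            ContinuationType: self.continuation_types,
            EventInstance: self.events,
            Continuation: self.continuations,
        }[type(obj)]
        if obj.id in registry:
            raise StructuralError(f"duplicate id {obj.id!r}")
        registry[obj.id] = obj

    def event(self, eid: str) -> EventInstance:
        try:
            return self.events[eid]
        except KeyError:
            raise ResolutionError(f"unknown event {eid!r}") from None

    def state(self, sid: str) -> StateOfAffairs:
        try:
            return self.states[sid]
        except KeyError:
            raise ResolutionError(f"unknown state {sid!r}") from None

    def continuation(self, kid: str) -> Continuation:
        try:
            return self.continuations[kid]
        except KeyError:
            raise ResolutionError(f"unknown continuation {kid!r}") from None

    def replace_event(self, ev: EventInstance) -> None:
        self.events[ev.id] = ev

    def replace_continuation(self, k: Continuation) -> None:
        self.continuations[k.id] = k

    def clone(self) -> "Document":
        """Independent copy; records are immutable so registries are
        shallow-copied."""
        return dataclasses.replace(
            self,
            continuants=dict(self.continuants),
            continuant_types=dict(self.continuant_types),
            states=dict(self.states),
            state_types=dict(self.state_types),
            continuation_types=dict(self.continuation_types),
            events=dict(self.events),
            continuations=dict(self.continuations),
        )

    # -- tree navigation -------------------------------------------------

    def children(self, eid: str) -> list[EventInstance]:
        """Direct subevents, in temporal order (then id order)."""
        kids = [ev for ev in self.events.values() if ev.parent == eid]
        kids.sort(key=lambda ev: (ev.extent.start, ev.extent.end, ev.id))
        return kids

    def root_events(self) -> list[EventInstance]:
        roots = [ev for ev in self.events.values() if ev.parent is None]
        roots.sort(key=lambda ev: (ev.extent.start, ev.id))
        return roots

    def ancestors(self, eid: str) -> list[str]:
        """Proper ancestors of an event, nearest first."""
        out: list[str] = []
        seen = {eid}
        cur = self.event(eid).parent
        while cur is not None:
            if cur in seen:
                raise StructuralError(f"subevent cycle at {cur!r}")
            out.append(cur)
            seen.add(cur)
            cur = self.event(cur).parent
        return out

    def depth(self, eid: str) -> int:
        return len(self.ancestors(eid))

    # -- state helpers ---------------------------------------------------

    def states_equal(self, a: str, b: str) -> bool:
        """Identity criterion for states: set equality of atoms."""
        return self.state(a).atoms == self.state(b).atoms

    def bearer_has_type(self, bearer: str, type_id: str) -> bool:
        cont = self.continuants.get(bearer)
        return cont is not None and type_id in cont.types

    # -- validation ------------------------------------------------------

    def validate(self) -> list[Issue]:
        """Structural and referential validation.

        Returns the full list of problems instead of stopping at the first,
        so a CLI run can report every dangling id at once.  Definition-level
        semantic checks are *not* performed here — see
        :func:`contsem.semantics.is_continuation_of` and friends.
        """
        issues: list[Issue] = []

        def dangle(path: str, what: str, ref: str) -> None:
            issues.append(Issue("dangling-id", path, f"{what} {ref!r} does not resolve"))

        for c in self.continuants.values():
            for t in c.types:
                if t not in self.continuant_types:
                    dangle(f"/continuants/{c.id}/types", "continuant type", t)
        for s in self.states.values():
            for atom in sorted(s.atoms, key=lambda a: (a.bearer, a.quality, str(a.value))):
                if atom.bearer not in self.continuants and \
                        atom.bearer not in self.continuant_types:
                    dangle(f"/states/{s.id}/atoms", "bearer", atom.bearer)
        for st in self.state_types.values():
            for tpl in st.templates:
                if tpl.bearer != WILDCARD and tpl.bearer not in self.continuants \
                        and tpl.bearer not in self.continuant_types:
                    dangle(f"/state_types/{st.id}/templates", "bearer", tpl.bearer)

        for ev in self.events.values():
            path = f"/events/{ev.id}"
            if ev.parent is not None:
                if ev.parent not in self.events:
                    dangle(path + "/parent", "event", ev.parent)
                else:
                    parent = self.events[ev.parent]
                    if not parent.extent.contains_extent(ev.extent):
                        issues.append(Issue(
                            "containment", path,
                            f"extent {ev.extent} not contained in parent "
                            f"{ev.parent!r} extent {parent.extent}"))
            for i, p in enumerate(ev.participants):
                if p.participant not in self.continuants and \
                        p.participant not in self.continuant_types:
                    dangle(f"{path}/participants/{i}", "participant", p.participant)
            for which in ("initial_state", "final_state"):
                sid = getattr(ev, which)
                if sid is not None and sid not in self.states:
                    dangle(f"{path}/{which}", "state", sid)

        # forest check: parent chains must terminate
        for ev in self.events.values():
            try:
                self.ancestors(ev.id)
            except StructuralError as exc:
                issues.append(Issue("cycle", f"/events/{ev.id}", str(exc)))
                break
            except ResolutionError:
                pass  # already reported as dangling

        for k in self.continuations.values():
            path = f"/continuations/{k.id}"
            if k.context_state not in self.states:
                dangle(path + "/context_state", "state", k.context_state)
            for ref, name in ((k.completed_subevent, "completed_subevent"),
                              (k.succeeding_subevent, "succeeding_subevent")):
                if ref not in self.events:
                    dangle(f"{path}/{name}", "event", ref)
            for dep in k.dependencies:
                if dep.target not in self.continuants and \
                        dep.target not in self.continuant_types:
                    dangle(path + "/dependencies", "dependency target", dep.target)
            if k.ctype not in self.continuation_types:
                dangle(path + "/ctype", "continuation type", k.ctype)
        for ct in self.continuation_types.values():
            if ct.context_state_type is not None and \
                    ct.context_state_type not in self.state_types:
                dangle(f"/continuation_types/{ct.id}", "state type",
                       ct.context_state_type)

        issues.sort(key=lambda i: (i.path, i.code, i.message))
        return issues

    def validate_or_raise(self) -> None:
        issues = self.validate()
        if issues:
            raise ResolutionError(
                "; ".join(str(i) for i in issues[:10])
                + ("" if len(issues) <= 10 else f" (+{len(issues) - 10} more)"))


# -- operations -----------------------------------------------------------

def proper_subevents(doc: Document, event: Union[str, EventInstance],
                     transitive: bool = True) -> list[EventInstance]:
    """The proper subevents of an event: direct children, or the transitive
    closure of the child relation.

    Transitivity is the classical-mereology default.  The non-transitive
    setting models the view on which a sub-subevent (moving the foot down)
    is not itself a subevent of the whole (driving the car); continuation
    sets then still aggregate recursively, so their membership does not
    depend on the flag.
    """
    eid = event if isinstance(event, str) else event.id
    doc.event(eid)  # raise early on dangling id
    out: list[EventInstance] = []
    seen: set[str] = {eid}
    frontier = doc.children(eid)
    while frontier:
        nxt: list[EventInstance] = []
        for ev in frontier:
            if ev.id in seen:
                raise StructuralError(f"subevent cycle at {ev.id!r}")
            seen.add(ev.id)
            out.append(ev)
            if transitive:
                nxt.extend(doc.children(ev.id))
        frontier = nxt
    return out


def _atom_matches(doc: Document, template: StateAtom, atom: StateAtom) -> bool:
    if template.quality != WILDCARD and template.quality != atom.quality:
        return False
    if template.value != WILDCARD and template.value != atom.value:
        return False
    if template.bearer == WILDCARD or template.bearer == atom.bearer:
        return True
    # a type-level bearer in the template matches any individual of the type
    return doc.bearer_has_type(atom.bearer, template.bearer)


def state_instance_of(doc: Document, state: Union[str, StateOfAffairs],
                      state_type: Union[str, StateType]) -> bool:
    """True iff every template of the state type is matched by at least one
    atom of the state.  Wildcards match anything; a type-level bearer in a
    template matches any individual continuant carrying that type."""
    s = doc.state(state) if isinstance(state, str) else state
    if isinstance(state_type, str):
        if state_type not in doc.state_types:
            raise ResolutionError(f"unknown state type {state_type!r}")
        st = doc.state_types[state_type]
    else:
        st = state_type
    return all(any(_atom_matches(doc, tpl, atom) for atom in s.atoms)
               for tpl in st.templates)


def home_event(doc: Document, k: Continuation) -> Optional[str]:
    """The lowest event of which ``k`` can be a continuation: the nearest
    common proper ancestor of its completed and succeeding subevents."""
    anc_completed = doc.ancestors(k.completed_subevent)
    anc_succeeding = set(doc.ancestors(k.succeeding_subevent))
    for eid in anc_completed:
        if eid in anc_succeeding:
            return eid
    return None
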