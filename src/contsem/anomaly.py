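"""Detection and classification of structural process anomalies.

Two anomaly kinds are distinguished by severity and by their effect on
duration:

* a **delay** is a contiguous proper part of the event during which the
  continuation for the next genuine subevent merely persists — nothing
  relevant to the process happens, but the process is still in effect.
  Delays lie inside the event's temporal extent and contribute to its
  duration.  Detection rule: a continuation life-time episode that lasts
  longer than the continuation's canonical duration evidences a delay,
  right-aligned with the episode (the right boundaries coincide).
* an **interruption** is a foreign contiguous event filling a gap in the
  event's (scattered) extent: the prerequisites for continuing are absent,
  the process is not taking place, and the gap does not contribute to the
  duration.  The flanking continuation vanishes at the gap and reappears —
  numerically the same record, with a new life-time episode starting at
  the gap's right boundary — once the interrupting event has restored its
  context state.

A gap in a *subprocess* can at the same time be a delay of its
superprocess (the train ride is interrupted in Brussels even though the
journey is not — the journey is merely delayed): if the superprocess
remains in effect across a subprocess gap and the gap's flanking
continuation belongs to the superprocess's continuation set, the gap is
reported as a superprocess delay.  Within a single event the two kinds are
exclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Optional, Sequence, Union

from .errors import InvariantViolation
from .model import (
    AnomalyFinding,
    Continuation,
    ContinuationSignature,
    Document,
    EventInstance,
    proper_subevents,
)
from .semantics import ClauseReport, continuation_set, instantiates
from .temporal import Interval, as_instant, lies_between, overlaps

#: Phenotype-quality term attached to delay findings.
PATO_DELAYED = "PATO:0000502 delayed"
#: Phenotype-quality term attached to interruption findings.
PATO_DISRUPTED = "PATO:0001507 disrupted"


def _life_flanks_gap(k: Continuation, gap: Interval) -> bool:
    """The continuation existed at or before the gap's left boundary and
    one of its life-time episodes begins exactly at the gap's right
    boundary — intermittent existence around the gap."""
    if k.life_time.start > gap.start:
        return False
    return any(ep.start == gap.end for ep in k.life_time.episodes)


def detect_delays(doc: Document, event: Union[str, EventInstance],
                  transitive: bool = True) -> list[AnomalyFinding]:
    """All maximal delay episodes of an event.

    Two sources:

    1. **excess life-time** — for every continuation in the event's
       continuation set, every life-time episode longer than the
       continuation's canonical duration yields a delay whose episode is
       the right-aligned excess portion (with canonical duration 0 the
       whole episode is excess; threshold behaviour at exactly-canonical
       length is "not a delay");
    2. **subprocess gaps** — a gap in a proper subevent's extent that the
       event itself spans, flanked by an intermittently existing
       continuation of the set, is a delay of this event (level
       sensitivity).

    Only maximal episodes are reported; proper subintervals of a reported
    delay count as delays on query via :func:`is_delay`.
    """
    e = doc.event(event) if isinstance(event, str) else event
    ks = continuation_set(doc, e, transitive=transitive)
    findings: list[AnomalyFinding] = []
    seen: set[tuple[Fraction, Fraction]] = set()

    for kid in sorted(ks.members):
        k = doc.continuation(kid)
        for ep in k.life_time.episodes:
            excess = ep.length - k.canonical_duration
            if excess <= 0:
                continue
            episode = Interval(ep.end - excess, ep.end)
            if not e.extent.contains_interval(episode):
                continue  # the event is not in effect there; not its delay
            if (episode.start, episode.end) in seen:
                continue
            seen.add((episode.start, episode.end))
            findings.append(AnomalyFinding(
                kind="delay", episode=episode, evidencing_continuation=kid,
                affected_event=e.id,
                justification=("D6.2a", "D6.2b", "D6.2c")))

    for sub in proper_subevents(doc, e, transitive=True):
        for gap in sub.extent.gaps():
            if not e.extent.contains_interval(gap):
                continue  # the event is not in effect during the gap either
            if (gap.start, gap.end) in seen:
                continue
            flank = next(
                (kid for kid in sorted(ks.members)
                 if _life_flanks_gap(doc.continuation(kid), gap)), None)
            if flank is None:
                continue
            seen.add((gap.start, gap.end))
            findings.append(AnomalyFinding(
                kind="delay", episode=gap, evidencing_continuation=flank,
                affected_event=e.id,
                justification=("D6.2a", f"gap-of-subevent:{sub.id}",
                               "level-sensitivity")))

    findings.sort(key=lambda f: (f.episode.start, f.episode.end))
    return findings


def interruption_report(doc: Document, event: Union[str, EventInstance],
                        candidate: Union[str, EventInstance],
                        transitive: bool = True) -> ClauseReport:
    """Clause-by-clause evaluation of whether a candidate event is an
    interruption of the event.

    Clause ids: D7.2a (candidate contiguous), D7.2b (strictly between the
    event's outer boundaries), D7.2c (extents do not overlap — a candidate
    overlapping the event is recorded as a 2c failure, not an exception),
    D7.2d-i..v (a continuation of the set whose context state the candidate's
    final state restores, which existed at or before the gap and reappears
    exactly at its right boundary).
    """
    e = doc.event(event) if isinstance(event, str) else event
    c = doc.event(candidate) if isinstance(candidate, str) else candidate
    rep = ClauseReport("D7", subject=c.id, object=e.id)

    rep.set("D7.2a", c.extent.is_contiguous)
    rep.set("D7.2b", lies_between(c.extent, e.extent),
            "" if lies_between(c.extent, e.extent) else
            "candidate not strictly between the event's outer boundaries")
    rep.set("D7.2c", not overlaps(c.extent, e.extent),
            "" if not overlaps(c.extent, e.extent) else
            "temporal extensions overlap")

    ks = continuation_set(doc, e, transitive=transitive)
    gap = Interval(c.extent.start, c.extent.end)
    witness: Optional[str] = None
    best: tuple[bool, bool, bool] = (False, False, False)
    for kid in sorted(ks.members):
        k = doc.continuation(kid)
        restores = (c.final_state is not None and
                    doc.state(c.final_state).atoms ==
                    doc.state(k.context_state).atoms)
        before = k.life_time.start <= gap.start
        reappears = any(ep.start == gap.end for ep in k.life_time.episodes)
        cand = (restores, before, reappears)
        if all(cand):
            witness = kid
            best = cand
            break
        if sum(cand) > sum(best):
            witness, best = kid, cand
    rep.set("D7.2d-i", witness is not None,
            "" if witness else "continuation set is empty")
    rep.set("D7.2d-iii", best[0],
            "" if best[0] else
            "candidate's final state is no continuation's context state")
    rep.set("D7.2d-iv", best[1])
    rep.set("D7.2d-v", best[2])
    if witness is not None and all(best):
        rep.notes["witness"] = witness
    return rep


def detect_interruptions(doc: Document, event: Union[str, EventInstance],
                         candidates: Sequence[Union[str, EventInstance]] = (),
                         transitive: bool = True) -> list[AnomalyFinding]:
    """Classify candidate events as interruptions, and report unexplained
    extent gaps.

    A candidate satisfying all clauses yields a ``kind="interruption"``
    finding.  Gaps of the event's own extent that no accepted candidate
    covers — but that are flanked by episodes of one and the same
    continuation — are reported as ``kind="gap"``: interruption-shaped but
    unconfirmed.
    """
    e = doc.event(event) if isinstance(event, str) else event
    findings: list[AnomalyFinding] = []
    covered: set[tuple[Fraction, Fraction]] = set()

    for cand in candidates:
        c = doc.event(cand) if isinstance(cand, str) else cand
        rep = interruption_report(doc, e, c, transitive=transitive)
        if rep.overall:
            episode = Interval(c.extent.start, c.extent.end)
            covered.add((episode.start, episode.end))
            findings.append(AnomalyFinding(
                kind="interruption", episode=episode,
                evidencing_continuation=rep.notes.get("witness"),
                affected_event=e.id,
                justification=tuple(sorted(rep.clauses))))

    ks = continuation_set(doc, e, transitive=transitive)
    for gap in e.extent.gaps():
        if (gap.start, gap.end) in covered:
            continue
        flank = next((kid for kid in sorted(ks.members)
                      if _life_flanks_gap(doc.continuation(kid), gap)), None)
        if flank is not None:
            findings.append(AnomalyFinding(
                kind="gap", episode=gap, evidencing_continuation=flank,
                affected_event=e.id,
                justification=("extent-gap", "D7.2d-iv", "D7.2d-v"),
                unconfirmed=True))

    findings.sort(key=lambda f: (f.episode.start, f.episode.end, f.kind))
    return findings


def is_delay(doc: Document, event: Union[str, EventInstance],
             episode: Interval) -> bool:
    """Is the interval a delay of the event?  True for every reported
    maximal delay episode and for all its subintervals (a proper subevent
    of a delay is a delay)."""
    return any(f.episode.contains_interval(episode)
               for f in detect_delays(doc, event))


def is_interruption(doc: Document, event: Union[str, EventInstance],
                    episode: Interval,
                    candidates: Sequence[Union[str, EventInstance]] = ()) -> bool:
    """Is the interval (part of) an interruption of the event?  Subevents
    of an interruption count as interruptions."""
    return any(f.kind == "interruption" and f.episode.contains_interval(episode)
               for f in detect_interruptions(doc, event, candidates))


@dataclass(frozen=True)
class DurationReport:
    """Decomposition of an event's effective duration.

    ``total = phase_time + delay_time``; ``gap_time`` is the summed length
    of extent gaps, which by construction is excluded from the total.
    """

    event: str
    total: Fraction
    phase_time: Fraction
    delay_time: Fraction
    gap_time: Fraction
    unit: Optional[str] = None


def duration_report(doc: Document, event: Union[str, EventInstance],
                    transitive: bool = True) -> DurationReport:
    """Compute and cross-check the duration decomposition of an event.

    Verifies the kind/extent invariants (delays inside the extent,
    interruption gaps outside it); a violation raises
    :class:`InvariantViolation` because it means the document's extents
    and findings disagree about what counts as process time.
    """
    e = doc.event(event) if isinstance(event, str) else event
    total = e.extent.duration
    delays = detect_delays(doc, e, transitive=transitive)
    delay_time = Fraction(0)
    for f in delays:
        if not e.extent.contains_interval(f.episode):
            raise InvariantViolation(
                f"delay {f.episode} of {e.id!r} outside its extent {e.extent}")
        delay_time += f.episode.length
    gap_time = Fraction(0)
    for gap in e.extent.gaps():
        if any(ep.overlaps(gap) for ep in e.extent.episodes):
            raise InvariantViolation(
                f"gap {gap} of {e.id!r} overlaps its own extent")
        gap_time += gap.length
    return DurationReport(event=e.id, total=total,
                          phase_time=total - delay_time,
                          delay_time=delay_time, gap_time=gap_time,
                          unit=doc.unit)


def effective_duration(doc: Document, event: Union[str, EventInstance],
                       transitive: bool = True) -> Fraction:
    """The event's effective duration: the measure of its temporal extent.

    Delays lie inside the extent and therefore contribute; interruption
    gaps lie outside it and do not.  The decomposition invariants are
    asserted on every call (see :func:`duration_report`).
    """
    return duration_report(doc, event, transitive=transitive).total


def _context_multiset(doc: Document, members: frozenset[str]) -> dict:
    out: dict[tuple[str, frozenset], int] = {}
    for kid in members:
        k = doc.continuation(kid)
        key = (k.ctype, doc.state(k.context_state).atoms)
        out[key] = out.get(key, 0) + 1
    return out


def check_invariance(canonical_doc: Document, canonical_event: str,
                     perturbed_doc: Document, perturbed_event: str,
                     sig: ContinuationSignature,
                     transitive: bool = True) -> bool:
    """The anomaly-invariance property: a structurally anomalous token
    still belongs to the same event type as the canonical one.

    True iff (1) both events instantiate the signature, (2) their
    continuation sets agree as multisets of (continuation type, context
    state) pairs, and (3) every gap in the perturbed document's extents is
    flanked by ONE continuation record with a multi-episode life-time —
    identity of the continuation, and hence of the event, across the
    interruption.
    """
    if not instantiates(canonical_doc, canonical_event, sig,
                        transitive=transitive).overall:
        return False
    if not instantiates(perturbed_doc, perturbed_event, sig,
                        transitive=transitive).overall:
        return False

    m_can = _context_multiset(
        canonical_doc,
        continuation_set(canonical_doc, canonical_event, transitive).members)
    m_per = _context_multiset(
        perturbed_doc,
        continuation_set(perturbed_doc, perturbed_event, transitive).members)
    if m_can != m_per:
        return False

    pe = perturbed_doc.event(perturbed_event)
    for ev in [pe] + proper_subevents(perturbed_doc, pe, transitive=True):
        for gap in ev.extent.gaps():
            flankers = [
                k for k in perturbed_doc.continuations.values()
                if len(k.life_time.episodes) >= 2 and _life_flanks_gap(k, gap)
            ]
            if len(flankers) != 1:
                return False
    return True


def map_finding_terms(doc: Document, finding: AnomalyFinding) -> AnomalyFinding:
    """Attach the phenotype-quality term and annotation target.

    Delays carry "PATO:0000502 delayed", attached not to the superprocess
    experiencing the delay but to the subprocess immediately succeeding it
    (the succeeding subevent of the evidencing continuation).  Interruptions
    carry "PATO:0001507 disrupted" on the interrupted event.  Gap findings
    stay term-less and flagged unconfirmed.
    """
    if finding.kind == "delay":
        target: Optional[str] = None
        if finding.evidencing_continuation is not None:
            k = doc.continuation(finding.evidencing_continuation)
            if k.succeeding_subevent in doc.events:
                target = k.succeeding_subevent
        if target is None:
            warnings.warn(
                f"delay finding on {finding.affected_event!r} has no "
                f"succeeding subevent; term annotation skipped", stacklevel=2)
            return finding
        return replace(finding, term=PATO_DELAYED, annotation_target=target)
    if finding.kind == "interruption":
        return replace(finding, term=PATO_DISRUPTED,
                       annotation_target=finding.affected_event)
    return replace(finding, unconfirmed=True)
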