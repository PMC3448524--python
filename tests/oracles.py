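"""Brute-force clause enumerators, independent of the library's interval
arithmetic.

These oracles decide the definitional clauses by literal enumeration:
dense "for every timepoint" quantifiers are evaluated over a finite sample
containing every boundary instant plus the midpoints between consecutive
ones (all membership conditions are finite unions of closed intervals with
those boundaries, so the sample is decision-complete), and the anomaly
detectors are mirrored by exhaustive candidate-interval enumeration over
the same grid.  The library must agree with them on every document.
"""

from __future__ import annotations

from fractions import Fraction

from contsem.model import Continuation, Document, EventInstance


# ---------------------------------------------------------------------------
# sampling grid
# ---------------------------------------------------------------------------

def boundary_instants(doc: Document) -> list[Fraction]:
    pts: set[Fraction] = set()
    for ev in doc.events.values():
        for ep in ev.extent.episodes:
            pts.update((ep.start, ep.end))
        for p in ev.participants:
            pts.update((p.interval.start, p.interval.end))
    for k in doc.continuations.values():
        for ep in k.life_time.episodes:
            pts.update((ep.start, ep.end))
        # right boundary of the canonical portion of each life episode
        for ep in k.life_time.episodes:
            pts.add(ep.start + k.canonical_duration)
    return sorted(pts)


def sample_instants(doc: Document) -> list[Fraction]:
    bounds = boundary_instants(doc)
    out = list(bounds)
    for a, b in zip(bounds, bounds[1:]):
        out.append((a + b) / 2)
    return sorted(out)


def _in_extent(extent, t: Fraction) -> bool:
    return any(ep.start <= t <= ep.end for ep in extent.episodes)


# ---------------------------------------------------------------------------
# subevents and continuation sets by literal recursion
# ---------------------------------------------------------------------------

def brute_subevents(doc: Document, eid: str, transitive: bool = True
                    ) -> list[EventInstance]:
    if transitive:
        out = []
        for ev in doc.events.values():
            cur = ev.parent
            while cur is not None:
                if cur == eid:
                    out.append(ev)
                    break
                cur = doc.events[cur].parent
        return out
    return [ev for ev in doc.events.values() if ev.parent == eid]


def _dep_ok(doc: Document, k: Continuation, participant: str) -> bool:
    for dep in k.dependencies:
        if dep.target == participant:
            return True
        if dep.generic:
            cont = doc.continuants.get(participant)
            if cont is not None and dep.target in cont.types:
                return True
    return False


def brute_is_continuation_of(doc: Document, k: Continuation,
                             e: EventInstance, transitive: bool = True) -> dict:
    """Literal per-clause evaluation of the continuation definition."""
    clauses: dict[str, bool] = {}
    clauses["D1.1"] = k.id in doc.continuations

    ok = True
    for t in sample_instants(doc):
        if not (_in_extent(e.extent, t) and _in_extent(k.life_time, t)):
            continue
        for p in e.participants:
            if p.interval.start <= t <= p.interval.end and \
                    not _dep_ok(doc, k, p.participant):
                ok = False
    clauses["D1.2"] = ok

    subs = brute_subevents(doc, e.id, transitive)
    left = k.life_time.episodes[0].start
    right = k.life_time.episodes[-1].end
    ctx = doc.states[k.context_state].atoms
    coinciding = [s for s in subs if s.extent.episodes[-1].end == left]
    clauses["D1.3"] = bool(coinciding)
    clauses["D1.4a"] = any(
        s.final_state is not None and doc.states[s.final_state].atoms == ctx
        for s in coinciding)
    clauses["D1.4b"] = any(
        s.extent.episodes[0].start == right and s.initial_state is not None
        and doc.states[s.initial_state].atoms == ctx
        for s in subs)
    return clauses


def brute_continuation_set(doc: Document, eid: str) -> frozenset[str]:
    members = {k.id for k in doc.continuations.values()
               if all(brute_is_continuation_of(doc, k, doc.events[eid]).values())}
    for child in doc.events.values():
        if child.parent == eid:
            members |= brute_continuation_set(doc, child.id)
    return frozenset(members)


# ---------------------------------------------------------------------------
# anomaly detection by exhaustive candidate enumeration
# ---------------------------------------------------------------------------

def brute_delays(doc: Document, eid: str) -> set[tuple[Fraction, Fraction]]:
    """Maximal delay episodes by enumerating every candidate interval over
    the sampling grid and keeping the clause-satisfying, set-maximal ones."""
    e = doc.events[eid]
    ks = [doc.continuations[kid] for kid in brute_continuation_set(doc, eid)]
    grid = sample_instants(doc)
    accepted: set[tuple[Fraction, Fraction]] = set()
    for i, a in enumerate(grid):
        for b in grid[i + 1:]:
            if not any(ep.start <= a and b <= ep.end
                       for ep in e.extent.episodes):
                continue
            # excess life-time clauses: right boundaries coincide with a
            # life episode, candidate within the beyond-canonical portion
            for k in ks:
                for ep in k.life_time.episodes:
                    if ep.end == b and (ep.end - ep.start) > k.canonical_duration \
                            and (b - a) <= (ep.end - ep.start) - k.canonical_duration:
                        accepted.add((a, b))
            # level sensitivity: a gap of a proper subevent, spanned by e,
            # flanked by a continuation of the set
            for sub in brute_subevents(doc, eid, True):
                for p, q in zip(sub.extent.episodes, sub.extent.episodes[1:]):
                    if (p.end, q.start) != (a, b):
                        continue
                    if any(k.life_time.episodes[0].start <= a and
                           any(ep.start == b for ep in k.life_time.episodes)
                           for k in ks):
                        accepted.add((a, b))
    return {c for c in accepted
            if not any(o != c and o[0] <= c[0] and c[1] <= o[1]
                       for o in accepted)}


def brute_interruptions(doc: Document, eid: str,
                        candidates: list[str]) -> set[tuple[Fraction, Fraction]]:
    """Literal clause check of the interruption definition per candidate."""
    e = doc.events[eid]
    ks = [doc.continuations[kid] for kid in brute_continuation_set(doc, eid)]
    grid = sample_instants(doc)
    out: set[tuple[Fraction, Fraction]] = set()
    for cid in candidates:
        c = doc.events[cid]
        if len(c.extent.episodes) != 1:
            continue  # 2a
        lo, hi = c.extent.episodes[0].start, c.extent.episodes[0].end
        e_lo = e.extent.episodes[0].start
        e_hi = e.extent.episodes[-1].end
        if not (e_lo < lo and hi < e_hi):
            continue  # 2b
        # 2c by point sampling: positive-length overlap contains a grid point
        # interior to both extents
        if any(_in_extent(e.extent, t) and lo < t < hi for t in grid):
            continue
        ok = False
        for k in ks:  # 2d
            if c.final_state is None:
                continue
            if doc.states[c.final_state].atoms != doc.states[k.context_state].atoms:
                continue  # iii
            if k.life_time.episodes[0].start > lo:
                continue  # iv
            if any(ep.start == hi for ep in k.life_time.episodes):  # v
                ok = True
        if ok:
            out.add((lo, hi))
    return out
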