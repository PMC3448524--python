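"""Exact temporal arithmetic for process timelines.

Instants are rational numbers (:class:`fractions.Fraction`), intervals are
closed on both ends, and a :class:`TemporalExtent` is an ordered list of
pairwise-disjoint intervals, so that the life-time of an interrupted
occurrent can be *scattered*.  All comparisons — in particular boundary
coincidence, on which the identity criteria for continuations rest — are
exact equalities; nothing in this module ever goes through a float.

Two conventions matter throughout:

* two closed intervals that share exactly one instant are *in direct
  succession* (they coincide at a common boundary) and do **not** overlap;
  overlap requires a shared subinterval of positive length;
* "lies between" is strict on both sides: an episode that starts at the
  very beginning of an extent or ends at its very end does not lie between
  its boundaries.

Time units are abstract.  Documents may carry a unit label (e.g. "hour")
which is threaded through to reports but never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence, Union

from .errors import ExactnessError, StructuralError

#: An instant on the (rational) timeline.
Instant = Fraction

InstantLike = Union[Fraction, int, str]


def as_instant(value: InstantLike) -> Fraction:
    """Coerce ``value`` to an exact rational instant.

    Accepts Fractions, ints and strings ("3", "7/2", "1.5" — the decimal
    string form converts exactly, 1.5 -> 3/2).  Binary floats are rejected:
    they silently misrepresent most decimal literals, which would make
    boundary coincidence unstable.
    """
    if isinstance(value, bool):
        raise ExactnessError("$", f"not an instant: {value!r}")
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        raise ExactnessError(
            "$", f"float instant {value!r} rejected; use an exact string such as "
                 f'"{value}" (decimal strings convert exactly)')
    if isinstance(value, str):
        try:
            return Fraction(value)
        except (ValueError, ZeroDivisionError) as exc:
            raise ExactnessError("$", f"cannot parse instant {value!r}: {exc}") from exc
    raise ExactnessError("$", f"not an instant: {value!r}")


def format_instant(t: Fraction) -> str:
    """Canonical string form: "3" for integers, "7/2" otherwise."""
    if t.denominator == 1:
        return str(t.numerator)
    return f"{t.numerator}/{t.denominator}"


def coincide(a: InstantLike, b: InstantLike) -> bool:
    """True iff the two instants are exactly equal (boundary coincidence)."""
    return as_instant(a) == as_instant(b)


@dataclass(frozen=True, order=True)
class Interval:
    """A closed interval [start, end] on the rational timeline.

    ``start == end`` denotes an instantaneous interval, e.g. the
    boundary-only life-time of a continuation at a phase transition.
    """

    start: Fraction
    end: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", as_instant(self.start))
        object.__setattr__(self, "end", as_instant(self.end))
        if self.start > self.end:
            raise StructuralError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> Fraction:
        return self.end - self.start

    @property
    def instantaneous(self) -> bool:
        return self.start == self.end

    def contains(self, t: InstantLike) -> bool:
        t = as_instant(t)
        return self.start <= t <= self.end

    def contains_interval(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def intersects(self, other: "Interval") -> bool:
        """Shares at least one instant (boundary contact counts)."""
        return self.start <= other.end and other.start <= self.end

    def overlaps(self, other: "Interval") -> bool:
        """Shares a subinterval of positive length (boundary contact does not)."""
        return max(self.start, other.start) < min(self.end, other.end)

    def shift(self, delta: InstantLike) -> "Interval":
        d = as_instant(delta)
        return Interval(self.start + d, self.end + d)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"[{format_instant(self.start)}, {format_instant(self.end)}]"


IntervalLike = Union[Interval, Sequence[InstantLike]]


def _as_interval(value: IntervalLike) -> Interval:
    if isinstance(value, Interval):
        return value
    try:
        a, b = value
    except (TypeError, ValueError) as exc:
        raise StructuralError(f"not an interval: {value!r}") from exc
    return Interval(as_instant(a), as_instant(b))


@dataclass(frozen=True)
class TemporalExtent:
    """An ordered tuple of pairwise-disjoint, strictly increasing intervals.

    A contiguous extent has exactly one episode; the null extent (no
    episodes) is permitted only as an explicit degenerate value.  Scattered
    extents model both the temporal extension of an interrupted event (the
    interruption gap is excluded) and the intermittent life-time of a
    continuation that vanishes during a gap and reappears afterwards.
    """

    episodes: tuple[Interval, ...]

    def __post_init__(self) -> None:
        eps = tuple(_as_interval(iv) for iv in self.episodes)
        object.__setattr__(self, "episodes", eps)
        for prev, nxt in zip(eps, eps[1:]):
            if prev.end >= nxt.start:
                raise StructuralError(
                    f"episodes not strictly increasing/disjoint: {prev} then {nxt}")

    # -- construction ---------------------------------------------------

    @classmethod
    def from_intervals(cls, intervals: Iterable[IntervalLike],
                       merge_touching: bool = False) -> "TemporalExtent":
        """Normalize arbitrary intervals into a canonical extent.

        With ``merge_touching`` overlapping or boundary-adjacent intervals
        are merged into maximal episodes; without it, any contact between
        input intervals is a structural error.  Normalization is
        idempotent: re-normalizing an extent's episodes returns an equal
        extent.
        """
        ivs = sorted((_as_interval(iv) for iv in intervals),
                     key=lambda iv: (iv.start, iv.end))
        if not merge_touching:
            return cls(tuple(ivs))
        merged: list[Interval] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1].end:
                last = merged.pop()
                merged.append(Interval(last.start, max(last.end, iv.end)))
            else:
                merged.append(iv)
        return cls(tuple(merged))

    @classmethod
    def single(cls, start: InstantLike, end: InstantLike) -> "TemporalExtent":
        return cls((Interval(as_instant(start), as_instant(end)),))

    @classmethod
    def null(cls) -> "TemporalExtent":
        return cls(())

    # -- basic queries ---------------------------------------------------

    @property
    def is_null(self) -> bool:
        return not self.episodes

    @property
    def is_contiguous(self) -> bool:
        return len(self.episodes) == 1

    @property
    def start(self) -> Fraction:
        """Left boundary of the whole extent."""
        if self.is_null:
            raise StructuralError("null extent has no boundaries")
        return self.episodes[0].start

    @property
    def end(self) -> Fraction:
        """Right boundary of the whole extent."""
        if self.is_null:
            raise StructuralError("null extent has no boundaries")
        return self.episodes[-1].end

    @property
    def duration(self) -> Fraction:
        """Total measure: the sum of episode lengths.  Gaps do not count."""
        return sum((ep.length for ep in self.episodes), Fraction(0))

    def contains(self, t: InstantLike) -> bool:
        t = as_instant(t)
        return any(ep.contains(t) for ep in self.episodes)

    def contains_interval(self, iv: IntervalLike) -> bool:
        iv = _as_interval(iv)
        return any(ep.contains_interval(iv) for ep in self.episodes)

    def contains_extent(self, other: "TemporalExtent") -> bool:
        return all(self.contains_interval(ep) for ep in other.episodes)

    def gaps(self) -> tuple[Interval, ...]:
        """The closed intervals between consecutive episodes.

        A gap shares its boundary instants with the flanking episodes —
        which is exactly the shared-boundary picture an interruption needs.
        """
        return tuple(Interval(a.end, b.start)
                     for a, b in zip(self.episodes, self.episodes[1:]))

    def shift(self, delta: InstantLike) -> "TemporalExtent":
        d = as_instant(delta)
        return TemporalExtent(tuple(ep.shift(d) for ep in self.episodes))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return "[" + ", ".join(str(ep) for ep in self.episodes) + "]"


ExtentLike = Union[TemporalExtent, Iterable[IntervalLike]]


def as_extent(value: ExtentLike, merge_touching: bool = False) -> TemporalExtent:
    if isinstance(value, TemporalExtent):
        return value
    return TemporalExtent.from_intervals(value, merge_touching=merge_touching)


# -- module-level operations ----------------------------------------------

def duration(x: ExtentLike) -> Fraction:
    """Total measure of an extent (sum of episode lengths)."""
    return as_extent(x).duration


def overlaps(a: ExtentLike, b: ExtentLike) -> bool:
    """True iff some pair of episodes shares an interval of positive length.

    Sharing a single boundary instant does not count: direct succession is
    not overlap.
    """
    a, b = as_extent(a), as_extent(b)
    return any(ea.overlaps(eb) for ea in a.episodes for eb in b.episodes)


def lies_between(x: ExtentLike, e: ExtentLike) -> bool:
    """True iff x's outer boundaries lie strictly between e's.

    Strict on both sides: an episode starting at e's very start (or ending
    at its very end) is a late start or an abortion, not something lying
    between the boundaries.
    """
    x, e = as_extent(x), as_extent(e)
    if x.is_null or e.is_null:
        raise StructuralError("lies_between requires non-null extents")
    return e.start < x.start and x.end < e.end
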