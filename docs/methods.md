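# Methods

## The model

`contsem` treats an occurrent as an **event instance**: a temporal extent
(a list of disjoint closed rational intervals), a forest of subevents,
participant records `(continuant, interval, generic?)`, and an initial and
final **state of affairs** — a finite set of `(bearer, quality, value)`
atoms whose identity criterion is plain set equality.  Between a completed
subevent and its successor sits a **continuation**: a dependent continuant
whose context state is at once the final state of the one and the initial
state of the other, and which depends on every participant of the event
while both exist.  Five clause groups (D1.1–D1.4b in the clause reports)
make this precise; the package evaluates each clause separately so that a
failure names exactly the condition violated.

Class-level process types are **continuation signatures**: an ordered list
of continuation types plus a final-state type.  An event instantiates the
type when its final state instantiates the final-state type, every member
of its continuation set instantiates some listed type, every listed type
has an instance (D5.1–D5.3), and — because these event types are strictly
linear — the first appearances of the matched continuations are
non-decreasing along the list (D5.order).  Conditional or branching
process types are out of scope; they would require unions of signatures.

Anomalies are defined against the canonical course:

* **Delay** (D6): a continuation life-time episode exceeding the
  continuation's `canonical_duration` evidences a delay equal to the
  right-aligned excess.  Delays are parts of the event (inside its
  extent) and contribute to its duration.
* **Interruption** (D7): a contiguous foreign event strictly between the
  event's outer boundaries, non-overlapping with its extent, whose final
  state equals the context state of a continuation that existed at or
  before the gap and has a life-time episode beginning exactly at the
  gap's right boundary.  The flanking continuation is intermittently
  existent but numerically one record — the identity criterion that makes
  the pre-gap and post-gap stretches one event.  Gaps flanked this way but
  lacking a confirming interrupter are reported as `gap` (unconfirmed).
* **Level sensitivity**: a gap in a subprocess that the superprocess
  spans, flanked by a continuation of the superprocess's set, is reported
  as a *delay of the superprocess* — the interrupted train ride inside a
  merely delayed journey.  Within one event, no episode is ever both.

`effective_duration` is simply the measure of the extent; by construction
delay episodes lie inside it and interruption gaps outside, and the
operation asserts that decomposition (`total = phase time + delay time`,
gaps excluded) on every call.

## Time

All instants are `fractions.Fraction`.  The definitions repeatedly demand
boundary *coincidence* (a life-time starting exactly where a subevent
ends); under floating point, instantiating a signature would depend on
rounding noise, so floats are rejected at the I/O boundary (decimal
literals can be converted exactly on request: `0.1` → 1/10).  Closed
intervals sharing a single instant are *in direct succession*, not
overlapping; "lies between" is strict on both sides, so an episode
starting at the event's very start (a late start) or ending at its very
end (an abortion) never qualifies as an interruption.  Dense
"for every timepoint t" quantifiers are decided by exact interval
intersection — every membership condition involved is a finite union of
closed rational intervals, so no sampling is needed (the test oracles *do*
sample, over all boundaries plus midpoints, which is decision-complete
for the same reason; the two routes are independent).

Units are abstract.  A document may declare a unit label ("hour"), which
reports carry along but nothing interprets.

## Parameters and conventions that matter

* `canonical_duration` (per continuation, default 0; units as the
  document's): the life-time the continuation has canonically.  Phase
  transitions are instantaneous (0); a **rest continuation** spanning a
  latency phase carries the declared latency length, which is how
  essential rest is told apart from a delay — excess beyond it is delay,
  exactly-canonical length is not (strict threshold).  With canonical
  duration 0, the whole positive episode is the excess; the definitional
  "life-time longer than the delay" is read as "longer than its canonical
  portion", since the literal reading would brand right-aligned slices of
  every canonical rest phase as delays.  Canonical durations are data,
  never inferred: natural timing presupposes a reference frame, and that
  frame belongs in the signature/instance documents.
* `rest_grid` (off by default): expands a latency phase into a δ-grid of
  minimal rest periods bridged by instantaneous rest continuations — the
  finite stand-in for "a continuation for every minimally extended period
  of rest", useful as a stress test.  δ must divide the latency length.
* `transitive_subevents` (default true): classical-mereology reading of
  the subevent relation.  Continuation-*set* membership is independent of
  the flag whenever continuations connect sibling subevents, because the
  set aggregates recursively; continuations that cross nesting levels
  (the contraction run's rest continuations, whose completed subevent
  lives inside contraction *i* but whose successor is contraction *i+1*)
  require the transitive reading to be continuations of anything at all.
* Onset boundaries: a process's first continuation needs a *completed*
  subevent, realized as an instantaneous boundary event at the start
  (nested in the first phase, or a direct child where nothing depends on
  the direct-children inventory); dually a contraction run ends with an
  instantaneous end boundary so its last rest continuation has a
  successor.
* Dependence is operationalized as participation: "the event depends on c
  at t" means c occurs in a participant record whose interval contains t.
  `generic: true` on a dependency means any instance of the named
  continuant type sustains the continuation (the replaced chess pawn).
* Continuation types are opaque labels; optionally a type carries a state
  type constraining its instances' context states.  A continuation
  matching two signature types is flagged as a signature defect (D4.3b),
  never resolved silently.

## Fixtures: what they emulate, what they do not

`build_childbirth` encodes the three-phase childbirth (defaults 5+3+1
abstract hours) with mother/child participating throughout, placenta in
the third phase, the dilation-complete context state, and the
child-and-placenta-outside final state; optionally a contraction run nests
inside the dilation phase.  `build_contraction_run` encodes n
contractions (contraction/relaxation/latency, defaults 1+1+2) whose
context states all include a sufficient-oxytocin atom, so an oxytocin
drop-and-recovery event is the canonical interrupter.
`build_tooth_eruption` is a minimal developmental timeline whose delayed
variant reproduces the delayed-primary-tooth-eruption annotation pattern.
`random_process` generates seeded linear chains (random rational phase
durations 1/3–6, 1–3 participants, occasionally one generic participant
and one interior rest phase) and injects anomalies with exact ground
truth.

Injection is exact instant-shifting: inserting time at a pivot boundary
shifts all later instants, stretches enclosing events (delay) or splits
the interrupted event's extent around the gap (interruption), and splits
the flanking continuation's life-time in place.  Because all coincidences
move rigidly, the output revalidates without constraint solving.  Two
deliberate injector limits: a delay cannot be injected at a process's
onset boundary (the completed boundary event is nested inside the phase
that would shift), and injections whose pivots coincide — positions
adjacent across a rest phase — are rejected as overlapping.

These generators produce *complete*, strictly linear processes with
piecewise-constant states.  Passing tests therefore say nothing about
aborted or partial processes (signatures treat processes as complete by
definition — the truncated-childbirth fixture shows instantiation
*failing*), about continuously accumulated slowdowns (a growth process at
reduced speed throughout has no discrete delay episode), about branching
event types, or about statistical steady-state collections in which
different molecules occupy a reaction over time.  Real timeline data
would additionally bring measurement noise on boundary instants, which
exact coincidence deliberately does not model; aligning noisy data onto
this representation is upstream preprocessing.

## Numerical and design choices

* Exactness end to end; no tolerances exist anywhere.
* Detectors report **maximal** episodes; the `is_delay`/`is_interruption`
  predicates answer true for subintervals (a proper subevent of a delay
  is a delay) without listing them.
* Order ties in `D5.order` (equal first instants) pass the non-decreasing
  check; when a signature is read off a document, ties order by subevent
  nesting depth (shallower first), then type id.
* A signature checked without a witness event reports its existence
  clause as *undecided*, not failed.
* An interruption candidate overlapping the event records a clause-2c
  failure rather than raising.
* Degenerate inputs: null extents are structural errors for events and
  life-times; instantaneous intervals are first-class (boundary events,
  transition continuations); the empty state of affairs and the empty
  state type are legal (the latter is vacuously instantiated).
* Batch sizes: the oracle-equivalence and recovery properties run over
  1000 seeded documents, invariance and duration accounting over 300
  seeded triples — sizes chosen to exhaust the generators' structural
  variety (3–7 phases, rest phases, generic participants, 0–2 mixed
  injections) while keeping the suite in the tens of seconds.

## Known limitations

Beyond the scope limits above: the document model fixes participation as
the only dependence relation; qualities do not vary continuously in time;
signatures cannot express optional or repeated-with-variation segments
(repeated segments of *identical* type, like contractions, are fine); and
the superprocess-delay rule requires the subprocess gap to be flanked by
a continuation visible in the superprocess's continuation set — a gap in
an unrelated parallel event is not attributed.
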