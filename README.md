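# contsem — continuation semantics for structural process anomalies

Phenotype ontologies lean heavily on process qualities such as *delayed*
(PATO:0000502) and *disrupted* (PATO:0001507) — think *delayed eruption of
primary teeth* (HP:0000680) — yet those qualities rarely come with
semantics precise enough to *detect* such anomalies in encoded instance
data. `contsem` implements an executable semantics for them, built on an
idea borrowed from programming-language theory: describe a process by its
**continuations**.

A continuation κ of an event *e* is a dependent continuant that exists at
a stage of *e*: it depends on *e*'s participants, carries a **context
state** s_c that is simultaneously the final state of the just-completed
subevent e_c and the initial state of the succeeding subevent e_s, and its
life-time runs from the right boundary of e_c to the left boundary of e_s.
Continuations are interfaces between subevents, not parts of the event.
From them the library builds:

* the **continuation set** K_e (all continuations of *e* and of its proper
  subevents, recursively),
* the **event description** ⟨K_e, s⟩ (the set paired with *e*'s final
  state), and
* class-level **continuation signatures** ⟨Σ, S⟩ — an ordered list of
  continuation types plus a final-state type — with *e* instantiating the
  event type iff its description maps onto ⟨Σ, S⟩.

Structural anomalies then fall out of the same machinery:

* a **delay** is a contiguous proper part of *e* during which a
  continuation merely persists beyond its canonical life-time
  (right-aligned with it); delays lie inside *e*'s temporal extent and
  contribute to its duration;
* an **interruption** is a foreign contiguous event filling a gap in *e*'s
  (scattered) extent whose final state restores the context state of the
  flanking continuation; the continuation is intermittently existent —
  numerically the same record before and after the gap, which is what
  keeps the interrupted event *the same event* — and the gap never counts
  toward the duration;
* both perturbations leave the event description's (type, context-state)
  content untouched, so canonical, delayed and interrupted tokens
  instantiate the same signature: **anomaly invariance**.

Everything temporal uses exact rational arithmetic (`fractions.Fraction`):
the definitions hinge on boundary *coincidence*, and floating tolerance
would make identity criteria unstable.

## Worked example: a delayed childbirth

```python
import contsem as cs

doc, sig = cs.build_childbirth((5, 3, 1))      # dilation, fetal expulsion,
delayed = cs.inject_delay(doc, "dilation", 2)  # placental expulsion (hours)

print("canonical duration:", cs.effective_duration(doc, "childbirth"))
print("delayed duration:  ", cs.effective_duration(delayed, "childbirth"))
for f in cs.detect_delays(delayed, "childbirth"):
    f = cs.map_finding_terms(delayed, f)
    print(f"{f.kind} {f.episode} evidenced by {f.evidencing_continuation}; "
          f"{f.term} on {f.annotation_target}")
print("same event type as canonical:",
      cs.check_invariance(doc, "childbirth", delayed, "childbirth", sig))
```

prints

```
canonical duration: 9
delayed duration:   11
delay [5, 7] evidenced by childbirth.k1; PATO:0000502 delayed on fetal_expulsion
same event type as canonical: True
```

The dilation→expulsion continuation (`childbirth.k1`, context state:
cervix completely dilated, fetal head below the ischial spines, fetus
still in the uterus) has canonical duration 0; after the injection it
persists for two extra hours, so those two hours are a delay, the PATO
*delayed* term is attached to the subprocess *succeeding* the delay
(fetal expulsion, per the PATO convention), the total duration grows from
9 to 11 — and the delayed token still instantiates the childbirth
signature.

Interruptions work dually.  `build_contraction_run` models uterine
contractions (contraction / relaxation / latency phases, every context
state containing a sufficient-oxytocin atom); injecting an
oxytocin-restoring interrupter punches a gap into the run's extent that is
classified `interruption` (PATO *disrupted*), leaves the effective
duration unchanged, and — when the run is nested inside a childbirth —
simultaneously surfaces as a *delay of the childbirth*, the package's
train-ride/journey level sensitivity.

The same operations are available from the shell:

```
contsem generate --scenario childbirth --inject delay:dilation:2 \
        -o delayed.json --signature-out cb.sig.json
contsem detect delayed.json --format tsv
contsem classify delayed.json --signature cb.sig.json
contsem validate delayed.json        # per-clause reports, exit 1 on failure
```

## Layout

| module | contents |
| --- | --- |
| `contsem.temporal` | exact instants, closed intervals, scattered extents |
| `contsem.model` | continuants, states of affairs, events, continuations, signatures, document validation |
| `contsem.semantics` | clause-by-clause checkers: continuation validity, continuation sets, event descriptions, signature well-formedness, instantiation |
| `contsem.anomaly` | delay/interruption detectors, duration accounting, invariance check, PATO term mapping |
| `contsem.fixtures` | childbirth / contraction-run / tooth-eruption builders, anomaly injectors, seeded random processes |
| `contsem.io`, `contsem.cli` | JSON document & signature formats, reports, the `contsem` command |

See `docs/methods.md` for the model's assumptions, parameter conventions
and known limitations.
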