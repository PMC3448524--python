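"""Fixture builders and anomaly injectors: structural guarantees,
determinism, and the injection→detection round trip."""

from fractions import Fraction

import pytest

from contsem import (
    InterrupterSpec,
    Interval,
    build_childbirth,
    build_contraction_run,
    detect_delays,
    detect_interruptions,
    dumps_document,
    effective_duration,
    inject_delay,
    inject_interruption,
    instantiates,
    is_continuation_of,
    random_process,
    signature_from_document,
)
from contsem.errors import InjectionError
from contsem.model import home_event


class TestBuilders:
    def test_childbirth_validates_and_self_instantiates(self):
        for durations in ((5, 3, 1), (1, 1, 1), ("7/2", "1/2", 2)):
            doc, sig = build_childbirth(durations)
            assert doc.validate() == []
            assert instantiates(doc, "childbirth", sig).overall

    def test_childbirth_rejects_nonpositive_durations(self):
        with pytest.raises(InjectionError):
            build_childbirth((5, 0, 1))

    def test_contraction_run_counts(self):
        doc, _ = build_contraction_run(3)
        contractions = [e for e in doc.events.values()
                        if e.parent == "ctr.run" and ".c" in e.id]
        assert len(contractions) == 3
        peaks = [k for k in doc.continuations.values()
                 if k.ctype == "ctr.peak"]
        rests = [k for k in doc.continuations.values()
                 if k.ctype == "ctr.rest"]
        assert len(peaks) == 3 and len(rests) == 3

    def test_single_contraction_has_rest_continuation(self):
        doc, _ = build_contraction_run(1, (1, 1, 2))
        rest = doc.continuation("ctr.run.c1.k_rest")
        assert rest.canonical_duration == 2
        assert rest.life_time.duration == 2

    def test_every_declared_continuation_passes_definition_check(self):
        for doc, _ in (build_childbirth((5, 3, 1), contractions=2),
                       build_contraction_run(2),
                       build_contraction_run(2, rest_grid=1)):
            for k in doc.continuations.values():
                home = home_event(doc, k)
                assert home is not None, k.id
                assert is_continuation_of(doc, k, home).overall, k.id

    def test_rest_grid_expands_latency(self):
        doc, sig = build_contraction_run(1, (1, 1, 2), rest_grid="1/2")
        cells = [e for e in doc.events.values()
                 if e.parent == "ctr.run.c1.latency"]
        assert len(cells) == 4
        grid_conts = [k for k in doc.continuations.values()
                      if k.ctype == "ctr.rest"]
        assert len(grid_conts) == 5
        assert instantiates(doc, "ctr.run", sig).overall
        assert detect_delays(doc, "ctr.run") == []

    def test_rest_grid_must_divide_latency(self):
        with pytest.raises(InjectionError):
            build_contraction_run(1, (1, 1, 2), rest_grid="3/4")


class TestInjectors:
    def test_zero_length_delay_is_identity(self, childbirth):
        doc, _ = childbirth
        assert dumps_document(inject_delay(doc, "dilation", 0)) == \
            dumps_document(doc)

    def test_delay_round_trips_through_detector(self, childbirth):
        doc, _ = childbirth
        delayed = inject_delay(doc, "dilation", 2)
        assert delayed.validate() == []
        assert [f.episode for f in detect_delays(delayed, "childbirth")] == \
            [Interval(Fraction(5), Fraction(7))]

    def test_delay_at_final_boundary_rejected(self, childbirth):
        doc, _ = childbirth
        with pytest.raises(InjectionError, match="succeeding continuation"):
            inject_delay(doc, "placental_expulsion", 2)

    def test_interruption_at_outer_boundary_rejected(self, contraction_run):
        doc, _ = contraction_run
        with pytest.raises(InjectionError, match="start or end"):
            inject_interruption(doc, "ctr.run.c3", 2,
                                InterrupterSpec(id="x"))

    def test_interruption_round_trip(self, contraction_run):
        doc, _ = contraction_run
        gapped = inject_interruption(doc, "ctr.run.c1", 4,
                                     InterrupterSpec(id="intr"))
        assert gapped.validate() == []
        assert gapped.event("ctr.run").extent.episodes == (
            Interval(Fraction(0), Fraction(4)),
            Interval(Fraction(8), Fraction(16)))
        found = detect_interruptions(gapped, "ctr.run", ["intr"])
        assert [(f.kind, f.episode) for f in found] == \
            [("interruption", Interval(Fraction(4), Fraction(8)))]
        assert effective_duration(gapped, "ctr.run") == \
            effective_duration(doc, "ctr.run")

    def test_interruption_splits_flanking_life_time_in_place(
            self, contraction_run):
        doc, _ = contraction_run
        gapped = inject_interruption(doc, "ctr.run.c1", 4,
                                     InterrupterSpec(id="intr"))
        rest = gapped.continuation("ctr.run.c1.k_rest")
        assert rest.life_time.episodes == (
            Interval(Fraction(2), Fraction(4)),
            Interval(Fraction(8), Fraction(8)))


class TestRandomProcesses:
    def test_same_seed_byte_identical(self):
        spec = [("delay", 2, 3), ("interruption", 4, 1)]
        a, _ = random_process(42, 5, spec)
        b, _ = random_process(42, 5, spec)
        assert dumps_document(a) == dumps_document(b)

    def test_ground_truth_recovered_exactly(self):
        doc, truth = random_process(42, 5, [("delay", 2, 3)])
        found = detect_delays(doc, "proc")
        assert [(f.kind, f.episode) for f in found] == \
            [(t.kind, t.episode) for t in truth]

    def test_generated_documents_validate_and_self_instantiate(self):
        for seed in range(25):
            doc, _ = random_process(seed, 4 + seed % 3)
            assert doc.validate() == []
            sig = signature_from_document(doc, "proc", "sig.proc")
            assert instantiates(doc, "proc", sig).overall, seed

    def test_duplicate_positions_rejected(self):
        with pytest.raises(InjectionError, match="overlapping"):
            random_process(1, 5, [("delay", 2, 1), ("interruption", 2, 1)])

    def test_bad_position_rejected(self):
        with pytest.raises(InjectionError):
            random_process(1, 5, [("delay", 5, 1)])
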