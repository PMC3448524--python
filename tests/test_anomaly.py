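"""Anomaly detection: delays, interruptions, duration accounting,
invariance, phenotype term mapping."""

from dataclasses import replace
from fractions import Fraction

import pytest

import oracles
from contsem import (
    InterrupterSpec,
    Interval,
    StateAtom,
    StateOfAffairs,
    build_contraction_run,
    check_invariance,
    detect_delays,
    detect_interruptions,
    duration_report,
    effective_duration,
    inject_delay,
    inject_interruption,
    interruption_report,
    is_delay,
    map_finding_terms,
)
from contsem.anomaly import PATO_DELAYED, PATO_DISRUPTED


class TestDelays:
    def test_canonical_documents_have_no_delays(self, childbirth,
                                                contraction_run,
                                                tooth_eruption):
        for doc, _ in (childbirth, contraction_run, tooth_eruption):
            for eid in doc.events:
                assert detect_delays(doc, eid) == []

    def test_delayed_childbirth_yields_right_aligned_episode(
            self, delayed_childbirth):
        findings = detect_delays(delayed_childbirth, "childbirth")
        assert [(f.kind, f.episode, f.evidencing_continuation)
                for f in findings] == \
            [("delay", Interval(Fraction(5), Fraction(7)), "childbirth.k1")]

    @pytest.mark.parametrize("extra", [0, Fraction(1, 2), 1, 3])
    def test_latency_threshold_sweep(self, extra):
        """Exactly-canonical latency is not a delay; any excess beyond the
        canonical rest duration is, as the right-aligned portion."""
        doc, _ = build_contraction_run(1, (1, 1, 2))
        if extra == 0:
            assert detect_delays(doc, "ctr.run") == []
            return
        delayed = inject_delay(doc, "ctr.run.c1.latency", extra)
        findings = detect_delays(delayed, "ctr.run")
        assert [f.episode for f in findings] == \
            [Interval(Fraction(4), Fraction(4) + extra)]

    def test_stacked_delays_are_additive(self, childbirth):
        doc, _ = childbirth
        once = inject_delay(doc, "dilation", 2)
        twice = inject_delay(once, "fetal_expulsion", 3)
        findings = detect_delays(twice, "childbirth")
        assert [f.episode for f in findings] == [
            Interval(Fraction(5), Fraction(7)),
            Interval(Fraction(10), Fraction(13))]
        assert effective_duration(twice, "childbirth") == 9 + 2 + 3

    def test_subintervals_count_as_delays_on_query(self, delayed_childbirth):
        assert is_delay(delayed_childbirth, "childbirth",
                        Interval(Fraction(11, 2), Fraction(6)))
        assert not is_delay(delayed_childbirth, "childbirth",
                            Interval(Fraction(1), Fraction(2)))


class TestInterruptions:
    def test_oxytocin_restoring_candidate_is_an_interruption(
            self, interrupted_run):
        findings = detect_interruptions(interrupted_run, "ctr.run",
                                        ["oxy_drop"])
        assert [(f.kind, f.episode) for f in findings] == \
            [("interruption", Interval(Fraction(4), Fraction(8)))]
        rep = interruption_report(interrupted_run, "ctr.run", "oxy_drop")
        assert rep.overall and all(rep.clauses.values())

    def test_context_state_without_oxytocin_defeats_restoration_clause(
            self, interrupted_run):
        broken = interrupted_run.clone()
        resting = broken.state("ctr.s_resting")
        broken.states["ctr.s_resting"] = StateOfAffairs(
            id="ctr.s_resting",
            atoms=frozenset(a for a in resting.atoms
                            if a.quality != "oxytocin_concentration"))
        rep = interruption_report(broken, "ctr.run", "oxy_drop")
        assert rep.clauses["D7.2d-iii"] is False
        findings = detect_interruptions(broken, "ctr.run", ["oxy_drop"])
        assert all(f.kind != "interruption" for f in findings)

    def test_non_restoring_candidate_leaves_a_bare_gap(self, contraction_run):
        doc, _ = contraction_run
        hollow = inject_interruption(
            doc, "ctr.run.c1", 4,
            InterrupterSpec(id="noise", final_atoms=frozenset(
                {StateAtom("uterus", "tone", "cramped")})))
        findings = detect_interruptions(hollow, "ctr.run", ["noise"])
        assert [(f.kind, f.episode, f.unconfirmed) for f in findings] == \
            [("gap", Interval(Fraction(4), Fraction(8)), True)]

    def test_gap_without_candidate_reported_as_gap(self, contraction_run):
        doc, _ = contraction_run
        bare = inject_interruption(doc, "ctr.run.c1", 4, None)
        findings = detect_interruptions(bare, "ctr.run")
        assert [(f.kind, f.episode) for f in findings] == \
            [("gap", Interval(Fraction(4), Fraction(8)))]

    def test_candidate_overlapping_event_fails_2c_without_raising(
            self, contraction_run):
        doc, _ = contraction_run
        overlapper = doc.clone()
        from contsem import EventInstance, TemporalExtent
        overlapper.add(StateOfAffairs(id="x_final", atoms=frozenset()))
        overlapper.add(EventInstance(
            id="x", extent=TemporalExtent.single(1, 3),
            final_state="x_final"))
        rep = interruption_report(overlapper, "ctr.run", "x")
        assert rep.clauses["D7.2c"] is False
        assert detect_interruptions(overlapper, "ctr.run", ["x"]) == []

    def test_interruption_of_run_is_not_one_of_childbirth(self):
        """The oxytocin gap interrupts the continued contraction process,
        not the overall childbirth: for childbirth the candidate overlaps
        the (still in effect) extent."""
        from contsem import build_childbirth
        doc, _ = build_childbirth((5, 3, 1), contractions=2)
        perturbed = inject_interruption(doc, "ctr.run.c1", 2,
                                        InterrupterSpec(id="oxy_drop"))
        assert detect_interruptions(perturbed, "ctr.run",
                                    ["oxy_drop"])[0].kind == "interruption"
        assert detect_interruptions(perturbed, "childbirth",
                                    ["oxy_drop"]) == []


class TestDurationAccounting:
    def test_canonical_phases_sum(self, childbirth):
        doc, _ = childbirth
        assert effective_duration(doc, "childbirth") == 9

    def test_delays_contribute(self, delayed_childbirth):
        assert effective_duration(delayed_childbirth, "childbirth") == 11
        rep = duration_report(delayed_childbirth, "childbirth")
        assert (rep.total, rep.phase_time, rep.delay_time, rep.gap_time) == \
            (11, 9, 2, 0)

    def test_interruption_gaps_do_not_contribute(self, contraction_run,
                                                 interrupted_run):
        doc, _ = contraction_run
        assert effective_duration(doc, "ctr.run") == 12
        assert effective_duration(interrupted_run, "ctr.run") == 12
        rep = duration_report(interrupted_run, "ctr.run")
        assert (rep.total, rep.delay_time, rep.gap_time) == (12, 0, 4)


@pytest.fixture(scope="module")
def nested_interrupted():
    from contsem import build_childbirth
    doc, sig = build_childbirth((5, 3, 1), contractions=2)
    perturbed = inject_interruption(doc, "ctr.run.c1", 2,
                                    InterrupterSpec(id="oxy_drop"))
    return doc, perturbed, sig


class TestLevelSensitivity:
    def test_subprocess_interruption_is_superprocess_delay(
            self, nested_interrupted):
        doc, perturbed, _ = nested_interrupted
        gap = Interval(Fraction(5, 2), Fraction(9, 2))
        run_findings = detect_interruptions(perturbed, "ctr.run", ["oxy_drop"])
        assert [(f.kind, f.episode) for f in run_findings] == \
            [("interruption", gap)]
        cb_delays = detect_delays(perturbed, "childbirth")
        assert [(f.kind, f.episode) for f in cb_delays] == [("delay", gap)]
        # the journey lengthens, the ride does not
        assert effective_duration(perturbed, "ctr.run") == \
            effective_duration(doc, "ctr.run")
        assert effective_duration(perturbed, "childbirth") == \
            effective_duration(doc, "childbirth") + 2

    def test_exclusivity_within_one_level(self, nested_interrupted):
        _, perturbed, _ = nested_interrupted
        for eid in ("ctr.run", "childbirth"):
            delays = {f.episode for f in detect_delays(perturbed, eid)}
            interruptions = {
                f.episode for f in detect_interruptions(
                    perturbed, eid, ["oxy_drop"]) if f.kind == "interruption"}
            assert delays.isdisjoint(interruptions), eid


class TestInvariance:
    def test_delayed_token_same_type_and_multiset(self, childbirth,
                                                  delayed_childbirth):
        doc, sig = childbirth
        assert check_invariance(doc, "childbirth",
                                delayed_childbirth, "childbirth", sig)

    def test_interrupted_token_same_type_single_flanking_record(
            self, contraction_run, interrupted_run):
        doc, sig = contraction_run
        assert check_invariance(doc, "ctr.run", interrupted_run, "ctr.run",
                                sig)
        flank = interrupted_run.continuation("ctr.run.c1.k_rest")
        assert len(flank.life_time.episodes) == 2

    def test_truncated_token_fails(self, childbirth):
        from contsem import build_truncated_childbirth
        doc, sig = childbirth
        truncated, _ = build_truncated_childbirth((5, 3))
        assert not check_invariance(doc, "childbirth",
                                    truncated, "childbirth", sig)


class TestTermMapping:
    def test_delay_annotates_succeeding_subprocess(self, delayed_childbirth):
        finding = detect_delays(delayed_childbirth, "childbirth")[0]
        annotated = map_finding_terms(delayed_childbirth, finding)
        assert annotated.term == PATO_DELAYED
        assert annotated.annotation_target == "fetal_expulsion"

    def test_delayed_tooth_eruption_pattern(self, tooth_eruption):
        doc, _ = tooth_eruption
        late = inject_delay(doc, "jaw_maturation", 6)
        finding = detect_delays(late, "dentition_development")[0]
        annotated = map_finding_terms(late, finding)
        assert annotated.term == PATO_DELAYED
        assert annotated.annotation_target == "tooth_eruption"

    def test_interruption_gets_disrupted_term(self, interrupted_run):
        finding = detect_interruptions(interrupted_run, "ctr.run",
                                       ["oxy_drop"])[0]
        annotated = map_finding_terms(interrupted_run, finding)
        assert annotated.term == PATO_DISRUPTED
        assert annotated.annotation_target == "ctr.run"

    def test_gap_finding_stays_termless(self, contraction_run):
        doc, _ = contraction_run
        bare = inject_interruption(doc, "ctr.run.c1", 4, None)
        finding = detect_interruptions(bare, "ctr.run")[0]
        annotated = map_finding_terms(bare, finding)
        assert annotated.term is None and annotated.unconfirmed


class TestDetectorOracles:
    def test_delay_enumeration_agrees(self, delayed_childbirth,
                                      interrupted_run):
        for doc, eid in ((delayed_childbirth, "childbirth"),
                         (interrupted_run, "ctr.run")):
            got = {(f.episode.start, f.episode.end)
                   for f in detect_delays(doc, eid)}
            assert got == oracles.brute_delays(doc, eid)

    def test_interruption_enumeration_agrees(self, interrupted_run):
        got = {(f.episode.start, f.episode.end)
               for f in detect_interruptions(interrupted_run, "ctr.run",
                                             ["oxy_drop"])
               if f.kind == "interruption"}
        assert got == oracles.brute_interruptions(interrupted_run, "ctr.run",
                                                  ["oxy_drop"])
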