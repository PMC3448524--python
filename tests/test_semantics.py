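"""Continuation semantics: Definitions of continuations, continuation
sets, event descriptions, signatures and instantiation."""

from dataclasses import replace
from fractions import Fraction

import pytest

import oracles
from contsem import (
    Continuant,
    Continuation,
    ContinuationType,
    Dependency,
    Document,
    EventInstance,
    Participation,
    StateAtom,
    StateOfAffairs,
    TemporalExtent,
    continuation_set,
    event_description,
    instantiates,
    is_continuation_of,
    signature_from_document,
    signature_wellformed,
)
from contsem.temporal import Interval


class TestContinuationDefinition:
    def test_childbirth_transition_satisfies_every_clause(self, childbirth):
        doc, _ = childbirth
        rep = is_continuation_of(doc, "childbirth.k1", "childbirth")
        assert rep.clauses == {"D1.1": True, "D1.2": True, "D1.3": True,
                               "D1.4a": True, "D1.4b": True}
        assert rep.overall

    def test_missing_dependency_fails_dependence_clause(self, childbirth):
        doc, _ = childbirth
        broken = doc.clone()
        k = doc.continuation("childbirth.k1")
        broken.replace_continuation(replace(
            k, dependencies=frozenset(d for d in k.dependencies
                                      if d.target != "mother")))
        rep = is_continuation_of(broken, "childbirth.k1", "childbirth")
        assert rep.clauses["D1.2"] is False
        assert rep.clauses["D1.3"] is True

    def test_life_time_off_every_boundary_fails_clause_3(self, childbirth):
        doc, _ = childbirth
        broken = doc.clone()
        k = doc.continuation("childbirth.k1")
        shifted = replace(k, life_time=TemporalExtent.single(
            Fraction(9, 2), Fraction(9, 2)))
        broken.replace_continuation(shifted)
        rep = is_continuation_of(broken, "childbirth.k1", "childbirth")
        assert rep.clauses["D1.3"] is False
        # the brute-force boundary scan agrees that nothing coincides
        brute = oracles.brute_is_continuation_of(
            broken, shifted, broken.event("childbirth"))
        assert brute["D1.3"] is False

    def test_wrong_context_state_fails_4a_and_4b(self, childbirth):
        doc, _ = childbirth
        broken = doc.clone()
        k = doc.continuation("childbirth.k1")
        broken.replace_continuation(replace(k, context_state="s_prelabour"))
        rep = is_continuation_of(broken, "childbirth.k1", "childbirth")
        assert rep.clauses["D1.4a"] is False
        assert rep.clauses["D1.4b"] is False


class TestContinuationSet:
    def test_childbirth_members(self, childbirth):
        doc, _ = childbirth
        ks = continuation_set(doc, "childbirth")
        assert ks.members == {"childbirth.k_onset", "childbirth.k1",
                              "childbirth.k2"}

    def test_nested_contractions_aggregate(self, childbirth_with_contractions):
        doc, _ = childbirth_with_contractions
        ks = continuation_set(doc, "childbirth")
        assert {"childbirth.k_onset", "childbirth.k1", "childbirth.k2",
                "ctr.run.k_onset", "ctr.run.c1.k_peak",
                "ctr.run.c1.k_rest"} <= ks.members

    def test_atomic_event_has_empty_set(self, childbirth):
        doc, _ = childbirth
        assert continuation_set(doc, "placental_expulsion").members == \
            frozenset()

    def test_failing_continuation_never_joins(self, childbirth):
        """Monotonicity: adding a clause-violating continuation record
        changes no continuation set."""
        doc, _ = childbirth
        before = continuation_set(doc, "childbirth").members
        bigger = doc.clone()
        bigger.add(Continuation(
            id="impostor", life_time=TemporalExtent.single(1, 1),
            context_state="s_prelabour", completed_subevent="dilation",
            succeeding_subevent="fetal_expulsion", ctype="cb.onset"))
        assert continuation_set(bigger, "childbirth").members == before

    def test_recursion_replaces_transitivity_for_sibling_chains(self):
        """On a three-level nesting whose continuations connect sibling
        subevents, the transitive and non-transitive readings yield the
        same continuation set, because the set recursion supplies what
        subevent transitivity otherwise would."""
        doc = Document()
        doc.add(Continuant(id="agent"))
        for sid, stage in (("s0", "ready"), ("sa", "a_done"), ("sb", "mid_a"),
                           ("s_end", "all_done")):
            doc.add(StateOfAffairs(id=sid, atoms=frozenset(
                {StateAtom("agent", "stage", stage)})))
        doc.add(ContinuationType(id="t.mid"))
        doc.add(ContinuationType(id="t.top"))
        top = EventInstance(id="top", extent=TemporalExtent.single(0, 4),
                            participants=(Participation(
                                "agent", Interval(Fraction(0), Fraction(4))),),
                            initial_state="s0", final_state="s_end")
        doc.add(top)
        doc.add(EventInstance(id="a", extent=TemporalExtent.single(0, 2),
                              parent="top", initial_state="s0",
                              final_state="sa"))
        doc.add(EventInstance(id="b", extent=TemporalExtent.single(2, 4),
                              parent="top", initial_state="sa",
                              final_state="s_end"))
        doc.add(EventInstance(id="a1", extent=TemporalExtent.single(0, 1),
                              parent="a", initial_state="s0",
                              final_state="sb"))
        doc.add(EventInstance(id="a2", extent=TemporalExtent.single(1, 2),
                              parent="a", initial_state="sb",
                              final_state="sa"))
        deps = frozenset({Dependency("agent")})
        doc.add(Continuation(
            id="k_mid", life_time=TemporalExtent.single(1, 1),
            context_state="sb", completed_subevent="a1",
            succeeding_subevent="a2", ctype="t.mid", dependencies=deps))
        doc.add(Continuation(
            id="k_top", life_time=TemporalExtent.single(2, 2),
            context_state="sa", completed_subevent="a",
            succeeding_subevent="b", ctype="t.top", dependencies=deps))
        doc.validate_or_raise()
        with_trans = continuation_set(doc, "top", transitive=True).members
        without = continuation_set(doc, "top", transitive=False).members
        assert with_trans == without == {"k_mid", "k_top"}


class TestEventDescription:
    def test_final_state_is_outside_maternal_body(self, childbirth):
        doc, _ = childbirth
        desc = event_description(doc, "childbirth")
        atoms = doc.state(desc.final_state).atoms
        assert StateAtom("child", "location", "outside_maternal_body") in atoms
        assert StateAtom("placenta", "location",
                         "outside_maternal_body") in atoms

    def test_atomic_event_pairs_empty_set_with_final_state(self, childbirth):
        doc, _ = childbirth
        desc = event_description(doc, "placental_expulsion")
        assert desc.continuation_set.members == frozenset()
        assert desc.final_state == "s_birth_complete"

    def test_missing_final_state_is_structural_error(self, childbirth):
        from contsem.errors import StructuralError
        doc, _ = childbirth
        broken = doc.clone()
        broken.replace_event(replace(doc.event("childbirth"),
                                     final_state=None))
        with pytest.raises(StructuralError):
            event_description(broken, "childbirth")


class TestSignature:
    def test_childbirth_signature_wellformed_with_witness(self, childbirth):
        doc, sig = childbirth
        rep = signature_wellformed(doc, sig, witness="childbirth")
        assert rep.overall and rep.conclusive

    def test_without_witness_existence_clause_is_undecided(self, childbirth):
        doc, sig = childbirth
        rep = signature_wellformed(doc, sig)
        assert rep.clauses["D4.3"] is None
        assert rep.overall            # undecided is not failure
        assert not rep.conclusive

    def test_unmatchable_final_state_type_fails_witness_clause(self,
                                                               childbirth):
        doc, sig = childbirth
        from contsem import StateType
        bogus = replace(sig, final_state_type=StateType(
            id="never", templates=frozenset(
                {StateAtom("child", "location", "on_the_moon")})))
        rep = signature_wellformed(doc, bogus, witness="childbirth")
        assert rep.clauses["D4.3"] is False

    def test_dropping_a_type_leaves_witness_continuation_unmapped(
            self, childbirth):
        doc, sig = childbirth
        shorter = replace(sig,
                          ordered_types=tuple(sig.ordered_types[:-1]))
        rep = instantiates(doc, "childbirth", shorter)
        assert rep.clauses["D5.2"] is False   # k2 matches nothing

    def test_instantiation_order_clause(self, childbirth):
        doc, sig = childbirth
        assert instantiates(doc, "childbirth", sig).overall
        reversed_sig = replace(sig,
                               ordered_types=tuple(reversed(sig.ordered_types)))
        rep = instantiates(doc, "childbirth", reversed_sig)
        assert rep.clauses["D5.order"] is False

    def test_signature_read_off_document_matches_temporal_order(
            self, childbirth_with_contractions):
        doc, _ = childbirth_with_contractions
        sig = signature_from_document(doc, "childbirth", "sig.cbc")
        assert sig.ordered_types == (
            "cb.onset", "ctr.onset", "ctr.peak", "ctr.rest",
            "cb.dilation-complete", "cb.fetus-delivered")
        assert instantiates(doc, "childbirth", sig).overall


class TestOracleAgreement:
    def test_brute_force_agrees_on_all_fixture_continuations(
            self, childbirth, contraction_run, tooth_eruption,
            childbirth_with_contractions):
        for doc, _ in (childbirth, contraction_run, tooth_eruption,
                       childbirth_with_contractions):
            for eid in doc.events:
                if not doc.children(eid):
                    continue
                for k in doc.continuations.values():
                    rep = is_continuation_of(doc, k, eid)
                    brute = oracles.brute_is_continuation_of(
                        doc, k, doc.event(eid))
                    assert rep.clauses == brute, (eid, k.id)

    def test_brute_force_continuation_set_agrees(self, contraction_run):
        doc, _ = contraction_run
        assert oracles.brute_continuation_set(doc, "ctr.run") == \
            continuation_set(doc, "ctr.run").members
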