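"""Shared fixtures.  All test data is generated programmatically; the
session-scoped documents are treated as immutable (perturbations go
through the injectors, which clone)."""

import pytest

from contsem import (
    InterrupterSpec,
    StateAtom,
    build_childbirth,
    build_contraction_run,
    build_tooth_eruption,
    inject_delay,
    inject_interruption,
)


@pytest.fixture(scope="session")
def childbirth():
    """Canonical childbirth (phases 5+3+1) and its signature."""
    return build_childbirth((5, 3, 1))


@pytest.fixture(scope="session")
def contraction_run():
    """Three uterine contractions (phases 1+1+2 each) and their signature."""
    return build_contraction_run(3, (1, 1, 2))


@pytest.fixture(scope="session")
def tooth_eruption():
    return build_tooth_eruption()


@pytest.fixture(scope="session")
def childbirth_with_contractions():
    """Childbirth with a two-contraction run nested in the dilation phase."""
    return build_childbirth((5, 3, 1), contractions=2)


@pytest.fixture(scope="session")
def delayed_childbirth(childbirth):
    doc, _ = childbirth
    return inject_delay(doc, "dilation", 2)


@pytest.fixture(scope="session")
def interrupted_run(contraction_run):
    """Oxytocin drop after the first contraction, restored after 4 units."""
    doc, _ = contraction_run
    drop = InterrupterSpec(
        id="oxy_drop", label="oxytocin drop and recovery",
        initial_atoms=frozenset({StateAtom(
            "maternal_blood", "oxytocin_concentration", "insufficient")}))
    return inject_interruption(doc, "ctr.run.c1", 4, drop)
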