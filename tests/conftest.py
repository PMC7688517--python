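import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from tcrep import (
    Clonotype,
    CohortConfig,
    Group,
    Repertoire,
    RepertoireSet,
    generate_cohort,
)


@pytest.fixture
def toy_repertoire() -> Repertoire:
    """Five functional clones with distinct counts."""
    return Repertoire(
        "m1",
        [
            Clonotype("CASGETGTNERLFF", 80),
            Clonotype("CASSLGQAYEQYF", 10),
            Clonotype("CASSDRGNTLYF", 6),
            Clonotype("CAWSVGQGGYEQYF", 3),
            Clonotype("CASSPGTGGYEQYF", 1),
        ],
        group=Group.RESPONDER,
    )


@pytest.fixture
def two_group_cohort() -> RepertoireSet:
    """Hand-built 5-animal cohort with known sharing structure."""

    def rep(animal, group, counts):
        return Repertoire(
            animal,
            [Clonotype(c, n) for c, n in counts.items()],
            group=group,
        )

    shared_rr = "CASSRRSHAREDF"  # responders 1 & 2
    shared_mix = "CASSMWSHAREDF"  # responder 1, non-responder 1
    shared_nn = "CASSNNSHAREDF"  # non-responders 1 & 2
    reps = {
        "r1": rep("r1", Group.RESPONDER, {shared_rr: 5, shared_mix: 2, "CASSAAAAF": 9}),
        "r2": rep("r2", Group.RESPONDER, {shared_rr: 3, "CASSGGGGF": 7}),
        "r3": rep("r3", Group.RESPONDER, {"CASSCCCCF": 4}),
        "n1": rep("n1", Group.NON_RESPONDER, {shared_mix: 6, shared_nn: 1, "CASSDDDDF": 2}),
        "n2": rep("n2", Group.NON_RESPONDER, {shared_nn: 8, "CASSEEEEF": 3}),
    }
    return RepertoireSet(reps, tracked_clones=["CASGETGTNERLFF"])


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced-size simulated cohort for fast mechanical tests."""
    return generate_cohort(
        CohortConfig(seed=20240917, background_richness=300, depth=20_000)
    )
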