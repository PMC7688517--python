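"""Core domain types for TCRβ repertoire analysis.

A *clonotype* (TCRβ clone) is defined by its CDR3 amino-acid sequence;
abundance is a UMI-deduplicated count. A *repertoire* is the set of
clonotypes observed in one animal, and a *repertoire set* is the cohort:
repertoires keyed by animal, with response-group assignments, the list of
tracked (spiked-in) clones, and optional matched flow-cytometry
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Mapping, Optional, Sequence

__all__ = [
    "AA20",
    "CDR3_ALPHABET",
    "STOP_CHAR",
    "FRAMESHIFT_CHAR",
    "DEFAULT_TRACKED_CDR3",
    "ValidationError",
    "FormatError",
    "Group",
    "Compartment",
    "Clonotype",
    "Repertoire",
    "RepertoireSet",
    "validate_cdr3",
]

#: The 20 standard amino acids, single-letter code.
AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

STOP_CHAR = "*"
FRAMESHIFT_CHAR = "_"

#: Valid clone-key characters: amino acids plus stop / frameshift markers
#: (markers only survive until the functionality filter).
CDR3_ALPHABET = AA20 | {STOP_CHAR, FRAMESHIFT_CHAR}

#: CDR3 of the adoptively transferred, hemagglutinin-specific CL4 clone.
DEFAULT_TRACKED_CDR3 = "CASGETGTNERLFF"


class ValidationError(ValueError):
    """Raised when data violate a domain invariant."""


class FormatError(ValueError):
    """Raised when an input file does not match the expected format."""


class Group(str, Enum):
    """Response-group label of one animal after checkpoint therapy."""

    RESPONDER = "responder"
    NON_RESPONDER = "non_responder"
    UNASSIGNED = "unassigned"


class Compartment(str, Enum):
    TUMOR = "tumor"
    DLN = "dln"
    SPLEEN = "spleen"
    OTHER = "other"


def validate_cdr3(cdr3_aa: str) -> str:
    """Check that a clone key is non-empty and within the CDR3 alphabet.

    Unknown characters fail loudly; nothing is silently dropped.
    """
    if not isinstance(cdr3_aa, str) or not cdr3_aa:
        raise ValidationError("cdr3_aa must be a non-empty string")
    bad = set(cdr3_aa) - CDR3_ALPHABET
    if bad:
        raise ValidationError(
            f"cdr3_aa {cdr3_aa!r} contains invalid characters {sorted(bad)!r}; "
            f"allowed: 20 amino-acid letters plus '*' (stop) and '_' (frameshift)"
        )
    return cdr3_aa


@dataclass(frozen=True)
class Clonotype:
    """One unique CDR3 amino-acid sequence with its abundance in one animal."""

    cdr3_aa: str
    count: int
    v_gene: Optional[str] = None
    j_gene: Optional[str] = None

    def __post_init__(self) -> None:
        validate_cdr3(self.cdr3_aa)
        if not isinstance(self.count, int) or isinstance(self.count, bool):
            raise ValidationError(
                f"count for {self.cdr3_aa!r} must be an integer, got {self.count!r}"
            )
        if self.count < 1:
            raise ValidationError(
                f"count for {self.cdr3_aa!r} must be >= 1, got {self.count}"
            )


@dataclass
class Repertoire:
    """All clonotypes for one animal, plus metadata.

    CDR3 keys are unique within a repertoire (aggregation of duplicate rows
    happens in :mod:`tcrep.io`); ``total_count`` is always the sum of
    clonotype counts.
    """

    animal_id: str
    clonotypes: list[Clonotype]
    group: Group = Group.UNASSIGNED
    compartment: Compartment = Compartment.OTHER

    def __post_init__(self) -> None:
        if not self.animal_id:
            raise ValidationError("animal_id must be non-empty")
        keys = [c.cdr3_aa for c in self.clonotypes]
        if len(keys) != len(set(keys)):
            seen: set[str] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValidationError(
                f"repertoire {self.animal_id!r} has duplicate cdr3_aa {dup!r}"
            )

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    @property
    def richness(self) -> int:
        """Number of unique clones."""
        return len(self.clonotypes)

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self) -> Iterator[Clonotype]:
        return iter(self.clonotypes)

    def __contains__(self, cdr3_aa: str) -> bool:
        return any(c.cdr3_aa == cdr3_aa for c in self.clonotypes)

    def counts(self) -> dict[str, int]:
        return {c.cdr3_aa: c.count for c in self.clonotypes}

    def with_clonotypes(self, clonotypes: Sequence[Clonotype]) -> "Repertoire":
        return replace(self, clonotypes=list(clonotypes))


@dataclass
class RepertoireSet:
    """The cohort: repertoires keyed by animal id.

    ``tracked_clones`` lists CDR3s of spiked-in clones whose frequency is
    followed across animals (by default the transferred CL4 clone).
    ``flow_frequencies`` optionally carries a matched flow-cytometry
    frequency (fraction in [0, 1]) per animal.
    """

    repertoires: dict[str, Repertoire]
    tracked_clones: list[str] = field(
        default_factory=lambda: [DEFAULT_TRACKED_CDR3]
    )
    flow_frequencies: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        for animal_id, rep in self.repertoires.items():
            if rep.animal_id != animal_id:
                raise ValidationError(
                    f"repertoire keyed {animal_id!r} has animal_id {rep.animal_id!r}"
                )
        for cdr3 in self.tracked_clones:
            validate_cdr3(cdr3)
        if self.flow_frequencies is not None:
            for animal_id, f in self.flow_frequencies.items():
                if animal_id not in self.repertoires:
                    raise ValidationError(
                        f"flow frequency for unknown animal {animal_id!r}"
                    )
                if not 0.0 <= float(f) <= 1.0:
                    raise ValidationError(
                        f"flow frequency for {animal_id!r} outside [0, 1]: {f}"
                    )

    @property
    def animal_ids(self) -> list[str]:
        return list(self.repertoires)

    def __len__(self) -> int:
        return len(self.repertoires)

    def __iter__(self) -> Iterator[Repertoire]:
        return iter(self.repertoires.values())

    def __getitem__(self, animal_id: str) -> Repertoire:
        return self.repertoires[animal_id]

    def by_group(self, group: Group) -> list[Repertoire]:
        return [r for r in self if r.group == group]

    def grouped(self) -> "RepertoireSet":
        """Restrict to animals with an assigned response group."""
        reps = {
            aid: r
            for aid, r in self.repertoires.items()
            if r.group != Group.UNASSIGNED
        }
        flow = (
            {a: f for a, f in self.flow_frequencies.items() if a in reps}
            if self.flow_frequencies is not None
            else None
        )
        return RepertoireSet(reps, list(self.tracked_clones), flow)

    def group_counts(self) -> Mapping[Group, int]:
        out: dict[Group, int] = {g: 0 for g in Group}
        for rep in self:
            out[rep.group] += 1
        return out
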