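"""Functionality filter and per-clone frequency computation.

A clone is *non-functional* — and excluded from all downstream analysis —
if its CDR3 is shorter than 8 or longer than 20 amino acids, contains a
stop codon (``*``) or a frameshift (``_``). Length bounds are inclusive:
8- and 20-residue clones are retained. Each removed clone is assigned to
exactly one removal category, checked in the order frameshift, stop,
short, long.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .repertoire import (
    FRAMESHIFT_CHAR,
    STOP_CHAR,
    Repertoire,
    RepertoireSet,
    ValidationError,
)

__all__ = [
    "FilterReport",
    "filter_functional",
    "filter_set",
    "clone_frequencies",
    "top_n_clones",
    "clone_order",
]

MIN_CDR3_LENGTH = 8
MAX_CDR3_LENGTH = 20


@dataclass(frozen=True)
class FilterReport:
    """Accounting of one repertoire's pass through the functionality filter.

    Categories are mutually exclusive and exhaustive:
    ``n_input == n_retained + n_removed_frameshift + n_removed_stop +
    n_removed_short + n_removed_long``.
    """

    animal_id: str
    n_input: int
    n_retained: int
    n_removed_short: int
    n_removed_long: int
    n_removed_stop: int
    n_removed_frameshift: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_short
            + self.n_removed_long
            + self.n_removed_stop
            + self.n_removed_frameshift
        )
        if self.n_input != self.n_retained + removed:
            raise ValidationError(
                f"filter report for {self.animal_id!r} does not balance: "
                f"{self.n_input} != {self.n_retained} + {removed}"
            )

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def filter_functional(
    rep: Repertoire,
    min_length: int = MIN_CDR3_LENGTH,
    max_length: int = MAX_CDR3_LENGTH,
    stop_char: str = STOP_CHAR,
    frameshift_char: str = FRAMESHIFT_CHAR,
) -> tuple[Repertoire, FilterReport]:
    """Remove non-functional clones; counts of retained clones are unchanged.

    An all-removed repertoire is returned empty, with a complete report.
    Idempotent: filtering a filtered repertoire changes nothing.
    """
    retained = []
    n_frameshift = n_stop = n_short = n_long = 0
    for clone in rep:
        if frameshift_char in clone.cdr3_aa:
            n_frameshift += 1
        elif stop_char in clone.cdr3_aa:
            n_stop += 1
        elif len(clone.cdr3_aa) < min_length:
            n_short += 1
        elif len(clone.cdr3_aa) > max_length:
            n_long += 1
        else:
            retained.append(clone)
    report = FilterReport(
        animal_id=rep.animal_id,
        n_input=len(rep),
        n_retained=len(retained),
        n_removed_short=n_short,
        n_removed_long=n_long,
        n_removed_stop=n_stop,
        n_removed_frameshift=n_frameshift,
    )
    return rep.with_clonotypes(retained), report


def filter_set(
    rset: RepertoireSet, **kwargs
) -> tuple[RepertoireSet, dict[str, FilterReport]]:
    """Apply the functionality filter to every repertoire in a cohort."""
    filtered: dict[str, Repertoire] = {}
    reports: dict[str, FilterReport] = {}
    for animal_id, rep in rset.repertoires.items():
        filtered[animal_id], reports[animal_id] = filter_functional(rep, **kwargs)
    return (
        RepertoireSet(
            filtered,
            list(rset.tracked_clones),
            dict(rset.flow_frequencies) if rset.flow_frequencies else None,
        ),
        reports,
    )


def clone_frequencies(rep: Repertoire) -> dict[str, float]:
    """Clone frequencies (count / total count) of a filtered repertoire.

    Frequencies sum to 1 up to floating-point rounding.
    """
    total = rep.total_count
    if total <= 0:
        raise ValidationError(
            f"cannot compute frequencies of empty repertoire {rep.animal_id!r}"
        )
    return {c.cdr3_aa: c.count / total for c in rep}


def clone_order(rep: Repertoire) -> list[str]:
    """Deterministic abundance order: count descending, then CDR3 ascending."""
    return [
        c.cdr3_aa
        for c in sorted(rep.clonotypes, key=lambda c: (-c.count, c.cdr3_aa))
    ]


def top_n_clones(rep: Repertoire, n: int) -> list[tuple[str, float]]:
    """The up-to-``n`` most abundant clones with their frequencies.

    Sorted by count descending; ties broken by lexicographic CDR3 order so
    the result is reproducible. Returns fewer than ``n`` entries when the
    repertoire is smaller.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    freqs = clone_frequencies(rep)
    return [(cdr3, freqs[cdr3]) for cdr3 in clone_order(rep)[:n]]
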