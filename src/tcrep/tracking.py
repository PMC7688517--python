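"""Tracked-clone quantification across a cohort.

The experiment spikes a known antigen-specific clone (CL4, CDR3
``CASGETGTNERLFF``) into every animal; these functions measure its
frequency and rank per repertoire, relate it to matched flow-cytometry
frequencies, and summarize each animal's top-clone composition.
Tracked-clone matching is exact string equality on the CDR3 key.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import pandas as pd
from scipy import stats

from .filtering import clone_frequencies, clone_order, filter_functional
from .repertoire import (
    Clonotype,
    Group,
    Repertoire,
    RepertoireSet,
    ValidationError,
    validate_cdr3,
)

__all__ = [
    "TrackedCloneResult",
    "FlowCorrelation",
    "track_clone",
    "tracked_frequency_table",
    "correlate_with_flow",
    "composition_table",
]


@dataclass(frozen=True)
class TrackedCloneResult:
    """Frequency and rank of one tracked clone in one animal.

    ``rank`` is the clone's position in the deterministic abundance order
    (count desc, CDR3 asc); it is absent exactly when the clone is absent,
    in which case the frequency is 0.
    """

    animal_id: str
    group: Group
    tracked_frequency: float
    rank: Optional[int]
    is_most_frequent: bool

    def __post_init__(self) -> None:
        if (self.tracked_frequency == 0.0) != (self.rank is None):
            raise ValidationError(
                f"{self.animal_id!r}: rank must be absent iff frequency is 0"
            )
        if self.is_most_frequent != (self.rank == 1):
            raise ValidationError(
                f"{self.animal_id!r}: is_most_frequent must mirror rank == 1"
            )


def _track_in_repertoire(rep: Repertoire, cdr3: str) -> TrackedCloneResult:
    counts = rep.counts()
    if cdr3 not in counts or counts[cdr3] == 0:
        return TrackedCloneResult(rep.animal_id, rep.group, 0.0, None, False)
    freq = clone_frequencies(rep)[cdr3]
    rank = clone_order(rep).index(cdr3) + 1
    return TrackedCloneResult(rep.animal_id, rep.group, freq, rank, rank == 1)


def track_clone(rset: RepertoireSet, cdr3: str) -> list[TrackedCloneResult]:
    """Frequency and rank of the tracked clone in every animal.

    Repertoires are assumed already filtered. If the tracked CDR3 would
    itself fail the functionality filter a warning is raised (tracking an
    absent clone is still well defined), not an error.
    """
    validate_cdr3(cdr3)
    probe = Repertoire("_probe", [Clonotype(cdr3, 1)])
    kept, _ = filter_functional(probe)
    if len(kept) == 0:
        warnings.warn(
            f"tracked clone {cdr3!r} would itself be removed by the "
            f"functionality filter",
            stacklevel=2,
        )
    return [_track_in_repertoire(rep, cdr3) for rep in rset]


def tracked_frequency_table(
    rset: RepertoireSet, cdr3: str | None = None
) -> pd.DataFrame:
    """Per-animal tracked-clone table as a DataFrame (frequencies in [0,1])."""
    if cdr3 is None:
        if not rset.tracked_clones:
            raise ValidationError("no tracked clones configured")
        cdr3 = rset.tracked_clones[0]
    results = track_clone(rset, cdr3)
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in results],
            "group": [r.group.value for r in results],
            "cdr3_aa": cdr3,
            "tracked_frequency": [r.tracked_frequency for r in results],
            "rank": [r.rank for r in results],
            "is_most_frequent": [r.is_most_frequent for r in results],
        }
    )


class FlowCorrelation(NamedTuple):
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def correlate_with_flow(
    results: list[TrackedCloneResult], flow: dict[str, float]
) -> FlowCorrelation:
    """Pearson correlation and OLS fit of sequencing vs flow frequency.

    Pairs (flow, tracked_frequency) are formed for animals present in
    both inputs; both variables are fractions in [0, 1]. The p-value is
    the two-sided t-transform of r with n − 2 degrees of freedom.
    """
    pairs = [
        (flow[r.animal_id], r.tracked_frequency)
        for r in results
        if r.animal_id in flow
    ]
    if len(pairs) < 3:
        raise ValidationError(
            f"need >= 3 animals with both measurements, got {len(pairs)}"
        )
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValidationError(
            "correlation undefined: zero variance in one of the variables"
        )
    fit = stats.linregress(x, y)
    return FlowCorrelation(
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(pairs),
    )


def composition_table(rset: RepertoireSet, n: int = 10) -> pd.DataFrame:
    """Top-``n`` clone composition per animal, plus the aggregate remainder.

    One row per animal per occupied rank 1..n (columns: rank, cdr3_aa,
    frequency, is_tracked) and one ``other`` row carrying the remaining
    frequency mass, so per-animal frequencies sum to 1.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    tracked = set(rset.tracked_clones)
    rows = []
    for rep in rset:
        freqs = clone_frequencies(rep)
        order = clone_order(rep)[:n]
        top_mass = 0.0
        for rank, cdr3 in enumerate(order, start=1):
            top_mass += freqs[cdr3]
            rows.append(
                {
                    "animal_id": rep.animal_id,
                    "group": rep.group.value,
                    "rank": rank,
                    "cdr3_aa": cdr3,
                    "frequency": freqs[cdr3],
                    "is_tracked": cdr3 in tracked,
                }
            )
        rows.append(
            {
                "animal_id": rep.animal_id,
                "group": rep.group.value,
                "rank": 0,
                "cdr3_aa": "other",
                "frequency": max(0.0, 1.0 - top_mass),
                "is_tracked": False,
            }
        )
    return pd.DataFrame(rows)
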