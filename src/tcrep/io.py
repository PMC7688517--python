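"""Readers and writers for clonotype tables and cohort sample sheets.

Two tab-separated dialects are supported:

* ``airr`` — AIRR Rearrangement style: the clone key is ``junction_aa``
  and the abundance ``duplicate_count`` (optional ``v_call``/``j_call``).
  The junction string is used directly as the clone key; this is a naming
  convention, not a claim that junction and CDR3 coincide.
* ``simple`` — minimal clonotype table: ``cdr3_aa`` and ``count``
  (optional ``v_gene``/``j_gene``).

Counts are taken at face value as UMI-deduplicated abundances; no
deduplication is performed here. Rows sharing a clone key are summed.
Lines starting with ``#`` are provenance headers and are skipped.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Union

import pandas as pd

from .repertoire import (
    DEFAULT_TRACKED_CDR3,
    Clonotype,
    Compartment,
    FormatError,
    Group,
    Repertoire,
    RepertoireSet,
    ValidationError,
)

__all__ = [
    "DIALECT_COLUMNS",
    "read_clonotype_table",
    "write_clonotype_table",
    "read_sample_sheet",
    "apply_sample_sheet",
    "load_cohort",
]

PathLike = Union[str, Path]

#: dialect -> (clone-key column, count column, v column, j column)
DIALECT_COLUMNS = {
    "airr": ("junction_aa", "duplicate_count", "v_call", "j_call"),
    "simple": ("cdr3_aa", "count", "v_gene", "j_gene"),
}


def _dialect_columns(dialect: str) -> tuple[str, str, str, str]:
    try:
        return DIALECT_COLUMNS[dialect]
    except KeyError:
        raise FormatError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECT_COLUMNS)}"
        ) from None


def read_clonotype_table(
    path: PathLike, dialect: str = "simple", animal_id: str | None = None
) -> Repertoire:
    """Read one animal's clonotype table into a validated repertoire.

    Rows with the same clone key are aggregated by summing counts (the
    first V/J annotation is kept). Group and compartment are left
    unassigned until a sample sheet is applied. ``animal_id`` defaults to
    the file stem.
    """
    path = Path(path)
    key_col, count_col, v_col, j_col = _dialect_columns(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in (key_col, count_col):
        if col not in df.columns:
            raise FormatError(
                f"{path.name}: missing required column {col!r} for dialect {dialect!r}"
            )
    if len(df) == 0:
        raise ValidationError(f"{path.name}: clonotype table is empty")

    counts: dict[str, int] = {}
    vj: dict[str, tuple[str | None, str | None]] = {}
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        raw = getattr(row, count_col)
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path.name} row {row_number}: count {raw!r} is not a number"
            ) from None
        if not math.isfinite(value) or value != int(value):
            raise ValidationError(
                f"{path.name} row {row_number}: count {raw!r} is not an integer"
            )
        count = int(value)
        if count < 1:
            raise ValidationError(
                f"{path.name} row {row_number}: count must be >= 1, got {count}"
            )
        cdr3 = getattr(row, key_col)
        counts[cdr3] = counts.get(cdr3, 0) + count
        if cdr3 not in vj:
            v = getattr(row, v_col, None)
            j = getattr(row, j_col, None)
            vj[cdr3] = (
                None if v is None or (isinstance(v, float) and math.isnan(v)) else v,
                None if j is None or (isinstance(j, float) and math.isnan(j)) else j,
            )

    clonotypes = [
        Clonotype(cdr3, count, vj[cdr3][0], vj[cdr3][1])
        for cdr3, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return Repertoire(animal_id or path.stem, clonotypes)


def write_clonotype_table(
    rep: Repertoire, path: PathLike, dialect: str = "simple"
) -> None:
    """Write a repertoire as a TSV clonotype table.

    Guarantees a round trip: reading the written file reproduces the
    clonotype multiset. Refuses to write an empty repertoire.
    """
    if len(rep) == 0:
        raise ValidationError(
            f"refusing to write empty repertoire {rep.animal_id!r}"
        )
    key_col, count_col, v_col, j_col = _dialect_columns(dialect)
    rows = [
        {
            key_col: c.cdr3_aa,
            count_col: c.count,
            v_col: c.v_gene or "",
            j_col: c.j_gene or "",
        }
        for c in sorted(rep.clonotypes, key=lambda c: (-c.count, c.cdr3_aa))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    """Read a cohort sample sheet (animal_id, group, compartment, flow_frequency)."""
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str}, comment="#")
    if "animal_id" not in df.columns or "group" not in df.columns:
        raise FormatError("sample sheet requires columns 'animal_id' and 'group'")
    return df


def apply_sample_sheet(rset: RepertoireSet, sheet: pd.DataFrame) -> RepertoireSet:
    """Attach group / compartment / flow-frequency annotations from a sample sheet.

    Every sheet row must match a loaded repertoire; unknown group strings
    and flow frequencies outside [0, 1] are rejected. An absent or
    all-empty ``flow_frequency`` column leaves ``flow_frequencies`` unset,
    and correlation analyses will then refuse to run.
    """
    repertoires = dict(rset.repertoires)
    flow: dict[str, float] = {}
    for row_number, row in enumerate(sheet.itertuples(index=False), start=2):
        animal_id = str(row.animal_id)
        if animal_id not in repertoires:
            raise ValidationError(
                f"sample sheet row {row_number}: no repertoire loaded for "
                f"animal {animal_id!r}"
            )
        try:
            group = Group(str(row.group))
        except ValueError:
            raise ValidationError(
                f"sample sheet row {row_number}: unknown group {row.group!r}; "
                f"expected one of {[g.value for g in Group]}"
            ) from None
        compartment = Compartment.OTHER
        raw_comp = getattr(row, "compartment", None)
        if raw_comp is not None and not (
            isinstance(raw_comp, float) and math.isnan(raw_comp)
        ):
            try:
                compartment = Compartment(str(raw_comp))
            except ValueError:
                raise ValidationError(
                    f"sample sheet row {row_number}: unknown compartment "
                    f"{raw_comp!r}"
                ) from None
        rep = repertoires[animal_id]
        repertoires[animal_id] = Repertoire(
            rep.animal_id, rep.clonotypes, group=group, compartment=compartment
        )
        raw_flow = getattr(row, "flow_frequency", None)
        if raw_flow is not None and not (
            isinstance(raw_flow, float) and math.isnan(raw_flow)
        ):
            value = float(raw_flow)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"sample sheet row {row_number}: flow_frequency {value} "
                    f"outside [0, 1]"
                )
            flow[animal_id] = value
    return RepertoireSet(
        repertoires, list(rset.tracked_clones), flow or None
    )


def load_cohort(
    table_paths: dict[str, PathLike] | list[PathLike],
    sample_sheet: PathLike | None = None,
    dialect: str = "simple",
    tracked_clones: list[str] | None = None,
) -> RepertoireSet:
    """Load a cohort from per-animal clonotype tables plus a sample sheet."""
    if isinstance(table_paths, dict):
        items = [(aid, Path(p)) for aid, p in table_paths.items()]
    else:
        items = [(Path(p).stem, Path(p)) for p in table_paths]
    repertoires = {
        aid: read_clonotype_table(p, dialect=dialect, animal_id=aid)
        for aid, p in items
    }
    tracked = (
        list(tracked_clones) if tracked_clones is not None else [DEFAULT_TRACKED_CDR3]
    )
    rset = RepertoireSet(repertoires, tracked)
    if sample_sheet is not None:
        rset = apply_sample_sheet(rset, read_sample_sheet(sample_sheet))
    return rset
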