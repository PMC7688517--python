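#!/usr/bin/env python
"""Apply the functionality filter to the simulated cohort.

Reads the clonotype tables written by 01_simulate_cohort.py, removes
non-functional clones (length outside 8-20 aa, stop codon, frameshift)
and writes the per-animal filter report. The generator only emits
functional CDR3s, so the report doubles as a pipeline sanity check:
nothing should be removed.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from tcrep import filter_set, load_cohort

COHORT_DIR = Path("scratch/cohort")
RESULTS = Path("results")


def load():
    tables = sorted(
        p for p in COHORT_DIR.glob("*.tsv") if p.name != "sample_sheet.tsv"
    )
    return load_cohort(tables, sample_sheet=COHORT_DIR / "sample_sheet.tsv")


def main() -> None:
    rset = load()
    filtered, reports = filter_set(rset)
    df = pd.DataFrame([dataclasses.asdict(r) for r in reports.values()])
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "filter_report.tsv", sep="\t", index=False)
    n_removed = int(df.n_input.sum() - df.n_retained.sum())
    print(df.to_string(index=False))
    print(
        f"\n{df.n_input.sum()} input clones across {len(df)} animals, "
        f"{n_removed} removed -> results/filter_report.tsv"
    )


if __name__ == "__main__":
    main()
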