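#!/usr/bin/env python
"""Quantify the tracked CL4 clone and relate it to flow cytometry.

Per animal: the tracked clone's repertoire frequency and rank, the
top-10 clone composition, and the Pearson correlation / OLS fit between
sequencing frequency and the matched flow frequency.
"""

import importlib
import json
import sys
from pathlib import Path

from tcrep import (
    composition_table,
    correlate_with_flow,
    filter_set,
    track_clone,
    tracked_frequency_table,
)

sys.path.insert(0, str(Path(__file__).parent))
load = importlib.import_module("02_filter_clones").load

RESULTS = Path("results")


def main() -> None:
    filtered, _ = filter_set(load())
    RESULTS.mkdir(exist_ok=True)
    tracked_cdr3 = filtered.tracked_clones[0]

    table = tracked_frequency_table(filtered)
    table.to_csv(RESULTS / "tracked_clone.tsv", sep="\t", index=False)

    comp = composition_table(filtered, 10)
    comp.to_csv(RESULTS / "composition_top10.tsv", sep="\t", index=False)

    results = track_clone(filtered, tracked_cdr3)
    corr = correlate_with_flow(results, filtered.flow_frequencies)
    (RESULTS / "flow_correlation.json").write_text(
        json.dumps(corr._asdict(), indent=2) + "\n"
    )

    n_top = sum(r.is_most_frequent for r in results)
    print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print(
        f"\ntracked clone {tracked_cdr3} is the most frequent clone in "
        f"{n_top}/{len(results)} animals"
    )
    print(
        f"flow vs sequencing: r = {corr.pearson_r:.3f} "
        f"(p = {corr.p_value:.2e}), slope {corr.slope:.3f}, "
        f"intercept {corr.intercept:.3f}, n = {corr.n}"
    )
    print(
        "-> results/tracked_clone.tsv, results/composition_top10.tsv, "
        "results/flow_correlation.json"
    )


if __name__ == "__main__":
    main()
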