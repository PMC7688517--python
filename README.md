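# tcrep

TCRβ repertoire analysis for cohort studies that track a known
antigen-specific T-cell clone — e.g. an adoptively transferred,
tumor-antigen-specific clone followed through checkpoint therapy in
responding and non-responding animals.

Given per-animal clonotype tables (one row per unique CDR3 amino-acid
sequence with a UMI-deduplicated count) and a sample sheet assigning each
animal a response group, `tcrep` provides:

- **Functionality filtering** — clones with CDR3 length outside 8–20 aa,
  a stop codon (`*`) or a frameshift (`_`) are excluded, with an exact
  accounting report.
- **Diversity profiling** — Rényi entropy H_α = (1/(1−α)) ln Σ pᵢ^α over
  an α grid (α = 0: log richness; α → 1: Shannon; α = 2: log Simpson;
  α → ∞: dominance), plus the normalized Shannon index (Pielou evenness
  H₁/ln S ∈ [0, 1]).
- **Tracked-clone quantification** — frequency and rank of the spiked
  clone per animal, and Pearson/OLS agreement with matched
  flow-cytometry frequencies.
- **Sharing analysis** — clones public to ≥ 2 animals, classed by
  response group, with a sharing-degree histogram.
- **CDR3 similarity networks** — nodes are each animal's top-50 clones,
  edges connect sequences at Levenshtein distance 1; components are
  screened for group exclusivity.
- **Group statistics** — two-sided Mann-Whitney U (exact or
  normal-approximate) between responders and non-responders.
- **Synthetic cohorts** — a seeded generator that reproduces the study's
  statistical structure (8 vs 5 animals; tracked-clone frequencies from
  truncated normals at 0.805 ± 0.161 and 0.269 ± 0.355; heavy-tailed
  private backgrounds; injected public clones; noisy matched flow
  frequencies) with a complete ground-truth ledger.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
from tcrep import (
    CohortConfig, generate_cohort, filter_set, track_clone,
    compare_tracked_frequency, compare_diversity, correlate_with_flow,
)

cohort = generate_cohort(CohortConfig(seed=42))
rset, _ = filter_set(cohort.repertoire_set)

results = track_clone(rset, "CASGETGTNERLFF")
print(sum(r.is_most_frequent for r in results), "of", len(results))

corr = correlate_with_flow(results, rset.flow_frequencies)
print(f"r = {corr.pearson_r:.3f}")

for cmp in (compare_tracked_frequency(rset), compare_diversity(rset, alpha=1.0)):
    (ma, mb), (sa, sb) = cmp.group_means, cmp.group_sds
    print(f"{cmp.metric_name}: R {ma:.2f} +/- {sa:.2f} vs NR {mb:.2f} +/- {sb:.2f}; "
          f"U = {cmp.u_statistic:.0f}, p = {cmp.p_value:.4f} ({cmp.method})")
```

prints

```
11 of 13
r = 0.979
tracked_frequency_pct[CASGETGTNERLFF]: R 73.78 +/- 12.46 vs NR 39.12 +/- 15.15; U = 39, p = 0.0031 (exact)
renyi_entropy[alpha=1.0]: R 1.32 +/- 0.50 vs NR 2.45 +/- 0.40; U = 1, p = 0.0031 (exact)
```

The tracked clone dominates 11 of 13 repertoires; its sequencing
frequency tracks the flow measurement closely; responders carry it at a
far higher frequency (74% vs 39% here) and have correspondingly less
diverse repertoires (lower Shannon entropy), both significant at p ≈
0.003 by the exact two-sided Mann-Whitney test.

The same analysis, step by step with tables written under `results/`, is
in the numbered scripts:

```bash
python analysis/01_simulate_cohort.py   # cohort -> scratch/cohort/
python analysis/02_filter_clones.py     # filter report
python analysis/03_diversity_profiles.py
python analysis/04_tracked_clone.py     # tracked freq, flow correlation
python analysis/05_sharing_and_network.py
python analysis/06_group_comparisons.py
```

A `tcrep` console command mirrors these stages (`tcrep simulate`,
`tcrep filter`, `tcrep diversity`, `tcrep track`, `tcrep compare`,
`tcrep overlap`, `tcrep network`, `tcrep run-all`), and
`tcrep.run_all(RunConfig(...))` executes the whole pipeline into one
deterministic output directory.

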