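# Methods

`tcrep` analyzes bulk TCRβ clonotype tables from cohorts in which a known
antigen-specific T-cell clone was adoptively transferred into every animal
before tumor challenge and checkpoint therapy. A clone is identified by its
CDR3 amino-acid sequence; abundance is a UMI-deduplicated count, taken at
face value by the readers (no deduplication or alignment is attempted —
those belong to upstream read-processing pipelines).

## Clone definition and functionality filter

Clones with CDR3 length outside 8–20 amino acids, or containing a stop
codon (`*`) or frameshift marker (`_`), are non-functional and excluded
from every downstream analysis. Both length bounds are **inclusive**: the
filter removes strictly-shorter-than-8 and strictly-longer-than-20
sequences. Each removed clone lands in exactly one report category,
assigned in the order frameshift → stop → short → long; the categories
plus retained clones always sum to the input. The `*`/`_` conventions are
configurable because clonotype tables differ in how they mark
out-of-frame junctions. Whether the bounds should apply to the
IMGT-defined CDR3 or the anchor-inclusive junction is left to the caller:
the filter applies them to the clone key string exactly as read.

## Diversity

Repertoire diversity is profiled with the Rényi entropy

```
H_α(p) = 1/(1−α) · ln Σᵢ pᵢ^α ,   α ≥ 0,
```

with the analytic limits substituted where the closed form is singular:
H₀ = ln S (log richness), H₁ = −Σ pᵢ ln pᵢ (Shannon), H_∞ = −ln max pᵢ.
H₂ = −ln Σ pᵢ² is the log Simpson diversity. All entropies are in nats;
`hill_number` exponentiates to effective clone counts. The default α grid
is {0, 0.25, 0.5, 1, 2, 4, 8, 16, 32, 64, ∞}. Sums are accumulated in log
space (`logsumexp`) so large α cannot underflow; zero frequencies are
impossible by construction (counts ≥ 1) and are rejected if supplied
directly. Profiles are non-increasing in α (Schur concavity), which the
tests exercise as an invariant.

The normalized Shannon index is Pielou evenness, H₁/ln S, with the
convention that a monoclonal repertoire (S = 1) scores 0. A formula that
circulates for this index, `1 − H₁/n`, contradicts its own stated range
semantics (it would score a monoclonal sample 1, not 0); this package
follows the semantics — 0 for entirely monoclonal, 1 when every unique
clone is equally abundant — not that typography.

Diversity is computed on the post-filter repertoires at their observed
depths. No rarefaction or depth standardization is applied; cohorts with
strongly unequal depths should be interpreted with that in mind (the
synthetic cohorts use equal depths, so the comparison there is clean).

## Tracked-clone quantification

Tracked-clone matching is exact string equality on the CDR3 key — the
transferred clone is identified by a single known sequence
(`CASGETGTNERLFF` by default), so fuzzy matching would only admit false
positives. Rank uses the same deterministic order as top-N selection:
count descending, ties broken by lexicographic CDR3. The flow-cytometry
relationship is an ordinary least-squares fit of sequencing frequency on
flow frequency (both as fractions in [0, 1]), with the Pearson r p-value
from the two-sided t transform on n − 2 degrees of freedom. Group
contrasts use the Mann-Whitney test, not the regression.

## Sharing and similarity networks

A clone is *shared* when the identical CDR3 occurs in ≥ 2 animals with
assigned response groups; rows are classed responders-only /
non-responders-only / mixed. The tracked clone is excluded from sharing
by default — it is public by experimental construction — but included in
the similarity network by default, where it legitimately ranks among the
top clones. Both behaviours are flags.

The network takes the union of each animal's top-N (default 50) most
abundant clones as nodes and connects pairs at Levenshtein distance
exactly 1 (unit-cost substitution, insertion or deletion; "single amino
acid difference" is read as full edit distance, so indels count). Edge
discovery is an exhaustive O(V²) scan with a length-difference ≤ 1
pre-filter; at cohort scale (≤ ~650 nodes) this takes well under a
second and needs no indexing structure. Node attributes (`n_animals`,
`group_presence`) are counted over animals' full filtered repertoires,
not just their top lists. "Forming a network" means degree ≥ 1;
group-exclusive components require size ≥ 2 with every node present in
only one group.

## Group statistics

Two-sided Mann-Whitney U throughout. `auto` mode uses the exact
permutation distribution when n_a·n_b ≤ 400 and the pooled sample is
tie-free, otherwise the normal approximation with tie and continuity
corrections (backed by `scipy.stats.mannwhitneyu`; the test suite
cross-checks the exact branch against full enumeration of rank
assignments for all shapes with n_a + n_b ≤ 10). Group summaries are
mean ± sample SD; tracked-clone frequencies are reported on the
percentage scale. No multiple-testing correction is applied by default —
the analyses here make two planned comparisons — but a Benjamini-Hochberg
helper exists for callers running many metrics.

## Synthetic cohorts

The generator reproduces the *statistical* structure of the study
cohort; it makes no attempt at mechanistic T-cell or tumor dynamics.
Defaults:

| parameter | default | rationale |
|---|---|---|
| group sizes | 8 responders, 5 non-responders | the study design |
| tracked frequency, responders | Normal(0.805, 0.161) truncated to [0,1] | reported group mean ± SD |
| tracked frequency, non-responders | Normal(0.269, 0.355) truncated to [0,1] | reported group mean ± SD; truncation is mandatory at this SD |
| background richness | 2,000 clones/animal | assumption; the study reports no repertoire sizes |
| background abundances | Zipf, exponent 1.5 | heavy-tailed backgrounds: non-tracked top-10 clones span a few % to ~quarter of a repertoire |
| public clones | 6, sharing degree 2, absolute frequency 0.002 each | minimal sharing, degree 2–3, each well under 1% of a repertoire |
| depth | 100,000 UMIs/animal | assumption, typical bulk TCRβ yield |
| flow noise SD | 0.05 | measurement disagreement between flow and sequencing frequency |

Per animal, the true tracked frequency is drawn from the group's
truncated normal; the remaining mass is split between injected public
clones (capped at half the residual so an extreme tracked draw cannot
exhaust it) and the power-law background over freshly drawn private CDR3s
(`C` + uniform interior + `F`, lengths 8–20, so every generated clone
passes the functionality filter). Counts are one multinomial draw at the
configured depth; the matched flow frequency is the true tracked
frequency plus clipped Gaussian noise. Public clones are injected
explicitly into a fixed set of animals rather than emerging from a shared
pool, so sharing recovery has exact ground truth. The truth ledger
records every generating quantity, and `recovery_report` scores estimates
against it, including the attenuation-implied flow correlation
r = σ_true/√(σ_true² + σ_noise²).

What the generator does **not** emulate: V/J gene usage, sequence
similarity clusters among background clones (random CDR3s are almost
never within edit distance 1, so simulated networks are near-edgeless —
network mechanics are therefore tested on constructed sequence sets),
sequencing error, unequal depths, and any correlation between diversity
and response beyond what the tracked clone's expansion induces. Passing
tests demonstrate the pipeline's correctness and recovery of generating
parameters, not biological claims about real repertoires.

## Numerical and reproducibility choices

- Frequency vectors must sum to 1 within 1e-9; entropy inputs must be
  strictly positive.
- Top-N and rank tie-breaks are count-desc, then lexicographic CDR3 —
  determinism is required for reproducible tables.
- All randomness flows from one mandatory integer seed through
  `numpy.random.default_rng`; a cohort regenerated with the same
  configuration is byte-identical on disk, and `run_all` reruns reproduce
  identical analysis tables.
- Pipeline outputs carry a provenance header line (`# tcrep v… |
  stage=…`); readers skip `#` comment lines.
- The recovery study in the acceptance suite uses 500 simulated cohorts
  at the default configuration and compares replicate-averaged group
  means against the analytic truncated-normal expectations within five
  Monte-Carlo standard errors; test power at α = 0.05 is reported
  alongside.

## Known limitations

- No rarefaction; richness and entropy at α near 0 are depth-sensitive.
- Exact Mann-Whitney is delegated to SciPy's implementation (enumeration
  cross-checked in tests); very large tie-heavy samples always use the
  approximation.
- The AIRR reader treats `junction_aa` as the clone key without trimming
  anchors; mixing dialects across a cohort will mis-align clone keys if
  one table stores junctions and another trimmed CDR3s.
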