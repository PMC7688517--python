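"""Group statistics: Mann-Whitney U comparisons between responders and
non-responders, applied to tracked-clone frequency and repertoire
diversity.

Tests are two-sided throughout. ``auto`` mode uses the exact permutation
null when the sample sizes are small (n_a x n_b <= 400) and the data are
tie-free, and the normal approximation with tie and continuity
corrections otherwise. No multiple-testing correction is applied by
default; a Benjamini-Hochberg helper is provided for callers comparing
many metrics at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .diversity import renyi_entropy
from .filtering import clone_frequencies
from .repertoire import Group, RepertoireSet, ValidationError

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "compare_tracked_frequency",
    "compare_diversity",
    "benjamini_hochberg",
]

EXACT_MAX_PRODUCT = 400


@dataclass(frozen=True)
class GroupComparison:
    """A two-group Mann-Whitney comparison of one metric.

    ``u_statistic`` is the U of group a (within [0, n_a x n_b]); the
    two-sided p-value is invariant under swapping the groups. Group
    means and SDs (sample SD) are reported on the same scale as the
    values.
    """

    metric_name: str
    group_a_values: tuple[float, ...]
    group_b_values: tuple[float, ...]
    u_statistic: float
    p_value: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    method: str

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "metric": self.metric_name,
                "n_a": len(self.group_a_values),
                "n_b": len(self.group_b_values),
                "u_statistic": self.u_statistic,
                "p_value": self.p_value,
                "mean_a": self.group_means[0],
                "mean_b": self.group_means[1],
                "sd_a": self.group_sds[0],
                "sd_b": self.group_sds[1],
                "method": self.method,
            },
            **kwargs,
        )


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
    metric_name: str = "metric",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two samples.

    ``mode`` is one of ``exact`` (permutation null), ``normal_approx``
    (large-sample approximation with tie correction and continuity
    correction) or ``auto`` (exact when n_a x n_b <= 400 and the pooled
    sample is tie-free, otherwise the approximation).
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size == 0 or bv.size == 0:
        raise ValidationError("both groups must be non-empty")
    if mode not in {"exact", "normal_approx", "auto"}:
        raise ValidationError(f"unknown mode {mode!r}")
    has_ties = len(np.unique(np.concatenate([av, bv]))) < av.size + bv.size
    if mode == "auto":
        mode = (
            "exact"
            if av.size * bv.size <= EXACT_MAX_PRODUCT and not has_ties
            else "normal_approx"
        )
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(
        av, bv, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(
        metric_name=metric_name,
        group_a_values=tuple(av.tolist()),
        group_b_values=tuple(bv.tolist()),
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_means=(_mean_sd(av)[0], _mean_sd(bv)[0]),
        group_sds=(_mean_sd(av)[1], _mean_sd(bv)[1]),
        method=method,
    )


def _group_values(rset: RepertoireSet) -> tuple[list, list]:
    resp = rset.by_group(Group.RESPONDER)
    nonresp = rset.by_group(Group.NON_RESPONDER)
    if not resp or not nonresp:
        raise ValidationError(
            f"need animals in both groups (responders: {len(resp)}, "
            f"non-responders: {len(nonresp)})"
        )
    return resp, nonresp


def compare_tracked_frequency(
    rset: RepertoireSet, cdr3: str | None = None, mode: str = "auto"
) -> GroupComparison:
    """Responder vs non-responder comparison of tracked-clone frequency.

    Values are reported on the percentage scale (group mean ± SD in %),
    the convention for spike-in frequencies.
    """
    from .tracking import track_clone  # late import avoids a module cycle

    if cdr3 is None:
        if not rset.tracked_clones:
            raise ValidationError("no tracked clones configured")
        cdr3 = rset.tracked_clones[0]
    resp, nonresp = _group_values(rset)
    results = {r.animal_id: r for r in track_clone(rset, cdr3)}
    a = [100.0 * results[r.animal_id].tracked_frequency for r in resp]
    b = [100.0 * results[r.animal_id].tracked_frequency for r in nonresp]
    return mann_whitney(a, b, mode=mode, metric_name=f"tracked_frequency_pct[{cdr3}]")


def compare_diversity(
    rset: RepertoireSet, alpha: float = 1.0, mode: str = "auto"
) -> GroupComparison:
    """Responder vs non-responder comparison of Rényi entropy at order α.

    Defaults to α = 1 (Shannon entropy); α = 0 compares ln richness.
    """
    resp, nonresp = _group_values(rset)

    def entropy(rep) -> float:
        return renyi_entropy(list(clone_frequencies(rep).values()), alpha)

    a = [entropy(r) for r in resp]
    b = [entropy(r) for r in nonresp]
    return mann_whitney(a, b, mode=mode, metric_name=f"renyi_entropy[alpha={alpha}]")


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    return list(sps.false_discovery_control(p_values, method="bh"))
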