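"""Rényi entropy profiles and normalized Shannon diversity.

Repertoire diversity is profiled with the Rényi entropy

    H_α = 1/(1−α) · ln Σᵢ pᵢ^α

evaluated over a grid of orders α. α = 0 gives ln(richness), α → 1 the
Shannon entropy −Σ p ln p, α = 2 the (log) Simpson diversity −ln Σ p²,
and α → ∞ the dominance term −ln max(p). Increasing α weights abundant
clones more heavily, so a profile that drops steeply between α = 0 and 1
indicates a repertoire dominated by few expanded clones.

All entropies are in nats (natural log); exponentiating gives Hill
numbers, the "effective number of clones" at each order.

The normalized Shannon index (Pielou evenness) is H₁ / ln(richness),
ranging from 0 for an entirely monoclonal repertoire to 1 when every
unique clone occurs equally often (e.g. exactly once each).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .filtering import clone_frequencies
from .repertoire import Repertoire, RepertoireSet, ValidationError

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "DiversityProfile",
    "renyi_entropy",
    "renyi_profile",
    "shannon_evenness",
    "hill_number",
    "diversity_summary",
    "profiles_frame",
]

#: Default grid of Rényi orders, matching common repertoire-profiling practice.
DEFAULT_ALPHA_GRID: tuple[float, ...] = (
    0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, math.inf,
)

_SUM_TOL = 1e-9


def _validated_freqs(freqs: Iterable[float]) -> np.ndarray:
    p = np.asarray(list(freqs) if not isinstance(freqs, np.ndarray) else freqs,
                   dtype=float)
    if p.size == 0:
        raise ValidationError("frequency vector is empty")
    if np.any(p <= 0):
        raise ValidationError(
            "frequencies must be strictly positive (drop zero-frequency clones)"
        )
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValidationError(
            f"frequencies must sum to 1 within {_SUM_TOL}, got {p.sum()!r}"
        )
    return p


def renyi_entropy(freqs: Iterable[float], alpha: float) -> float:
    """Rényi entropy of order ``alpha`` of a frequency vector, in nats.

    α = 1 and α = ∞ are evaluated as their analytic limits (Shannon
    entropy and −ln max p), never by plugging into the generic formula.
    Intermediate sums use log-space accumulation so large α does not
    underflow.
    """
    p = _validated_freqs(freqs)
    if alpha < 0:
        raise ValidationError(f"alpha must be >= 0, got {alpha}")
    if alpha == 0:
        return float(np.log(p.size))
    if alpha == 1:
        return float(-np.sum(p * np.log(p)))
    if math.isinf(alpha):
        return float(-np.log(p.max()))
    return float(logsumexp(alpha * np.log(p)) / (1.0 - alpha))


def hill_number(freqs: Iterable[float], alpha: float) -> float:
    """Effective number of clones at order ``alpha``: exp(H_α)."""
    return float(math.exp(renyi_entropy(freqs, alpha)))


@dataclass(frozen=True)
class DiversityProfile:
    """Rényi entropy of one repertoire over a grid of orders.

    Entropies are non-increasing along increasing α; the α = 0 value is
    ln(richness).
    """

    animal_id: str
    alphas: tuple[float, ...]
    entropies: tuple[float, ...]
    richness: int
    shannon_evenness: float

    def __post_init__(self) -> None:
        if len(self.alphas) != len(self.entropies):
            raise ValidationError("alphas and entropies differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "alpha": list(self.alphas),
                "entropy": list(self.entropies),
            }
        )


def _rep_freqs(rep: Repertoire) -> np.ndarray:
    if len(rep) == 0:
        raise ValidationError(
            f"cannot profile empty repertoire {rep.animal_id!r}"
        )
    return np.fromiter(clone_frequencies(rep).values(), dtype=float, count=len(rep))


def renyi_profile(
    rep: Repertoire, alphas: Sequence[float] = DEFAULT_ALPHA_GRID
) -> DiversityProfile:
    """Evaluate the Rényi entropy of a filtered repertoire on an α grid."""
    p = _rep_freqs(rep)
    alphas = tuple(sorted(float(a) for a in alphas))
    entropies = tuple(renyi_entropy(p, a) for a in alphas)
    return DiversityProfile(
        animal_id=rep.animal_id,
        alphas=alphas,
        entropies=entropies,
        richness=len(rep),
        shannon_evenness=shannon_evenness(rep),
    )


def shannon_evenness(rep: Repertoire) -> float:
    """Normalized Shannon index (Pielou evenness) of a filtered repertoire.

    Returns (−Σ p ln p) / ln(N) with N the number of unique clones; by
    convention 0 for a monoclonal repertoire (N = 1), where no evenness
    is defined.
    """
    p = _rep_freqs(rep)
    if p.size == 1:
        return 0.0
    return float(-np.sum(p * np.log(p)) / np.log(p.size))


def diversity_summary(rset: RepertoireSet) -> pd.DataFrame:
    """Per-animal summary: richness, Shannon, Simpson (log), evenness."""
    rows = []
    for rep in rset:
        p = _rep_freqs(rep)
        rows.append(
            {
                "animal_id": rep.animal_id,
                "group": rep.group.value,
                "richness": len(rep),
                "shannon": renyi_entropy(p, 1.0),
                "simpson": renyi_entropy(p, 2.0),
                "evenness": shannon_evenness(rep),
            }
        )
    return pd.DataFrame(rows)


def profiles_frame(
    rset: RepertoireSet, alphas: Sequence[float] = DEFAULT_ALPHA_GRID
) -> pd.DataFrame:
    """Long-format table (animal_id, alpha, entropy) for a whole cohort."""
    return pd.concat(
        [renyi_profile(rep, alphas).to_frame() for rep in rset],
        ignore_index=True,
    )
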