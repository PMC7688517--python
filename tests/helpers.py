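"""Independent oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the edit distance is
a plain quadratic dynamic program, the Mann-Whitney p-value a full
enumeration over rank assignments, and the set-intersection sharing
oracle a brute-force pairwise scan.
"""

from __future__ import annotations

import itertools
import math
import random


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook O(len(a)·len(b)) edit distance with unit costs."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(
                    prev[j] + 1,
                    cur[j - 1] + 1,
                    prev[j - 1] + (ca != cb),
                )
            )
        prev = cur
    return prev[-1]


def enumerated_mannwhitney_p(a: list[float], b: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments.

    Assumes no ties. The null distribution of U is symmetric about
    n_a·n_b/2, so the two-sided p is the fraction of assignments at least
    as far from the center as the observed U.
    """
    n_a, n_b = len(a), len(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    center = n_a * n_b / 2.0
    dev = abs(u_obs - center)
    pooled = sorted(a + b)
    total = 0
    extreme = 0
    for a_idx in itertools.combinations(range(n_a + n_b), n_a):
        a_set = set(a_idx)
        u = sum(
            1
            for i in a_idx
            for j in range(n_a + n_b)
            if j not in a_set and pooled[i] > pooled[j]
        )
        total += 1
        if abs(u - center) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def brute_force_shared(counts_by_animal: dict[str, dict[str, int]]) -> dict[str, set[str]]:
    """cdr3 -> animals containing it, for clones in >= 2 animals."""
    presence: dict[str, set[str]] = {}
    for animal, counts in counts_by_animal.items():
        for cdr3 in counts:
            presence.setdefault(cdr3, set()).add(animal)
    return {c: a for c, a in presence.items() if len(a) >= 2}


def random_cdr3_string(rng: random.Random, lo: int = 8, hi: int = 20) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    length = rng.randint(lo, hi)
    return "C" + "".join(rng.choice(aas) for _ in range(length - 2)) + "F"


def random_frequency_vector(rng: random.Random, n: int) -> list[float]:
    raw = [rng.random() + 1e-9 for _ in range(n)]
    total = sum(raw)
    return [x / total for x in raw]


def shannon(p: list[float]) -> float:
    return -sum(x * math.log(x) for x in p)
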