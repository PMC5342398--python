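"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity from its definition (exact arithmetic,
exhaustive enumeration, or position-by-position summation) through a code
path entirely separate from the package implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_tail_exact(m: int, t: int, n: int, r: int) -> Fraction:
    """P(X >= r) for X ~ Hypergeom(m, t, n) by exact integer arithmetic."""
    num = sum(comb(t, x) * comb(m - t, n - x) for x in range(r, min(n, t) + 1))
    return Fraction(num, comb(m, n))


def hypergeom_tail_by_draws(m: int, t: int, n: int, r: int) -> Fraction:
    """Same tail probability by enumerating every possible draw of size n."""
    pathway = set(range(t))
    hits = sum(
        1
        for draw in itertools.combinations(range(m), n)
        if len(pathway & set(draw)) >= r
    )
    return Fraction(hits, comb(m, n))


def ks_profile_oracle(
    ranked_ids: list[str],
    ranked_scores: np.ndarray,
    members: set[str],
    q: float,
) -> tuple[list[float], float]:
    """Running sum and signed extremum, recomputed from scratch at each position."""
    n = len(ranked_ids)
    n_r = sum(
        abs(s) ** q for i, s in zip(ranked_ids, ranked_scores) if i in members
    )
    n_miss = sum(1 for i in ranked_ids if i not in members)
    assert n_r > 0 and n_miss > 0
    running = []
    for k in range(1, n + 1):
        fhit = (
            sum(
                abs(s) ** q
                for i, s in zip(ranked_ids[:k], ranked_scores[:k])
                if i in members
            )
            / n_r
        )
        fmiss = sum(1 for i in ranked_ids[:k] if i not in members) / n_miss
        running.append(fhit - fmiss)
    extremum = max(running, key=abs)
    return running, extremum


def unweighted_ks_oracle(
    ranked_ids: list[str], members: set[str]
) -> float:
    """Classic KS statistic: every hit steps up by 1/|members|."""
    n_hit = sum(1 for i in ranked_ids if i in members)
    n_miss = len(ranked_ids) - n_hit
    running = 0.0
    best = 0.0
    for i in ranked_ids:
        running += 1.0 / n_hit if i in members else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def bh_oracle(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up from its definition (cumulative minimum)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        adjusted[i] = prev
    return adjusted
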