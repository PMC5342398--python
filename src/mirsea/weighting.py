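"""Hypergeometric miRNA-pathway weighting and pathway conversion.

A miRNA regulates a pathway through the genes it targets.  The strength of
the association between miRNA *i* and pathway *j* is scored by the
upper-tail hypergeometric probability of their overlap:

    p_ij = P(X >= r_ij),   X ~ Hypergeometric(m, t_j, n_i)
    W_ij = 1 - p_ij

where ``m`` is the universe size, ``t_j`` the pathway's gene count, ``n_i``
the miRNA's target count and ``r_ij`` the observed overlap, all counted
within the universe.  ``W_ij`` is 0 exactly when the miRNA targets none of
the pathway's genes, and approaches 1 as the overlap becomes more surprising.

A gene pathway is *converted* into a miRNA pathway by keeping every miRNA
with W > 0; converted pathways outside a configurable size band are dropped
to avoid overly narrow or broad categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GeneSetCollection, GeneUniverse, TargetMap

__all__ = [
    "WeightMatrix",
    "ConvertedPathway",
    "hypergeom_upper_tail",
    "compute_weight_matrix",
    "convert_pathways",
]


def hypergeom_upper_tail(m: int, t: int, n: int, r) -> float | np.ndarray:
    """Upper-tail hypergeometric probability P(X >= r).

    X counts pathway genes in a draw of ``n`` from a universe of ``m`` genes
    of which ``t`` belong to the pathway.  Computed through the
    survival-function form ``sf(r - 1)``, which is numerically safe for
    extreme tails.  ``r`` may be a scalar or an array.
    """
    r_arr = np.asarray(r)
    if m < 0 or t < 0 or n < 0:
        raise ValueError("m, t and n must be non-negative")
    if t > m:
        raise ValueError(f"t={t} exceeds universe size m={m}")
    if n > m:
        raise ValueError(f"n={n} exceeds universe size m={m}")
    if np.any(r_arr < 0) or np.any(r_arr > np.minimum(n, t)):
        raise ValueError(f"r={r} outside [0, min(n, t)] = [0, {min(n, t)}]")
    p = stats.hypergeom.sf(r_arr - 1, m, t, n)
    p = np.minimum(p, 1.0)
    return float(p) if np.isscalar(r) or r_arr.ndim == 0 else p


@dataclass
class WeightMatrix:
    """Dense miRNA x pathway weight matrix with the underlying overlaps.

    ``weights[i, j] = 1 - p_hyper[i, j]``; ``overlaps[i, j] = r_ij``.
    """

    mirna_ids: list[str]
    pathway_ids: list[str]
    weights: np.ndarray
    p_hyper: np.ndarray
    overlaps: np.ndarray

    def __post_init__(self) -> None:
        self._row = {m: i for i, m in enumerate(self.mirna_ids)}
        self._col = {p: j for j, p in enumerate(self.pathway_ids)}
        shape = (len(self.mirna_ids), len(self.pathway_ids))
        for name in ("weights", "p_hyper", "overlaps"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, expected {shape}")

    def weight(self, mirna: str, pathway: str) -> float:
        return float(self.weights[self._row[mirna], self._col[pathway]])

    def column(self, pathway: str) -> dict[str, float]:
        j = self._col[pathway]
        return {m: float(self.weights[i, j]) for m, i in self._row.items()}


@dataclass
class ConvertedPathway:
    """A gene pathway re-expressed as its positively weighted miRNAs."""

    pathway_id: str
    members: dict[str, float]

    def __post_init__(self) -> None:
        bad = [m for m, w in self.members.items() if not (0.0 < w <= 1.0)]
        if bad:
            raise ValueError(f"{self.pathway_id}: member weights must be in (0, 1]: {bad}")

    @property
    def size(self) -> int:
        return len(self.members)


def compute_weight_matrix(
    targets: TargetMap,
    pathways: GeneSetCollection,
    universe: GeneUniverse,
) -> WeightMatrix:
    """Score every (miRNA, pathway) pair by the hypergeometric weight.

    Target sets and pathway gene sets are restricted to the universe first,
    so m, t, n and r are mutually consistent.  miRNAs whose targets fall
    entirely outside the universe get weight 0 everywhere (warned).
    """
    mirna_ids = sorted(targets.entries)
    pathway_ids = pathways.ids
    m = universe.m

    restricted_targets = {mi: universe.restrict(targets.entries[mi]) for mi in mirna_ids}
    orphans = [mi for mi in mirna_ids if not restricted_targets[mi]]
    if orphans:
        warnings.warn(
            f"{len(orphans)} miRNAs have no targets inside the universe; "
            "their pathway weights are all zero"
        )

    n_by_mirna = np.array([len(restricted_targets[mi]) for mi in mirna_ids])
    shape = (len(mirna_ids), len(pathway_ids))
    overlaps = np.zeros(shape, dtype=int)
    p_hyper = np.ones(shape, dtype=float)

    for j, pid in enumerate(pathway_ids):
        genes = universe.restrict(pathways.genes(pid))
        t = len(genes)
        if t == 0:
            continue
        r_col = np.array(
            [len(restricted_targets[mi] & genes) for mi in mirna_ids], dtype=int
        )
        overlaps[:, j] = r_col
        # one vectorized sf call per (pathway, distinct n) group
        for n in np.unique(n_by_mirna):
            rows = n_by_mirna == n
            if n == 0:
                continue
            p_hyper[rows, j] = stats.hypergeom.sf(r_col[rows] - 1, m, t, int(n))

    p_hyper = np.clip(p_hyper, 0.0, 1.0)
    weights = 1.0 - p_hyper
    weights[overlaps == 0] = 0.0
    return WeightMatrix(
        mirna_ids=mirna_ids,
        pathway_ids=pathway_ids,
        weights=weights,
        p_hyper=p_hyper,
        overlaps=overlaps,
    )


def convert_pathways(
    W: WeightMatrix,
    min_size: int = 10,
    max_size: int = 200,
    measured: set[str] | None = None,
    *,
    filter_before_intersection: bool = False,
) -> list[ConvertedPathway]:
    """Turn the weight matrix into size-filtered miRNA pathways.

    Membership is W > 0.  If ``measured`` is given, members are intersected
    with the measured miRNAs before the size filter (set
    ``filter_before_intersection`` to apply the filter to the full converted
    pathway instead).  Bounds are inclusive: ``min_size <= size <= max_size``.
    Input pathway order is preserved.
    """
    if min_size >= max_size:
        raise ValueError(f"min_size={min_size} must be < max_size={max_size}")
    out: list[ConvertedPathway] = []
    for pid in W.pathway_ids:
        j = W._col[pid]
        members = {
            m: float(W.weights[i, j]) for m, i in W._row.items() if W.weights[i, j] > 0.0
        }
        if filter_before_intersection and not (min_size <= len(members) <= max_size):
            continue
        if measured is not None:
            members = {m: w for m, w in members.items() if m in measured}
        if not filter_before_intersection and not (min_size <= len(members) <= max_size):
            continue
        if not members:
            continue
        out.append(ConvertedPathway(pathway_id=pid, members=members))
    if not out:
        warnings.warn("no pathway survived the size filter")
    return out
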