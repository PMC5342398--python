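"""Weighted Kolmogorov-Smirnov running-sum enrichment score.

Walking down the ranked miRNA list, the running statistic increases by the
normalised score magnitude at every pathway member and decreases by a
uniform step at every non-member:

    F_hit(k)  = sum_{members with rank <= k} |r_l|^q / N_R,
                N_R = sum_{members} |r_l|^q
    F_miss(k) = #(non-members with rank <= k) / N_miss

The enrichment score miRES is the value of F_hit - F_miss with the largest
absolute magnitude (signed); with q = 0 it reduces to the classic
unweighted KS statistic, and with q = 1 it is the GSEA weighted form.  The
core miRNAs — the leading-edge analogue — are the members at or before the
peak for a positive score, or at or after it for a negative score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import RankedMiRList
from .weighting import ConvertedPathway

__all__ = [
    "EnrichmentProfile",
    "CoreMiRSet",
    "running_enrichment",
    "extract_core_mirnas",
    "batch_enrichment_scores",
]


@dataclass
class EnrichmentProfile:
    """Running-sum trace and its signed extremum for one pathway."""

    pathway_id: str
    running: np.ndarray
    mires: float
    peak_position: int  # 1-based rank at which the extremum is attained
    q: float
    n_r: float
    n_miss: int


@dataclass
class CoreMiRSet:
    """Pathway members inside the leading edge of the running sum."""

    pathway_id: str
    mirna_ids: list[str]
    ranks: list[int]


def _orientation(scores: np.ndarray, mirna_ids: list[str]) -> float:
    """Sign statistic deciding the canonical walk direction.

    Summing the scores in miRNA-id order — an order shared by a ranked
    list and its label-swapped mirror — guarantees the statistic of the
    mirror is the bit-exact negation of the original, so both runs reduce
    to the same canonical computation.
    """
    id_order = np.argsort(np.asarray(mirna_ids), kind="stable")
    return float(np.sum(scores[id_order]))


def running_enrichment(
    ranked: RankedMiRList,
    pathway: ConvertedPathway,
    q: float = 1.0,
) -> EnrichmentProfile:
    """Compute the running sum F_hit - F_miss and the enrichment score.

    Pathway members absent from the ranked list are ignored (not measured).
    The peak is the earliest position attaining the maximal |running| value
    (evaluated in the canonical orientation, so that swapping the class
    labels negates the score exactly).
    """
    if q < 0:
        raise ValueError("exponent q must be >= 0")
    member = np.array([m in pathway.members for m in ranked.mirna_ids])
    n_hit = int(member.sum())
    if n_hit == 0:
        raise ValueError(f"{pathway.pathway_id}: no pathway member in the ranked list")
    n = len(ranked)
    n_miss = n - n_hit
    if n_miss == 0:
        raise ValueError(f"{pathway.pathway_id}: degenerate pathway (every miRNA is a member)")

    # canonicalise the orientation: a label swap reverses the ranked list and
    # negates every score; computing the mirrored instance on the same float
    # path and flipping the sign back makes the antisymmetry bit-exact
    mirrored = _orientation(ranked.scores, ranked.mirna_ids) < 0.0
    scores_c = -ranked.scores[::-1] if mirrored else ranked.scores
    member_c = member[::-1] if mirrored else member

    weighted = np.abs(scores_c) ** q
    # zero-padded reduction: the same summation grouping the batch scorer
    # uses, so scalar and vectorised paths agree bit-for-bit
    n_r = float(np.where(member_c, weighted, 0.0).sum())
    if n_r == 0.0:
        raise ValueError(f"{pathway.pathway_id}: all member scores are zero (N_R = 0)")

    step = np.where(member_c, weighted / n_r, -1.0 / n_miss)
    running_c = np.cumsum(step)

    if mirrored:
        # original position k corresponds to canonical position n-k (whose
        # own final value is the exact zero); ties at the peak magnitude
        # resolve to the earliest ORIGINAL position = last canonical one
        cc = np.concatenate(([0.0], np.abs(running_c[:-1])))
        j_star = (n - 1) - int(np.argmax(cc[::-1]))
        mires = -float(running_c[j_star - 1]) if j_star > 0 else 0.0
        peak_position = n - j_star
        running = -np.concatenate(([0.0], running_c[:-1]))[::-1]
    else:
        peak_c = int(np.argmax(np.abs(running_c)))  # earliest maximum
        mires = float(running_c[peak_c])
        peak_position = peak_c + 1
        running = running_c
    return EnrichmentProfile(
        pathway_id=pathway.pathway_id,
        running=running,
        mires=mires,
        peak_position=peak_position,
        q=q,
        n_r=n_r,
        n_miss=n_miss,
    )


def extract_core_mirnas(
    profile: EnrichmentProfile,
    ranked: RankedMiRList,
    pathway: ConvertedPathway,
) -> CoreMiRSet:
    """Members at/before the peak (positive score) or at/after it (negative).

    A zero enrichment score — possible only for degenerate constant data —
    yields an empty core by convention.
    """
    if profile.mires > 0:
        keep = lambda k: k <= profile.peak_position
    elif profile.mires < 0:
        keep = lambda k: k >= profile.peak_position
    else:
        return CoreMiRSet(pathway_id=pathway.pathway_id, mirna_ids=[], ranks=[])
    ids: list[int] = []
    ranks: list[int] = []
    for k, m in enumerate(ranked.mirna_ids, start=1):
        if m in pathway.members and keep(k):
            ids.append(m)
            ranks.append(k)
    return CoreMiRSet(pathway_id=pathway.pathway_id, mirna_ids=ids, ranks=ranks)


def batch_enrichment_scores(
    scores: np.ndarray,
    member_mask: np.ndarray,
    q: float,
    id_rank: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised miRES over many pathways sharing one miRNA panel.

    ``scores`` is pathways x miRNAs (each row that pathway's miRScores) and
    ``member_mask`` the matching boolean membership matrix.  Columns must be
    arranged so that equal scores resolve ties by ascending miRNA id, i.e.
    in id-ascending order unless ``id_rank`` supplies an explicit tie key.
    Rows are canonicalised by the sign of their column-order score sum, so
    negating every score (a class-label swap) negates each miRES bit-exactly.
    Returns (miRES, 1-based peak position) per pathway.  Rows where N_R = 0
    or the membership is degenerate come back as NaN.
    """
    scores = np.asarray(scores, dtype=float)
    member_mask = np.asarray(member_mask, dtype=bool)
    n_path, n_mir = scores.shape
    if id_rank is not None:
        # reorder columns so a stable sort breaks ties by id
        col_order = np.argsort(id_rank, kind="stable")
        scores = scores[:, col_order]
        member_mask = member_mask[:, col_order]

    flip = scores.sum(axis=1) < 0.0
    if flip.any():
        scores = scores.copy()
        member_mask = member_mask.copy()
        scores[flip] = -scores[flip, ::-1]
        member_mask[flip] = member_mask[flip, ::-1]

    order = np.argsort(-scores, axis=1, kind="stable")
    mask_sorted = np.take_along_axis(member_mask, order, axis=1)
    weighted = np.abs(np.take_along_axis(scores, order, axis=1)) ** q

    n_hit = mask_sorted.sum(axis=1)
    n_miss = n_mir - n_hit
    n_r = np.where(mask_sorted, weighted, 0.0).sum(axis=1)

    valid = (n_hit > 0) & (n_miss > 0) & (n_r > 0)
    safe_nr = np.where(valid, n_r, 1.0)
    safe_miss = np.where(n_miss > 0, n_miss, 1)
    step = np.where(
        mask_sorted, weighted / safe_nr[:, None], -1.0 / safe_miss[:, None]
    )
    running = np.cumsum(step, axis=1)
    magnitude = np.abs(running)
    rows = np.arange(n_path)

    # forward orientation: earliest peak position
    peak_fwd = np.argmax(magnitude, axis=1)
    mires_fwd = running[rows, peak_fwd]

    # mirrored rows: original position k maps to canonical position n-k
    # (canonical endpoint excluded — the view's own final value is the
    # exact zero); earliest original = last canonical argmax
    cc = np.concatenate([np.zeros((n_path, 1)), magnitude[:, :-1]], axis=1)
    j_star = (n_mir - 1) - np.argmax(cc[:, ::-1], axis=1)
    mires_rev = np.where(
        j_star > 0, -running[rows, np.maximum(j_star - 1, 0)], 0.0
    )

    mires = np.where(flip, mires_rev, mires_fwd)
    mires = np.where(valid, mires, np.nan)
    peak_pos = np.where(flip, n_mir - j_star, peak_fwd + 1)
    return mires, peak_pos
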