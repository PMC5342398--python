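"""Per-miRNA differential expression and pathway-specific ranking.

The default differential-expression metric is the signal-to-noise ratio
between the two phenotype classes,

    DE_i = (mean_A - mean_B) / (sd_A + sd_B),

with an optional GSEA-style floor on each class standard deviation.  For a
given pathway the ranking score combines differential expression with the
miRNA-pathway weight:

    miRScore_i = (1 + W_i) * DE_i,

so a miRNA strongly tied to the pathway (W near 1) has its statistic boosted
by up to a factor of two while the sign — the direction of regulation — is
never changed.  miRNAs are ranked by decreasing miRScore to form the list
the enrichment walk runs over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io import ExpressionDataset

__all__ = ["RankedMiRList", "signal_to_noise", "mir_score", "rank_mirnas"]

# GSEA's adjusted signal-to-noise constants
DEFAULT_FLOOR_FRAC = 0.2
DEFAULT_ABS_FLOOR = 1e-8


def signal_to_noise(
    dataset: ExpressionDataset,
    *,
    sd_floor: bool = False,
    floor_frac: float = DEFAULT_FLOOR_FRAC,
    abs_floor: float = DEFAULT_ABS_FLOOR,
) -> dict[str, float]:
    """Signal-to-noise ratio per miRNA; positive means higher in class A.

    Standard deviations are sample (ddof=1) per class.  With ``sd_floor``
    each class sd is raised to ``max(sd, floor_frac * |class mean|,
    abs_floor)``, the adjustment GSEA applies to stabilise low-variance
    rows.  Without the floor, a row whose two class sds sum to zero is an
    error (the ratio is undefined).
    """
    mask_a, mask_b = dataset.class_masks
    a = dataset.values[:, mask_a]
    b = dataset.values[:, mask_b]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a, sd_b = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    if sd_floor:
        sd_a = np.maximum(np.maximum(sd_a, floor_frac * np.abs(mean_a)), abs_floor)
        sd_b = np.maximum(np.maximum(sd_b, floor_frac * np.abs(mean_b)), abs_floor)
    denom = sd_a + sd_b
    if np.any(denom == 0.0):
        rows = [dataset.mirna_ids[i] for i in np.flatnonzero(denom == 0.0)]
        raise ValueError(
            f"zero variance in both classes for {rows}; enable sd_floor to proceed"
        )
    de = (mean_a - mean_b) / denom
    return dict(zip(dataset.mirna_ids, de.tolist()))


def mir_score(de: Mapping[str, float], weights: Mapping[str, float]) -> dict[str, float]:
    """Weight-boosted ranking score (1 + W_i) * DE_i for one pathway.

    miRNAs absent from ``weights`` get W = 0, so their score is their DE
    value unchanged.
    """
    out: dict[str, float] = {}
    for mirna, d in de.items():
        w = weights.get(mirna, 0.0)
        if not (0.0 <= w <= 1.0):
            raise ValueError(f"weight for {mirna!r} outside [0, 1]: {w}")
        out[mirna] = (1.0 + w) * d
    return out


@dataclass
class RankedMiRList:
    """miRNAs ordered by decreasing score; rank positions are 1-based."""

    mirna_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.mirna_ids) != len(self.scores):
            raise ValueError("ids and scores length mismatch")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")
        self._rank = {m: k + 1 for k, m in enumerate(self.mirna_ids)}

    def __len__(self) -> int:
        return len(self.mirna_ids)

    def rank(self, mirna: str) -> int:
        return self._rank[mirna]


def rank_mirnas(scores: Mapping[str, float]) -> RankedMiRList:
    """Order miRNAs by score descending, ties broken by id ascending."""
    arr = np.array([float(v) for v in scores.values()])
    if not np.all(np.isfinite(arr)):
        bad = [m for m, v in scores.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite scores for {bad}")
    ids = np.array(list(scores.keys()))
    id_order = np.argsort(ids, kind="stable")
    # stable sort on -score over id-ascending input => ties resolve by id
    order = id_order[np.argsort(-arr[id_order], kind="stable")]
    return RankedMiRList(mirna_ids=ids[order].tolist(), scores=arr[order])
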