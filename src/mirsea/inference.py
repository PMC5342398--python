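"""Phenotype-permutation significance, FDR control and score normalisation.

The null distribution of each pathway's enrichment score is built by
redistributing the phenotype labels across samples — which preserves the
miRNA-miRNA correlation structure — and recomputing the entire pipeline
(signal-to-noise, miRScore, ranking, miRES) for every relabelling.  The
empirical p-value is p = M/N, with M the number of permuted scores beyond
the observed one on its own side.  P-values are adjusted by
Benjamini-Hochberg, by default separately within the positive-score
(down-regulated) and negative-score (up-regulated) pathway groups.  The
normalised score NmiRES divides the observed miRES by the mean magnitude of
same-sign permuted scores, making pathways of different sizes comparable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .enrichment import (
    CoreMiRSet,
    batch_enrichment_scores,
    extract_core_mirnas,
    running_enrichment,
)
from .io import ExpressionDataset, GeneSetCollection, TargetMap, build_universe
from .scoring import mir_score, rank_mirnas, signal_to_noise
from .weighting import ConvertedPathway, compute_weight_matrix, convert_pathways

__all__ = [
    "MirseaConfig",
    "PathwayResult",
    "permute_labels",
    "empirical_pvalue",
    "bh_fdr",
    "normalize_es",
    "run_mirsea",
]

logger = logging.getLogger("mirsea")


@dataclass
class MirseaConfig:
    """Run-level settings for the full pipeline.

    ``q`` is the score-weighting exponent of the KS walk (1 by default;
    0 gives the unweighted statistic).  ``fdr_mode`` is ``"signed"`` —
    BH applied separately to positive- and negative-score pathways — or
    ``"pooled"``.  ``p_denominator`` selects the empirical p-value
    background (see :func:`empirical_pvalue`); ``smooth_pvalues`` switches
    M/N to (M+1)/(N+1).
    """

    q: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    min_size: int = 10
    max_size: int = 200
    universe_mode: str = "union"
    fixed_m: int | None = None
    sd_floor: bool = False
    fdr_mode: str = "signed"
    p_denominator: str = "same_sign"
    smooth_pvalues: bool = False
    fdr_threshold: float = 0.05

    @classmethod
    def from_file(cls, path: str | Path) -> "MirseaConfig":
        """Load settings from a YAML/key-value file; unknown keys are errors."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PathwayResult:
    """Final per-pathway record: scores, significance and core miRNAs."""

    pathway_id: str
    mirna_size: int
    mires: float
    nmires: float
    p_value: float
    fdr: float
    direction: str
    core: CoreMiRSet
    peak_position: int
    significant: bool = False


def permute_labels(
    dataset: ExpressionDataset, n_perm: int, seed: int
) -> np.ndarray:
    """Uniform random sample relabellings preserving the two class sizes.

    Returns an (n_perm, n_samples) boolean matrix: True marks the samples
    assigned to class A in that permutation.  Each row is the dataset's own
    label vector pushed through a uniform index permutation, so the stream
    of index permutations depends only on the sample count and the seed —
    running the swapped contrast therefore yields exactly complementary
    masks.  Permutations are drawn with replacement; when fewer distinct
    labelings exist than requested this is unavoidable and a warning notes
    it.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(dataset.sample_ids)
    is_a = dataset.class_masks[0]
    distinct = math.comb(n, int(is_a.sum()))
    if distinct < n_perm:
        warnings.warn(
            f"only {distinct} distinct labelings exist for {n_perm} requested "
            "permutations; duplicates will occur"
        )
    rng = np.random.default_rng(seed)
    masks = np.empty((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i] = is_a[rng.permutation(n)]
    return masks


def empirical_pvalue(
    observed: float,
    null: np.ndarray,
    *,
    denominator: str = "same_sign",
    smooth: bool = False,
) -> float:
    """Empirical permutation p-value on the side of the observed score.

    M counts permuted scores strictly greater than a positive observed
    score, or strictly less than a negative one.  With the default
    ``denominator="same_sign"`` M is divided by the number of permuted
    scores sharing the observed sign — the background relevant to that
    side, which makes the p-value uniform under an exchangeable null.
    ``denominator="all"`` divides by the full permutation count instead;
    that reading doubles the null rejection rate (the score chooses its
    side first), so it is kept only for strict comparability.

    ``smooth`` switches M/N to (M+1)/(N+1), bounding p away from zero.
    An observed score of exactly zero carries no direction and gets p = 1.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if denominator not in ("same_sign", "all"):
        raise ValueError(f"unknown denominator {denominator!r}")
    if observed > 0:
        m = int(np.sum(null > observed))
        n = int(np.sum(null > 0)) if denominator == "same_sign" else null.size
    elif observed < 0:
        m = int(np.sum(null < observed))
        n = int(np.sum(null < 0)) if denominator == "same_sign" else null.size
    else:
        return 1.0
    if smooth:
        return (m + 1) / (n + 1)
    return m / n if n > 0 else 0.0


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normalize_es(observed: float, null: np.ndarray) -> float:
    """Rescale miRES by the mean same-sign permuted score.

    Positive scores divide by the mean of the positive null scores,
    negative by the magnitude of the mean negative null score, so the sign
    is preserved and a null-like score lands near +/-1.  Returns NaN (with
    a warning) when the null contains no same-sign score.
    """
    null = np.asarray(null, dtype=float)
    if observed == 0.0:
        return 0.0
    same = null[null > 0] if observed > 0 else null[null < 0]
    if same.size == 0:
        warnings.warn("no same-sign permutation score; NmiRES undefined")
        return float("nan")
    return float(observed / abs(same.mean()))


def _s2n_matrix(
    values: np.ndarray,
    mask_a: np.ndarray,
    *,
    sd_floor: bool,
    floor_frac: float = 0.2,
    abs_floor: float = 1e-8,
) -> np.ndarray:
    """Vectorised signal-to-noise over all rows for one labelling."""
    a = values[:, mask_a]
    b = values[:, ~mask_a]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = a.std(axis=1, ddof=1)
    sd_b = b.std(axis=1, ddof=1)
    if sd_floor:
        sd_a = np.maximum(np.maximum(sd_a, floor_frac * np.abs(mean_a)), abs_floor)
        sd_b = np.maximum(np.maximum(sd_b, floor_frac * np.abs(mean_b)), abs_floor)
    return (mean_a - mean_b) / (sd_a + sd_b)


def run_mirsea(
    dataset: ExpressionDataset,
    targets: TargetMap,
    pathways: GeneSetCollection,
    config: MirseaConfig | None = None,
) -> list[PathwayResult]:
    """Full pipeline: weights, conversion, enrichment, permutation inference.

    Results come back in converted-pathway order (input GMT order); use
    :func:`mirsea.io.write_results` for the FDR-sorted table.
    """
    config = config or MirseaConfig()

    universe = build_universe(
        targets, pathways, config.universe_mode, fixed_m=config.fixed_m
    )
    logger.info("universe: %d genes (%s mode)", universe.m, config.universe_mode)

    W = compute_weight_matrix(targets, pathways, universe)
    measured = set(dataset.mirna_ids)
    converted = convert_pathways(
        W, config.min_size, config.max_size, measured=measured
    )
    logger.info(
        "%d miRNAs measured; %d/%d pathways pass the size filter [%d, %d]",
        len(measured),
        len(converted),
        len(pathways),
        config.min_size,
        config.max_size,
    )
    if not converted:
        return []

    de = signal_to_noise(dataset, sd_floor=config.sd_floor)
    if all(v == 0.0 for v in de.values()):
        raise ValueError("degenerate data: every miRNA has zero differential expression")

    # observed statistics, per pathway, through the reference implementation
    profiles = {}
    cores = {}
    for cp in converted:
        scores = mir_score(de, cp.members)
        ranked = rank_mirnas(scores)
        prof = running_enrichment(ranked, cp, q=config.q)
        profiles[cp.pathway_id] = prof
        cores[cp.pathway_id] = extract_core_mirnas(prof, ranked, cp)

    # permutation null: shared relabelling stream, batch-scored
    mir_order = sorted(dataset.mirna_ids)
    row_of = {m: i for i, m in enumerate(dataset.mirna_ids)}
    values = dataset.values[[row_of[m] for m in mir_order], :]
    weight_rows = np.zeros((len(converted), len(mir_order)))
    member_rows = np.zeros((len(converted), len(mir_order)), dtype=bool)
    col_of = {m: i for i, m in enumerate(mir_order)}
    for pi, cp in enumerate(converted):
        for m, w in cp.members.items():
            member_rows[pi, col_of[m]] = True
            weight_rows[pi, col_of[m]] = w

    masks = permute_labels(dataset, config.n_perm, config.seed)
    null = np.empty((len(converted), config.n_perm))
    for k in range(config.n_perm):
        de_perm = _s2n_matrix(values, masks[k], sd_floor=config.sd_floor)
        score_rows = (1.0 + weight_rows) * de_perm[None, :]
        mires_k, _ = batch_enrichment_scores(score_rows, member_rows, config.q)
        null[:, k] = mires_k
    if np.isnan(null).any():
        warnings.warn("degenerate permutation scores dropped from the null")

    results: list[PathwayResult] = []
    for pi, cp in enumerate(converted):
        prof = profiles[cp.pathway_id]
        row_null = null[pi][~np.isnan(null[pi])]
        p = empirical_pvalue(
            prof.mires,
            row_null,
            denominator=config.p_denominator,
            smooth=config.smooth_pvalues,
        )
        nmires = normalize_es(prof.mires, row_null)
        direction = (
            "down-regulated"
            if prof.mires > 0
            else "up-regulated"
            if prof.mires < 0
            else "none"
        )
        results.append(
            PathwayResult(
                pathway_id=cp.pathway_id,
                mirna_size=cp.size,
                mires=prof.mires,
                nmires=nmires,
                p_value=p,
                fdr=float("nan"),
                direction=direction,
                core=cores[cp.pathway_id],
                peak_position=prof.peak_position,
            )
        )

    _attach_fdr(results, config.fdr_mode)
    for r in results:
        r.significant = r.fdr < config.fdr_threshold
    n_sig = sum(r.significant for r in results)
    logger.info("%d pathways significant at FDR < %g", n_sig, config.fdr_threshold)
    return results


def _attach_fdr(results: list[PathwayResult], mode: str) -> None:
    if mode == "pooled":
        groups = [list(range(len(results)))]
    elif mode == "signed":
        groups = [
            [i for i, r in enumerate(results) if r.mires > 0],
            [i for i, r in enumerate(results) if r.mires <= 0],
        ]
    else:
        raise ValueError(f"unknown fdr_mode {mode!r}")
    for idx in groups:
        if not idx:
            continue
        adjusted = bh_fdr([results[i].p_value for i in idx])
        for i, a in zip(idx, adjusted):
            results[i].fdr = float(a)
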