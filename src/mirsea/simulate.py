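"""Seeded synthetic inputs with known planted structure.

The generator emulates a two-class miRNA profiling study: a panel of
miRNAs measured over two sample groups, a validated miRNA-target
interaction table, and a collection of gene pathways.  A configurable
subset of *planted* miRNAs carries the signal jointly required by the
method: their expression is shifted between classes (differential
expression) AND their target sets are enriched for one designated
pathway's genes (high miRNA-pathway weight).  With ``delta = 0`` no miRNA
has a class effect and the dataset is exchangeable — the regime the
permutation null assumes.

All generators are pure functions of the design (the seed lives inside
it): the same design always produces the same data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ExpressionDataset, GeneSetCollection, TargetMap

__all__ = [
    "SyntheticDesign",
    "null_design",
    "planted_design",
    "make_pathways",
    "make_target_map",
    "make_expression",
    "write_dataset",
]


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic study.

    ``delta`` is the class-mean shift of planted miRNAs in units of the
    noise standard deviation, applied to class A (the reference class)
    only; ``planted_overlap`` is how many of each planted miRNA's targets
    are drawn from the planted pathway's genes.
    """

    n_mirnas: int = 300
    n_samples_per_class: int = 10
    n_genes: int = 5600
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (30, 60)
    targets_per_mirna_range: tuple[int, int] = (15, 30)
    planted_pathway: str = "PW001"
    n_planted: int = 15
    planted_overlap: int = 14
    delta: float = 1.5
    noise_sd: float = 1.0
    baseline: float = 8.0
    classes: tuple[str, str] = ("Normal", "Tumor")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_mirnas",
            "n_samples_per_class",
            "n_genes",
            "n_pathways",
            "n_planted",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_planted > self.n_mirnas:
            raise ValueError("more planted miRNAs than miRNAs")
        if self.planted_overlap < 1:
            raise ValueError("planted miRNAs must overlap the planted pathway")
        if self.planted_overlap > self.pathway_size_range[0]:
            raise ValueError(
                "planted_overlap exceeds the smallest possible pathway size"
            )
        if self.planted_overlap > self.targets_per_mirna_range[0]:
            raise ValueError("planted_overlap exceeds the smallest target set")

    @property
    def mirna_ids(self) -> list[str]:
        return [f"hsa-miR-{i + 1:04d}" for i in range(self.n_mirnas)]

    @property
    def planted_mirnas(self) -> list[str]:
        return self.mirna_ids[: self.n_planted]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]

    @property
    def pathway_ids(self) -> list[str]:
        return [f"PW{i + 1:03d}" for i in range(self.n_pathways)]


def null_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """No class effect anywhere: the calibration regime."""
    return SyntheticDesign(delta=0.0, seed=seed, **overrides)


def planted_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """Default planted-signal regime (15 shifted miRNAs, delta = 1.5)."""
    return SyntheticDesign(seed=seed, **overrides)


def _rng(design: SyntheticDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng([design.seed, stream])


def make_pathways(design: SyntheticDesign) -> GeneSetCollection:
    """Random gene sets within the configured size range (GMT-compatible).

    The planted pathway's genes are exclusive to it: background pathways
    draw from the rest of the genome (they may overlap each other).  This
    keeps the ground truth well defined — were background pathways to
    contain the planted module's genes, they would share its regulation
    and partially count as true positives themselves.
    """
    if design.planted_pathway not in design.pathway_ids:
        raise ValueError(f"planted pathway {design.planted_pathway!r} not generated")
    rng = _rng(design, 1)
    genes = np.array(design.gene_ids)
    lo, hi = design.pathway_size_range
    planted_size = int(rng.integers(lo, hi + 1))
    planted_genes = rng.choice(genes, size=planted_size, replace=False)
    background = np.array(sorted(set(design.gene_ids) - set(planted_genes.tolist())))
    pathways: dict[str, tuple[str, set[str]]] = {}
    for pid in design.pathway_ids:
        if pid == design.planted_pathway:
            members = planted_genes
        else:
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(background, size=size, replace=False)
        pathways[pid] = (f"synthetic pathway {pid}", set(members.tolist()))
    return GeneSetCollection(pathways)


def make_target_map(design: SyntheticDesign) -> TargetMap:
    """Random target sets; planted miRNAs get forced overlap with the planted pathway."""
    pathways = make_pathways(design)
    planted_genes = np.array(sorted(pathways.genes(design.planted_pathway)))
    if design.planted_overlap > len(planted_genes):
        raise ValueError("planted overlap exceeds the planted pathway's gene count")
    rng = _rng(design, 2)
    genes = np.array(design.gene_ids)
    outside = np.array(sorted(set(design.gene_ids) - set(planted_genes.tolist())))
    lo, hi = design.targets_per_mirna_range
    planted = set(design.planted_mirnas)
    entries: dict[str, set[str]] = {}
    for mirna in design.mirna_ids:
        n = int(rng.integers(lo, hi + 1))
        if mirna in planted:
            inside = rng.choice(planted_genes, size=design.planted_overlap, replace=False)
            rest = rng.choice(outside, size=n - design.planted_overlap, replace=False)
            entries[mirna] = set(inside.tolist()) | set(rest.tolist())
        else:
            entries[mirna] = set(rng.choice(genes, size=n, replace=False).tolist())
    return TargetMap(entries)


def make_expression(design: SyntheticDesign) -> ExpressionDataset:
    """Gaussian intensities; planted miRNAs shifted by delta*noise_sd in class A."""
    rng = _rng(design, 3)
    n_per = design.n_samples_per_class
    n_samples = 2 * n_per
    values = rng.normal(
        loc=design.baseline, scale=design.noise_sd, size=(design.n_mirnas, n_samples)
    )
    shift = design.delta * design.noise_sd
    values[: design.n_planted, :n_per] += shift
    sample_ids = [f"{design.classes[0]}_{i + 1:02d}" for i in range(n_per)] + [
        f"{design.classes[1]}_{i + 1:02d}" for i in range(n_per)
    ]
    phenotype = [design.classes[0]] * n_per + [design.classes[1]] * n_per
    return ExpressionDataset(
        mirna_ids=design.mirna_ids,
        values=values,
        sample_ids=sample_ids,
        phenotype=phenotype,
        classes=design.classes,
    )


def write_dataset(design: SyntheticDesign, outdir: str | Path) -> dict[str, Path]:
    """Materialise a design as the four text inputs the pipeline reads.

    Writes ``expression.tsv``, ``classes.cls``, ``targets.tsv`` and
    ``pathways.gmt`` under ``outdir`` and returns their paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = make_expression(design)
    targets = make_target_map(design)
    pathways = make_pathways(design)

    expr_path = outdir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("miRNA\t" + "\t".join(dataset.sample_ids) + "\n")
        for i, mirna in enumerate(dataset.mirna_ids):
            row = "\t".join(f"{v:.6f}" for v in dataset.values[i])
            fh.write(f"{mirna}\t{row}\n")

    cls_path = outdir / "classes.cls"
    n = len(dataset.sample_ids)
    with open(cls_path, "w") as fh:
        fh.write(f"{n} 2 1\n")
        fh.write(f"# {dataset.classes[0]} {dataset.classes[1]}\n")
        fh.write(" ".join(dataset.phenotype) + "\n")

    targets_path = outdir / "targets.tsv"
    with open(targets_path, "w") as fh:
        fh.write("mirna\tgene\n")
        for mirna in sorted(targets.entries):
            for gene in sorted(targets.entries[mirna]):
                fh.write(f"{mirna}\t{gene}\n")

    gmt_path = outdir / "pathways.gmt"
    with open(gmt_path, "w") as fh:
        for pid, (desc, genes) in pathways.pathways.items():
            fh.write(pid + "\t" + desc + "\t" + "\t".join(sorted(genes)) + "\n")

    return {
        "expression": expr_path,
        "classes": cls_path,
        "targets": targets_path,
        "gmt": gmt_path,
    }
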