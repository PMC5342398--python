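"""Input/output for expression matrices, phenotype labels, target tables and gene sets.

All external formats are plain text:

* expression — TSV, miRNAs in rows, first column the miRNA id, header row of
  sample ids;
* phenotype — either a GSEA-style three-line CLS file or a two-column TSV
  (sample id, class label);
* miRNA-target interactions — TSV with a header naming the miRNA and gene
  columns (configurable);
* gene sets — GMT (name, description, member genes, tab-separated);
* results — TSV written by :func:`write_results`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "TargetMap",
    "GeneSetCollection",
    "GeneUniverse",
    "read_expression",
    "read_phenotype",
    "read_target_tables",
    "read_gmt",
    "build_universe",
    "write_results",
    "read_results",
    "normalize_gene_symbol",
]

RESULT_COLUMNS = [
    "pathway",
    "miRNA_size",
    "miRES",
    "NmiRES",
    "p_value",
    "FDR",
    "direction",
    "core_miRNAs",
]


def normalize_gene_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: stripped and upper-cased.

    No alias resolution is attempted; two symbols are the same gene iff
    their canonical forms are equal.
    """
    return symbol.strip().upper()


@dataclass
class ExpressionDataset:
    """A two-class miRNA expression experiment.

    ``values`` is a miRNAs x samples matrix of expression intensities on
    whatever scale the input provides.  ``phenotype`` assigns each sample to
    one of exactly two class labels; ``classes`` fixes the contrast order:
    ``classes[0]`` is "class A" and a positive differential-expression value
    means higher expression in class A.
    """

    mirna_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    phenotype: list[str]
    classes: tuple[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.sample_ids)} samples"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            dupes = sorted({m for m in self.mirna_ids if self.mirna_ids.count(m) > 1})
            raise ValueError(f"duplicate miRNA ids: {dupes}")
        if len(self.classes) != 2 or self.classes[0] == self.classes[1]:
            raise ValueError("exactly two distinct class labels are required")
        extra = set(self.phenotype) - set(self.classes)
        if extra:
            raise ValueError(f"phenotype labels outside declared classes: {sorted(extra)}")
        for c in self.classes:
            if sum(1 for p in self.phenotype if p == c) < 2:
                raise ValueError(f"class {c!r} has fewer than 2 samples")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def class_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean sample masks for (class A, class B)."""
        labels = np.asarray(self.phenotype)
        return labels == self.classes[0], labels == self.classes[1]

    def swap_classes(self) -> "ExpressionDataset":
        """Return the same data with the contrast direction reversed."""
        return ExpressionDataset(
            mirna_ids=list(self.mirna_ids),
            values=self.values.copy(),
            sample_ids=list(self.sample_ids),
            phenotype=list(self.phenotype),
            classes=(self.classes[1], self.classes[0]),
        )


@dataclass
class TargetMap:
    """miRNA id -> set of validated target gene symbols (union over sources)."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mirna, genes in self.entries.items():
            if not genes:
                raise ValueError(f"miRNA {mirna!r} has an empty target set")

    def target_count(self, mirna: str) -> int:
        return len(self.entries.get(mirna, ()))

    @property
    def n_interactions(self) -> int:
        """Number of unique (miRNA, gene) pairs."""
        return sum(len(g) for g in self.entries.values())

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.entries.values():
            out |= genes
        return out

    def merged_with(self, other: "TargetMap") -> "TargetMap":
        entries = {m: set(g) for m, g in self.entries.items()}
        for m, g in other.entries.items():
            entries.setdefault(m, set()).update(g)
        return TargetMap(entries)


@dataclass
class GeneSetCollection:
    """Ordered pathway id -> (description, set of gene symbols)."""

    pathways: dict[str, tuple[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")

    @property
    def ids(self) -> list[str]:
        return list(self.pathways)

    def genes(self, pathway_id: str) -> set[str]:
        return self.pathways[pathway_id][1]

    def size(self, pathway_id: str) -> int:
        return len(self.pathways[pathway_id][1])

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.pathways.values():
            out |= genes
        return out

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class GeneUniverse:
    """The reference gene population for the hypergeometric weighting."""

    genes: set[str] | None
    m: int

    def __post_init__(self) -> None:
        if self.genes is not None and len(self.genes) != self.m:
            raise ValueError("universe size m does not match the gene set")
        if self.m <= 0:
            raise ValueError("universe must be non-empty")

    def restrict(self, genes: Iterable[str]) -> set[str]:
        """Intersect a gene set with the universe (identity for size-only universes)."""
        gset = set(genes)
        if self.genes is None:
            return gset
        return gset & self.genes


def read_phenotype(path: str | Path, sample_ids: Sequence[str]) -> tuple[list[str], tuple[str, str]]:
    """Read class labels from a CLS file or a two-column TSV.

    CLS dialect (GSEA): line 1 ``<n> <k> 1``, line 2 ``# classA classB``,
    line 3 space-separated labels (names or 0/1 indices) in sample order.
    TSV dialect: one ``sample<TAB>label`` row per sample, any order.

    Returns per-sample labels aligned with ``sample_ids`` and the contrast
    pair ``(class A, class B)`` — class A is the first class declared.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty phenotype file")
    lines = text.splitlines()
    if lines[0].lstrip().split()[0].isdigit() and len(lines) >= 3:
        return _parse_cls(lines, sample_ids, path)
    return _parse_phenotype_tsv(lines, sample_ids, path)


def _parse_cls(lines: list[str], sample_ids: Sequence[str], path: Path):
    header = lines[0].split()
    n_samples = int(header[0])
    if n_samples != len(sample_ids):
        raise ValueError(
            f"{path}: CLS declares {n_samples} samples but matrix has {len(sample_ids)}"
        )
    class_line = lines[1].split()
    if class_line[0] != "#":
        # some writers glue the hash onto the first name
        class_names = [class_line[0].lstrip("#")] + class_line[1:]
    else:
        class_names = class_line[1:]
    if len(class_names) != 2:
        raise ValueError(f"{path}: expected two classes, found {class_names}")
    raw = lines[2].split()
    if len(raw) != n_samples:
        raise ValueError(f"{path}: label line has {len(raw)} entries, expected {n_samples}")
    if set(raw) <= {"0", "1"}:
        labels = [class_names[int(x)] for x in raw]
    else:
        if set(raw) != set(class_names):
            raise ValueError(f"{path}: labels {sorted(set(raw))} do not match classes {class_names}")
        labels = list(raw)
    return labels, (class_names[0], class_names[1])


def _parse_phenotype_tsv(lines: list[str], sample_ids: Sequence[str], path: Path):
    assignment: dict[str, str] = {}
    class_order: list[str] = []
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{i}: expected 'sample<TAB>label'")
        sample, label = fields[0].strip(), fields[1].strip()
        if sample.lower() in {"sample", "sample_id"} and i == 1:
            continue
        if sample in assignment:
            raise ValueError(f"{path}:{i}: duplicate sample {sample!r}")
        assignment[sample] = label
        if label not in class_order:
            class_order.append(label)
    missing = [s for s in sample_ids if s not in assignment]
    if missing:
        raise ValueError(f"{path}: no label for samples {missing}")
    unknown = sorted(set(assignment) - set(sample_ids))
    if unknown:
        raise ValueError(f"{path}: labels for samples absent from the matrix: {unknown}")
    if len(class_order) != 2:
        raise ValueError(f"{path}: expected exactly two classes, found {class_order}")
    return [assignment[s] for s in sample_ids], (class_order[0], class_order[1])


def read_expression(
    path: str | Path,
    class_file: str | Path,
    *,
    drop_missing: bool = False,
) -> ExpressionDataset:
    """Load an expression matrix plus its phenotype assignment.

    Rows with missing values abort the load unless ``drop_missing`` is set,
    in which case they are dropped with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate miRNA ids: {dupes}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        if not drop_missing:
            raise ValueError(
                f"{path}: missing values present; pass drop_missing=True to drop those rows"
            )
        keep = ~np.isnan(values).any(axis=1)
        warnings.warn(f"{path}: dropping {int((~keep).sum())} rows with missing values")
        df = df.loc[keep]
        values = df.to_numpy(dtype=float)
    sample_ids = [str(c) for c in df.columns]
    labels, classes = read_phenotype(class_file, sample_ids)
    return ExpressionDataset(
        mirna_ids=[str(i) for i in df.index],
        values=values,
        sample_ids=sample_ids,
        phenotype=labels,
        classes=classes,
    )


def read_target_tables(
    paths: Sequence[str | Path],
    *,
    mirna_column: str = "mirna",
    gene_column: str = "gene",
) -> TargetMap:
    """Union-merge one or more miRNA-target interaction tables.

    Each file is a TSV whose header names (case-insensitively) the miRNA and
    gene columns.  Duplicate (miRNA, gene) pairs — within or across files —
    collapse to a single interaction.
    """
    entries: dict[str, set[str]] = {}
    for path in paths:
        path = Path(path)
        text = path.read_text()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            warnings.warn(f"{path}: empty target table, skipped")
            continue
        header = [h.strip().lower() for h in lines[0].split("\t")]
        try:
            mi = header.index(mirna_column.lower())
            gi = header.index(gene_column.lower())
        except ValueError:
            raise ValueError(
                f"{path}: header must contain columns {mirna_column!r} and "
                f"{gene_column!r}; found {header}"
            ) from None
        for lineno, line in enumerate(lines[1:], start=2):
            fields = line.split("\t")
            if len(fields) <= max(mi, gi):
                raise ValueError(f"{path}:{lineno}: expected >= {max(mi, gi) + 1} fields")
            mirna = fields[mi].strip()
            gene = normalize_gene_symbol(fields[gi])
            if not mirna or not gene:
                raise ValueError(f"{path}:{lineno}: empty miRNA id or gene symbol")
            entries.setdefault(mirna, set()).add(gene)
    return TargetMap(entries)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file, preserving file order and deduplicating genes."""
    path = Path(path)
    pathways: dict[str, tuple[str, set[str]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        name, desc = fields[0].strip(), fields[1].strip()
        if name in pathways:
            raise ValueError(f"{path}:{lineno}: duplicate pathway id {name!r}")
        genes = {normalize_gene_symbol(g) for g in fields[2:] if g.strip()}
        if not genes:
            raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
        pathways[name] = (desc, genes)
    return GeneSetCollection(pathways)


def build_universe(
    targets: TargetMap,
    pathways: GeneSetCollection,
    mode: str = "union",
    *,
    fixed_m: int | None = None,
) -> GeneUniverse:
    """Construct the gene universe for hypergeometric weighting.

    ``union`` (default) — all target genes plus all pathway genes;
    ``targets_only`` — genes appearing as targets;
    ``fixed_count`` — a size-only universe of ``fixed_m`` genes, for matching
    an externally chosen genome size (must not be smaller than the union).
    """
    union = targets.all_genes | pathways.all_genes
    if mode == "union":
        return GeneUniverse(genes=union, m=len(union))
    if mode == "targets_only":
        genes = targets.all_genes
        return GeneUniverse(genes=genes, m=len(genes))
    if mode == "fixed_count":
        if fixed_m is None:
            raise ValueError("fixed_count mode requires fixed_m")
        if fixed_m < len(union):
            raise ValueError(
                f"fixed_m={fixed_m} is smaller than the observed union ({len(union)} genes)"
            )
        return GeneUniverse(genes=None, m=fixed_m)
    raise ValueError(f"unknown universe mode {mode!r}")


def write_results(results: Sequence, path: str | Path) -> None:
    """Write pathway results as a TSV table.

    Rows are sorted by FDR ascending, then |NmiRES| descending, then pathway
    id — the order a reader scanning for significant pathways expects.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "pathway": r.pathway_id,
                "miRNA_size": r.mirna_size,
                "miRES": r.mires,
                "NmiRES": r.nmires,
                "p_value": r.p_value,
                "FDR": r.fdr,
                "direction": r.direction,
                "core_miRNAs": ";".join(r.core.mirna_ids),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        order = sorted(
            range(len(df)),
            key=lambda i: (
                df["FDR"].iloc[i],
                -abs(df["NmiRES"].iloc[i]) if np.isfinite(df["NmiRES"].iloc[i]) else 0.0,
                df["pathway"].iloc[i],
            ),
        )
        df = df.iloc[order].reset_index(drop=True)
    # default float repr is shortest-round-trip: values survive re-reading
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"core_miRNAs": str})
    df["core_miRNAs"] = df["core_miRNAs"].fillna("")
    return df
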