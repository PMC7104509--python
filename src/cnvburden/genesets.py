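"""Dosage-sensitivity and brain-only expression-sensitivity gene sets.

Dosage sensitivity follows the ohnolog/whole-genome-duplication scheme:
every gene falls in one of four classes — ohnologs that later underwent a
small-scale duplication (SSD), ohnologs without SSD, non-ohnologous
duplicates, and singletons. Under the gene balance hypothesis the
dosage-sensitive (DS) set is *ohnologs without SSD* plus *singletons*; the
other two classes are dosage-insensitive (DinS).

Expression sensitivity is defined per tissue from eQTL catalogue files:
a gene is *stable* in a tissue when it is expressed there (listed among
the tissue's eGenes) and has no significant eQTL in that tissue, and
*unstable* when expressed with at least one significant eQTL. A gene has
expression sensitivity **only in brain** when it is stable in every brain
tissue and unstable outside brain; see :func:`es_only_in_brain` for the
precise handling of tissues where the gene is not expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "DOSAGE_CLASSES",
    "DS_CLASSES",
    "GeneRecord",
    "TissueEvidence",
    "GeneSetCatalog",
    "classify_dosage",
    "stable_in_tissue",
    "unstable_in_tissue",
    "es_only_in_brain",
    "combine_categories",
    "FOUR_GROUPS",
    "read_ohnolog_table",
    "read_gene_bed",
    "read_egenes",
    "read_signif_pairs",
    "write_catalog",
]

OHNOLOG_NO_SSD = "ohnolog_no_ssd"
OHNOLOG_SSD = "ohnolog_ssd"
NON_OHNOLOG_DUPLICATE = "non_ohnolog_duplicate"
SINGLETON = "singleton"
UNCLASSIFIED = "unclassified"

DOSAGE_CLASSES = (OHNOLOG_NO_SSD, OHNOLOG_SSD, NON_OHNOLOG_DUPLICATE, SINGLETON)
DS_CLASSES = frozenset({OHNOLOG_NO_SSD, SINGLETON})

FOUR_GROUPS = ("DS&ES", "DS&-ES", "DinS&ES", "DinS&-ES")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    dosage_class: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.dosage_class not in DOSAGE_CLASSES + (UNCLASSIFIED,):
            raise ValueError(f"unknown dosage class {self.dosage_class!r}")


@dataclass
class TissueEvidence:
    """Per-tissue expression evidence: eGenes and genes with >= 1 eQTL.

    The two sets come from independent files, so ``eqtl_genes`` is not
    required to be a subset of ``egenes``.
    """

    tissue_id: str
    is_brain: bool
    egenes: frozenset[str]
    eqtl_genes: frozenset[str]


@dataclass
class GeneSetCatalog:
    """The assembled gene sets used by every downstream enrichment test."""

    ds: frozenset[str]
    dosage_insensitive: frozenset[str]
    es_brain_only: frozenset[str]
    four_groups: dict[str, str] = field(default_factory=dict)


def classify_dosage(
    table: Mapping[str, str] | pd.DataFrame,
) -> tuple[dict[str, str], frozenset[str]]:
    """Map each gene to its dosage class and derive the DS set.

    ``table`` maps gene_id -> class label (or a two-column DataFrame).
    DS = ohnologs without SSD plus singletons; ohnologs with SSD and
    non-ohnologous duplicates are dosage-insensitive; genes absent from
    the table are neither. Unknown labels raise, naming the offending row.
    """
    if isinstance(table, pd.DataFrame):
        items = list(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)))
    else:
        items = list(table.items())
    classes: dict[str, str] = {}
    for row, (gene, label) in enumerate(items):
        if label not in DOSAGE_CLASSES:
            raise ValueError(
                f"row {row} (gene {gene!r}): unknown dosage class {label!r}"
            )
        classes[gene] = label
    ds = frozenset(g for g, c in classes.items() if c in DS_CLASSES)
    return classes, ds


def stable_in_tissue(gene_id: str, t: TissueEvidence) -> bool:
    """Expressed in the tissue with no significant eQTL there."""
    return gene_id in t.egenes and gene_id not in t.eqtl_genes


def unstable_in_tissue(gene_id: str, t: TissueEvidence) -> bool:
    """Expressed in the tissue with at least one significant eQTL there."""
    return gene_id in t.egenes and gene_id in t.eqtl_genes


def es_only_in_brain(
    tissues: Sequence[TissueEvidence],
    mode: str = "all_expressed",
) -> frozenset[str]:
    """Genes with expression sensitivity only in brain.

    A gene qualifies iff it is stable in **every** brain tissue, and its
    behaviour outside brain satisfies the chosen reading of "unstable in
    other tissues":

    - ``all_expressed`` (default): unstable in every non-brain tissue where
      it is expressed, and unstable in at least one non-brain tissue.
      Non-expression outside brain does not disqualify, since an
      unexpressed gene is neither stable nor unstable there.
    - ``all_strict``: unstable in every configured non-brain tissue.
    - ``any``: unstable in at least one non-brain tissue.

    The modes are nested: ``any`` ⊇ ``all_expressed`` ⊇ ``all_strict``.
    """
    if mode not in ("all_expressed", "all_strict", "any"):
        raise ValueError(f"unknown mode {mode!r}")
    brain = [t for t in tissues if t.is_brain]
    other = [t for t in tissues if not t.is_brain]
    if not brain:
        raise ValueError("no brain tissues configured")

    candidates = set.intersection(
        *({g for g in t.egenes if g not in t.eqtl_genes} for t in brain)
    )
    result: set[str] = set()
    for g in candidates:
        unstable = [unstable_in_tissue(g, t) for t in other]
        if mode == "any":
            ok = any(unstable)
        elif mode == "all_strict":
            ok = len(other) > 0 and all(unstable)
        else:  # all_expressed
            expressed = [g in t.egenes for t in other]
            ok = any(unstable) and all(
                u for u, e in zip(unstable, expressed) if e
            )
        if ok:
            result.add(g)
    return frozenset(result)


def combine_categories(
    ds: frozenset[str] | set[str],
    es: frozenset[str] | set[str],
    universe: Iterable[str],
) -> dict[str, str]:
    """Partition the annotated universe into the four DS x ES groups.

    ``universe`` should contain only genes carrying both a dosage class and
    an expression-sensitivity determination; genes outside it are ignored.
    """
    groups: dict[str, str] = {}
    for g in universe:
        d = "DS" if g in ds else "DinS"
        e = "ES" if g in es else "-ES"
        groups[g] = f"{d}&{e}"
    return groups


# ---------------------------------------------------------------------------
# file readers / writers


def read_ohnolog_table(path: str | Path) -> pd.DataFrame:
    """Read a two-column TSV: gene_id, dosage class label."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_gene_bed(
    path: str | Path, classes: Mapping[str, str] | None = None
) -> list[GeneRecord]:
    """Read gene intervals from a BED file whose 4th column is the gene id."""
    from .intervals import normalize_chrom

    genes: list[GeneRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{ln}: gene BED needs 4 columns")
            gid = fields[3]
            cls = (classes or {}).get(gid, UNCLASSIFIED)
            genes.append(
                GeneRecord(
                    gid,
                    GenomicInterval(
                        normalize_chrom(fields[0]), int(fields[1]), int(fields[2])
                    ),
                    cls,
                )
            )
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def read_egenes(path: str | Path) -> frozenset[str]:
    """Gene ids from a per-tissue eGene list (GTEx-style header tolerated).

    Only a ``gene_id`` column is required; membership is taken as printed,
    without re-thresholding q-values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: no gene_id column")
    return frozenset(df["gene_id"].dropna())


def read_signif_pairs(path: str | Path) -> frozenset[str]:
    """Gene ids appearing in a significant variant-gene pair list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: no gene_id column")
    return frozenset(df["gene_id"].dropna())


def write_catalog(
    genes: Sequence[GeneRecord],
    catalog: GeneSetCatalog,
    path: str | Path,
) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "dosage_class": g.dosage_class,
                "es_brain_only": g.gene_id in catalog.es_brain_only,
                "four_group": catalog.four_groups.get(g.gene_id, "unassigned"),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
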