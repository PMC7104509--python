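#!/usr/bin/env python
"""Build the gene-set catalog: dosage sensitivity x brain-only ES.

Reads the ohnolog class table, gene annotation BED and per-tissue eQTL
evidence written by 01_simulate.py; derives the dosage-sensitive set
(ohnologs without SSD + singletons), the brain-only
expression-sensitivity set, and the four combined categories; writes the
catalog TSV and prints the group sizes.
"""

import argparse
from pathlib import Path

from cnvburden.genesets import (
    FOUR_GROUPS,
    GeneSetCatalog,
    TissueEvidence,
    classify_dosage,
    combine_categories,
    es_only_in_brain,
    read_egenes,
    read_gene_bed,
    read_ohnolog_table,
    read_signif_pairs,
    write_catalog,
)


def load_tissues(gtex_dir: Path) -> list[TissueEvidence]:
    tissues = []
    for egene_file in sorted(gtex_dir.glob("*_Analysis.v6p.egenes.txt")):
        tid = egene_file.name.replace("_Analysis.v6p.egenes.txt", "")
        pair_file = gtex_dir / f"{tid}_Analysis.v6p.signif_snpgene_pairs.txt"
        tissues.append(
            TissueEvidence(
                tid,
                tid.startswith("Brain"),
                read_egenes(egene_file),
                read_signif_pairs(pair_file),
            )
        )
    return tissues


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--out", type=Path, default=Path("results/genesets"))
    parser.add_argument("--mode", default="all_expressed",
                        choices=["all_expressed", "all_strict", "any"])
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_ohnolog_table(args.sim / "ohnolog_classes.tsv")
    classes, ds = classify_dosage(dict(zip(table.gene_id, table.dosage_class)))
    genes = read_gene_bed(args.sim / "genes.bed", classes)
    tissues = load_tissues(args.sim / "gtex")
    es = es_only_in_brain(tissues, mode=args.mode)
    groups = combine_categories(ds, es, [g.gene_id for g in genes])
    catalog = GeneSetCatalog(
        ds=frozenset(ds),
        dosage_insensitive=frozenset(g for g in classes if g not in ds),
        es_brain_only=frozenset(es),
        four_groups=groups,
    )
    write_catalog(genes, catalog, args.out / "catalog.tsv")

    print(f"{len(genes)} genes: {len(ds)} dosage-sensitive "
          f"({len(ds) / len(genes):.1%}), {len(es)} brain-only ES (mode={args.mode})")
    for lab in FOUR_GROUPS:
        n = sum(1 for v in groups.values() if v == lab)
        print(f"  {lab}: {n}")


if __name__ == "__main__":
    main()
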