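#!/usr/bin/env python
"""Patient-only region discovery and cross-disease sharing.

Builds each disease's case-only footprint from the post-QC test calls,
intersects footprints across diseases, tallies dosage-sensitive genes per
candidate region, runs the density and carrier exact tests, and writes a
shared-region table plus a disease-specific table.
"""

import argparse
from pathlib import Path

import pandas as pd

from cnvburden.cnv import read_phenotypes
from cnvburden.enrichment import GeneIndex
from cnvburden.genesets import read_gene_bed, read_ohnolog_table
from cnvburden.regions import (
    classify_candidates,
    count_carriers,
    count_region_genes,
    patient_only_regions,
    shared_regions,
)

DISEASES = ["narcolepsy", "hypersomnia", "panic", "autism", "alzheimer"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--qc", type=Path, default=Path("results/qc"))
    parser.add_argument("--reported", type=Path, default=None,
                        help="optional BED of previously reported regions")
    parser.add_argument("--out", type=Path, default=Path("results/regions"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    from analysis_io import read_test_calls  # local helper shared with 04

    table = read_ohnolog_table(args.sim / "ohnolog_classes.tsv")
    classes = dict(zip(table.gene_id, table.dosage_class))
    genes = read_gene_bed(args.sim / "genes.bed", classes)
    index = GeneIndex(genes)

    footprints = {}
    carriers_input = {}
    cohort_sizes = {}
    for disease in DISEASES:
        calls = read_test_calls(args.qc / f"{disease}.test_calls.tsv")
        phen = read_phenotypes(args.sim / f"{disease}.phenotypes.tsv")
        case_calls = [c for c in calls if phen[c.sample_id] == "case"]
        ctrl_calls = [c for c in calls if phen[c.sample_id] == "control"]
        footprints[disease] = patient_only_regions(case_calls, ctrl_calls)
        carriers_input[disease] = (case_calls, ctrl_calls)
        cohort_sizes[disease] = (
            sum(1 for v in phen.values() if v == "case"),
            sum(1 for v in phen.values() if v == "control"),
        )

    candidates = shared_regions(footprints)
    reported = []
    if args.reported:
        from cnvburden.intervals import read_bed

        reported = read_bed(args.reported)

    carrier_counts = {}
    for cand in candidates:
        count_region_genes(cand, index)
        pooled_cases = [c for d in cand.diseases for c in carriers_input[d][0]]
        pooled_ctrls = carriers_input[next(iter(cand.diseases))][1]
        count_carriers(cand, {"case": pooled_cases, "control": pooled_ctrls})
        n_cases = sum(cohort_sizes[d][0] for d in cand.diseases)
        n_controls = cohort_sizes[next(iter(cand.diseases))][1]
        carrier_counts[id(cand)] = (
            cand.carriers["case"], n_cases, cand.carriers["control"], n_controls
        )
    shared, specific = classify_candidates(
        candidates, reported, carrier_counts=carrier_counts
    )

    def to_rows(cands):
        return [
            {
                "region": c.region.to_region_string(),
                "span": c.span.to_region_string(),
                "diseases": ",".join(sorted(c.diseases)),
                "cnv_type": c.cnv_type,
                "n_ds_genes": len(c.ds_genes),
                "total_genes": c.total_genes,
                "previously_reported": c.previously_reported,
                "shared": c.shared,
                "ds_rich": c.ds_rich,
                "case_carriers": c.carriers.get("case"),
                "control_carriers": c.carriers.get("control"),
                "fisher_density_p": c.fisher_density_p,
                "fisher_carrier_p": c.fisher_carrier_p,
            }
            for c in cands
        ]

    pd.DataFrame(to_rows(shared)).to_csv(args.out / "shared_regions.tsv",
                                         sep="\t", index=False)
    pd.DataFrame(to_rows(specific)).to_csv(args.out / "disease_specific_regions.tsv",
                                           sep="\t", index=False)
    print(f"{len(candidates)} multi-disease candidates: "
          f"{len(shared)} shared, {len(specific)} disease-specific")
    for c in shared[:10]:
        dens = f"{c.fisher_density_p:.3g}" if c.fisher_density_p is not None else "NA"
        print(f"  {c.region.to_region_string()} [{','.join(sorted(c.diseases))}] "
              f"{c.cnv_type}, {len(c.ds_genes)}/{c.total_genes} DS genes, "
              f"density p={dens}")


if __name__ == "__main__":
    main()
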