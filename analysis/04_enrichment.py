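#!/usr/bin/env python
"""Case-control enrichment tests per disease, gene subset and CNV stratum.

For every disease, tests the dosage-sensitive set, the brain-only ES set
and the four combined categories, in the pooled / deletion / duplication
strata: ratio of mean per-sample subset-gene counts, one-sided
permutation p, and the logistic-regression analogue adjusted for total
gene burden. Writes one row per comparison plus a Benjamini-Hochberg
summary column and a JSON run manifest.
"""

import argparse
import json
from pathlib import Path

import pandas as pd
from statsmodels.stats.multitest import multipletests

from cnvburden.cnv import QCThresholds, read_phenotypes
from cnvburden.enrichment import GeneIndex, per_sample_counts, run_enrichment
from cnvburden.genesets import FOUR_GROUPS, read_gene_bed, read_ohnolog_table

from analysis_io import read_test_calls

DISEASES = ["narcolepsy", "hypersomnia", "panic", "autism", "alzheimer"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--qc", type=Path, default=Path("results/qc"))
    parser.add_argument("--catalog", type=Path,
                        default=Path("results/genesets/catalog.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/enrichment"))
    parser.add_argument("--n-perm", type=int, default=999)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_ohnolog_table(args.sim / "ohnolog_classes.tsv")
    classes = dict(zip(table.gene_id, table.dosage_class))
    genes = read_gene_bed(args.sim / "genes.bed", classes)
    index = GeneIndex(genes)
    cat = pd.read_csv(args.catalog, sep="\t")
    subsets = {"DS": set(cat.loc[cat.dosage_class.isin(
                   ["ohnolog_no_ssd", "singleton"]), "gene_id"]),
               "ES_brain_only": set(cat.loc[cat.es_brain_only, "gene_id"])}
    for lab in FOUR_GROUPS:
        subsets[lab] = set(cat.loc[cat.four_group == lab, "gene_id"])

    rows = []
    seed = args.seed
    for disease in DISEASES:
        calls = read_test_calls(args.qc / f"{disease}.test_calls.tsv")
        phen = read_phenotypes(args.sim / f"{disease}.phenotypes.tsv")
        for subset_name, subset in subsets.items():
            for stratum in ("all", "deletion", "duplication"):
                counts = per_sample_counts(calls, index, subset, phen, stratum)
                seed += 1
                res = run_enrichment(counts, subset_name, stratum,
                                     n_perm=args.n_perm, seed=seed)
                rows.append({
                    "disease": disease, "subset": subset_name,
                    "stratum": stratum, "mean_case": res.mean_case,
                    "mean_control": res.mean_control, "ratio": res.ratio,
                    "p_perm": res.p_perm, "p_model": res.p_model,
                    "beta1": res.beta1, "flag": res.flag,
                })
    df = pd.DataFrame(rows)
    df["p_perm_bh"] = multipletests(df.p_perm, method="fdr_bh")[1]
    df.to_csv(args.out / "enrichment.tsv", sep="\t", index=False)
    with open(args.out / "manifest.json", "w") as fh:
        json.dump({"seed": args.seed, "n_perm": args.n_perm,
                   "thresholds": vars(QCThresholds()),
                   "n_tests": len(df)}, fh, indent=2)

    sig = df[(df.stratum == "all") & (df.p_perm <= 0.05)]
    print(f"{len(df)} comparisons; significant (pooled stratum, p_perm <= 0.05):")
    for r in sig.itertuples(index=False):
        print(f"  {r.disease} / {r.subset}: ratio {r.ratio:.2f}, p {r.p_perm:.3f}")


if __name__ == "__main__":
    main()
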