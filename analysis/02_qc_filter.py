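#!/usr/bin/env python
"""Run the QC cascade on each disease's simulated call set.

Reads the rawcnv / metrics / phenotype / mask files written by
01_simulate.py, applies sample QC, call QC, artifact masking, frequency
estimation and the rare/large selection, and writes per-disease filtered
call TSVs plus an exclusion tally.
"""

import argparse
from pathlib import Path

import pandas as pd

from cnvburden.cnv import (
    QCThresholds,
    qc_pipeline,
    read_phenotypes,
    read_rawcnv,
    read_sample_metrics,
)
from cnvburden.intervals import read_bed

DISEASES = ["narcolepsy", "hypersomnia", "panic", "autism", "alzheimer"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--out", type=Path, default=Path("results/qc"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    mask = read_bed(args.sim / "artifact_mask.bed")
    thresholds = QCThresholds()
    tallies = []
    for disease in DISEASES:
        calls = read_rawcnv(args.sim / f"{disease}.rawcnv")
        metrics = read_sample_metrics(args.sim / f"{disease}.metrics.tsv")
        phen = read_phenotypes(args.sim / f"{disease}.phenotypes.tsv")
        res = qc_pipeline(calls, metrics, mask, thresholds, n_samples=len(phen))
        rows = [
            {
                "sample_id": c.sample_id,
                "cohort": phen[c.sample_id],
                "region": c.interval.to_region_string(),
                "cnv_type": c.cnv_type,
                "n_probes": c.n_probes,
                "copy_number": c.copy_number,
                "length_bp": c.length,
                "frequency": res.frequencies[id(c)],
            }
            for c in res.test_calls
        ]
        pd.DataFrame(rows).to_csv(args.out / f"{disease}.test_calls.tsv",
                                  sep="\t", index=False)
        tally = res.exclusion_reasons()
        tally.update(disease=disease, input_calls=len(calls),
                     test_calls=len(res.test_calls),
                     excluded_samples=len(res.excluded_samples))
        tallies.append(tally)
        print(f"{disease}: {len(calls)} calls -> {len(res.test_calls)} test calls "
              f"({len(res.excluded_samples)} samples failed QC)")
    pd.DataFrame(tallies).fillna(0).to_csv(args.out / "exclusion_tally.tsv",
                                           sep="\t", index=False)


if __name__ == "__main__":
    main()
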