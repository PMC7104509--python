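"""Replicated simulation studies over the full pipeline.

Each study runs the whole chain — synthetic study generation, QC cascade,
gene-set construction, per-sample counting, inference — many times and
summarizes an operating characteristic: the type-I error of the
permutation test under the null, the recovery of a planted enrichment
effect across the four DS x ES gene categories, the exactness of the QC
cascade on a slotted planted-violation fixture, and the round-trip
recovery of the planted brain-only expression-sensitive gene set.

All studies are deterministic given their seed; replicate r of a study
seeded with ``seed`` uses generator seeds derived as ``seed + r`` offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cnv import QCThresholds, qc_pipeline
from .enrichment import GeneIndex, per_sample_counts, permutation_test, ratio_statistic
from .genesets import FOUR_GROUPS, classify_dosage, combine_categories, es_only_in_brain
from .intervals import GenomicInterval
from .simulate import (
    SimulationConfig,
    planted_qc_scenario,
    simulate_cohort,
    simulate_expression_tables,
    simulate_genes,
)

__all__ = [
    "StudyCatalog",
    "build_catalog",
    "null_calibration_study",
    "effect_recovery_study",
    "planted_qc_study",
    "es_roundtrip_study",
]

# offsets keep per-replicate generator seeds distinct across studies
_NULL_OFFSET = 100_000
_EFFECT_OFFSET = 200_000
_PERM_OFFSET = 300_000


@dataclass
class StudyCatalog:
    """A fixed gene annotation shared by the replicates of one study."""

    genes: list
    index: GeneIndex
    ds: frozenset[str]
    es: frozenset[str]
    groups: dict[str, str]
    subsets: dict[str, set[str]]
    mask: list[GenomicInterval]


def build_catalog(cfg: SimulationConfig) -> StudyCatalog:
    """Simulate genes and expression evidence once; derive the four subsets."""
    genes, classes, _ = simulate_genes(cfg)
    tissues, _ = simulate_expression_tables(cfg, genes)
    _, ds = classify_dosage(classes)
    es = es_only_in_brain(tissues)
    groups = combine_categories(ds, es, [g.gene_id for g in genes])
    subsets = {
        lab: {g for g, l in groups.items() if l == lab} for lab in FOUR_GROUPS
    }
    mask = [GenomicInterval(c, 0, 10_000) for c in cfg.chrom_sizes]
    return StudyCatalog(genes, GeneIndex(genes), ds, es, groups, subsets, mask)


def _run_pipeline(cfg: SimulationConfig, catalog: StudyCatalog, target):
    calls, metrics, phen, _ = simulate_cohort(cfg, catalog.genes, target)
    res = qc_pipeline(calls, metrics, catalog.mask, QCThresholds(), n_samples=len(phen))
    phen_kept = {s: phen[s] for s in phen if s not in res.excluded_samples}
    return res.test_calls, phen_kept


def null_calibration_study(
    seed: int,
    n_replicates: int = 500,
    n_cases: int = 200,
    n_controls: int = 200,
    alpha: float = 0.05,
    n_perm: int = 999,
) -> dict:
    """Type-I error of the permutation test under the null (no targeting).

    Each replicate simulates a fresh case/control cohort with no placement
    bias, runs the full QC cascade, counts dosage-sensitive gene overlaps
    per sample, and records whether the permutation p-value falls at or
    below ``alpha``. Returns the rejection rate and its binomial SE.
    """
    cfg0 = SimulationConfig(seed=seed)
    catalog = build_catalog(cfg0)
    rejections = 0
    for r in range(n_replicates):
        cfg = SimulationConfig(
            seed=seed + _NULL_OFFSET + r,
            n_cases=n_cases,
            n_controls=n_controls,
            rho=1.0,
        )
        test_calls, phen = _run_pipeline(cfg, catalog, frozenset())
        counts = per_sample_counts(test_calls, catalog.index, catalog.ds, phen)
        p = permutation_test(counts, n_perm=n_perm, seed=seed + _PERM_OFFSET + r)
        if p <= alpha:
            rejections += 1
    rate = rejections / n_replicates
    return {
        "rejection_rate": rate,
        "n_replicates": n_replicates,
        "alpha": alpha,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_replicates)),
    }


def effect_recovery_study(
    seed: int,
    n_replicates: int = 100,
    rho: float = 2.0,
    n_cases: int = 200,
    n_controls: int = 200,
) -> dict:
    """Recovery of a planted enrichment targeting the DS&ES gene category.

    Case CNVs are placed with relative rate ``rho`` toward windows holding
    a dosage-sensitive, brain-only expression-sensitive gene. Per
    replicate the four category ratios are computed; the study reports how
    often DS&ES has the largest ratio and the mean ratio per category.
    """
    catalog = build_catalog(SimulationConfig(seed=seed))
    target = frozenset(catalog.subsets["DS&ES"])
    wins = 0
    ratio_sums = {lab: 0.0 for lab in FOUR_GROUPS}
    for r in range(n_replicates):
        cfg = SimulationConfig(
            seed=seed + _EFFECT_OFFSET + r,
            n_cases=n_cases,
            n_controls=n_controls,
            rho=rho,
        )
        test_calls, phen = _run_pipeline(cfg, catalog, target)
        ratios = {}
        for lab, sub in catalog.subsets.items():
            counts = per_sample_counts(test_calls, catalog.index, sub, phen)
            _, _, ratio = ratio_statistic(counts)
            ratios[lab] = ratio if ratio is not None else float("inf")
            ratio_sums[lab] += ratios[lab]
        if max(ratios, key=ratios.get) == "DS&ES":
            wins += 1
    return {
        "win_fraction": wins / n_replicates,
        "n_replicates": n_replicates,
        "rho": rho,
        "mean_ratios": {k: v / n_replicates for k, v in ratio_sums.items()},
    }


def planted_qc_study(seed: int) -> dict:
    """Exactness of the QC cascade on the slotted planted-violation fixture."""
    sc = planted_qc_scenario(seed)
    res = qc_pipeline(
        sc["calls"], sc["metrics"], sc["mask"], QCThresholds(),
        n_samples=sc["n_samples"],
    )
    exp = sc["expected"]
    got_excluded = {sc["calls"].index(c): rs for c, rs in res.excluded_calls}
    kept_idx = {sc["calls"].index(c) for c in res.test_calls}
    exact = (
        set(res.excluded_samples) == set(exp["excluded_samples"])
        and set(got_excluded) == set(exp["excluded_call_idx"])
        and all(
            reason in got_excluded[i]
            for i, reason in exp["excluded_call_idx"].items()
        )
        and kept_idx == set(exp["kept_call_idx"])
    )
    return {
        "exact": exact,
        "n_planted_exclusions": len(exp["excluded_call_idx"])
        + len(exp["excluded_samples"]),
        "n_kept": len(kept_idx),
    }


def es_roundtrip_study(seed: int, n_genes: int = 5_000) -> dict:
    """Round-trip recovery of the planted brain-only ES gene set."""
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        chrom_sizes={"chr1": 2_000_000_000},
        p_es_brain_only=0.3,
    )
    genes, _, _ = simulate_genes(cfg)
    tissues, truth = simulate_expression_tables(cfg, genes)
    planted = {g for g, v in truth.items() if v["es_brain_only"]}
    recovered = es_only_in_brain(tissues, "all_expressed")
    return {
        "exact": recovered == planted,
        "n_planted": len(planted),
        "n_recovered": len(recovered),
    }
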