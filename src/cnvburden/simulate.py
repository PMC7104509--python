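"""Synthetic study generator with known ground truth.

Emulates every input the pipeline consumes: a gene annotation with
dosage-class labels at realistic genome-wide proportions, per-tissue
eQTL evidence tables (10 brain + 16 other tissues) with a configurable
fraction of brain-only expression-sensitive genes, and case/control CNV
calls with a configurable placement bias toward a target gene subset in
cases. Every stochastic choice flows from one integer seed through a
single numpy generator, so outputs are reproducible byte for byte.

Case targeting is implemented by *biased placement* (rejection sampling
toward windows containing target genes at relative rate ``rho``), not by
relabeling samples post hoc, so per-sample covariates such as the total
gene burden and total CNV length retain realistic confounding structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cnv import CNVCall, SampleQCMetrics, DELETION, DUPLICATION
from .genesets import (
    GeneRecord,
    TissueEvidence,
    NON_OHNOLOG_DUPLICATE,
    OHNOLOG_NO_SSD,
    OHNOLOG_SSD,
    SINGLETON,
)
from .intervals import GenomicInterval

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "simulate_genes",
    "simulate_expression_tables",
    "simulate_cohort",
    "planted_qc_scenario",
    "shared_region_scenario",
    "write_expression_tables",
    "write_study",
]

# genome-wide DS fraction from published ohnolog tallies (11,927 of 20,287)
P_DS_DEFAULT = 11_927 / 20_287


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults are the reference setup.

    The scaled genome (four chromosomes, 200 Mb, 800 genes) keeps the gene
    density close to genomic reality (~1 gene per 250 kb) while staying
    cheap enough for replicated simulation studies. ``rho`` is the relative
    rate at which case CNVs land on windows containing a target-subset
    gene; ``rho = 1`` is the null, ``rho >= 1`` required.
    """

    seed: int
    n_genes: int = 800
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 60_000_000,
            "chr2": 50_000_000,
            "chr3": 50_000_000,
            "chr4": 40_000_000,
        }
    )
    p_ds: float = P_DS_DEFAULT
    p_no_ssd_within_ds: float = 0.6  # DS split: ohnologs without SSD vs singletons
    p_ssd_within_dins: float = 0.5
    n_brain_tissues: int = 10
    n_other_tissues: int = 16
    p_es_brain_only: float = 0.30
    p_expressed_other: float = 0.8  # per non-brain tissue, for qualifying genes
    n_cases: int = 200
    n_controls: int = 200
    cnv_rate: float = 5.0  # mean calls per sample (post-calling scale)
    size_log_mean: float = math.log(80_000)
    size_log_sd: float = 0.8
    min_sim_size_bp: int = 5_000  # array resolution floor, below call-QC cut
    p_dup: float = 0.5
    rho: float = 1.0
    probe_per_bp: float = 1 / 2000  # array probe density
    qc_violation_rates: dict[str, float] = field(
        default_factory=lambda: {
            "sample_lrr": 0.02,
            "sample_baf": 0.02,
            "sample_count": 0.01,
            "call_low_probes": 0.03,
        }
    )

    def __post_init__(self) -> None:
        for name in ("p_ds", "p_es_brain_only", "p_dup", "p_expressed_other"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.rho < 1:
            raise ValueError(
                "rho must be >= 1 (to deplete a subset, target its complement)"
            )


@dataclass
class CohortTruth:
    """Planted ground truth for one simulated cohort."""

    sample_violations: dict[str, list[str]] = field(default_factory=dict)
    call_violations: list[tuple[int, str]] = field(default_factory=list)
    target_hits: list[bool] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_violations": self.sample_violations,
                "call_violations": self.call_violations,
                "target_hits": self.target_hits,
            }
        )


# ---------------------------------------------------------------------------
# genes


def simulate_genes(
    cfg: SimulationConfig,
) -> tuple[list[GeneRecord], dict[str, str], dict[str, bool]]:
    """Place non-overlapping genes uniformly and draw dosage classes.

    Returns the gene records, the ohnolog class table (gene_id -> class),
    and the DS ground truth. Gene counts per chromosome are proportional
    to chromosome length; placement draws sorted uniform gaps so the
    arrangement is exchangeable along each chromosome.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_genes == 0:
        return [], {}, {}
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    alloc = np.floor(cfg.n_genes * sizes / sizes.sum()).astype(int)
    for i in range(cfg.n_genes - alloc.sum()):
        alloc[i % len(alloc)] += 1

    genes: list[GeneRecord] = []
    classes: dict[str, str] = {}
    ds_truth: dict[str, bool] = {}
    gid = 0
    for chrom, n in zip(chroms, alloc):
        if n == 0:
            continue
        L = cfg.chrom_sizes[chrom]
        lengths = np.exp(rng.normal(math.log(30_000), 0.7, size=n))
        lengths = np.clip(lengths, 5_000, 300_000).astype(int)
        free = L - int(lengths.sum())
        if free < 0:
            raise ValueError(
                f"cannot place {n} genes on {chrom} without overlap; "
                "reduce n_genes or enlarge chrom_sizes"
            )
        gaps = np.sort(rng.uniform(0, free, size=n)).astype(int)
        starts = gaps + np.concatenate(([0], np.cumsum(lengths[:-1])))
        for s, l in zip(starts, lengths):
            gene_id = f"G{gid:05d}"
            gid += 1
            is_ds = rng.random() < cfg.p_ds
            if is_ds:
                cls = (
                    OHNOLOG_NO_SSD
                    if rng.random() < cfg.p_no_ssd_within_ds
                    else SINGLETON
                )
            else:
                cls = (
                    OHNOLOG_SSD
                    if rng.random() < cfg.p_ssd_within_dins
                    else NON_OHNOLOG_DUPLICATE
                )
            genes.append(
                GeneRecord(gene_id, GenomicInterval(chrom, int(s), int(s + l)), cls)
            )
            classes[gene_id] = cls
            ds_truth[gene_id] = is_ds
    return genes, classes, ds_truth


# ---------------------------------------------------------------------------
# expression tables


def simulate_expression_tables(
    cfg: SimulationConfig,
    genes: Sequence[GeneRecord],
) -> tuple[list[TissueEvidence], dict[str, dict]]:
    """Build per-tissue eGene / eQTL-gene sets with planted ES ground truth.

    A fraction ``p_es_brain_only`` of genes is constructed to satisfy the
    default brain-only definition exactly (stable in every brain tissue,
    unstable in every non-brain tissue where expressed, unstable in at
    least one non-brain tissue). Every other gene violates at least one
    clause, via one of four planted violation patterns.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    brain_ids = [f"Brain_{i}" for i in range(cfg.n_brain_tissues)]
    other_ids = [f"Other_{i}" for i in range(cfg.n_other_tissues)]
    egenes: dict[str, set[str]] = {t: set() for t in brain_ids + other_ids}
    eqtl: dict[str, set[str]] = {t: set() for t in brain_ids + other_ids}
    truth: dict[str, dict] = {}

    violations = ("brain_eqtl", "brain_unexpressed", "stable_outside", "never_unstable")
    for g in genes:
        gid = g.gene_id
        is_es = bool(rng.random() < cfg.p_es_brain_only)
        if is_es:
            for t in brain_ids:
                egenes[t].add(gid)
            expressed = rng.random(len(other_ids)) < cfg.p_expressed_other
            if not expressed.any():
                expressed[rng.integers(len(other_ids))] = True
            for t, e in zip(other_ids, expressed):
                if e:
                    egenes[t].add(gid)
                    eqtl[t].add(gid)
            truth[gid] = {"es_brain_only": True, "violation": None}
            continue

        v = violations[int(rng.integers(len(violations)))]
        if v == "brain_eqtl":
            for t in brain_ids:
                egenes[t].add(gid)
            eqtl[brain_ids[int(rng.integers(len(brain_ids)))]].add(gid)
            unstable_others = rng.random(len(other_ids)) < cfg.p_expressed_other
            for t, u in zip(other_ids, unstable_others):
                if u:
                    egenes[t].add(gid)
                    eqtl[t].add(gid)
        elif v == "brain_unexpressed":
            skip = int(rng.integers(len(brain_ids)))
            for i, t in enumerate(brain_ids):
                if i != skip:
                    egenes[t].add(gid)
            for t in other_ids:
                if rng.random() < cfg.p_expressed_other:
                    egenes[t].add(gid)
                    eqtl[t].add(gid)
        elif v == "stable_outside":
            # stable in brain, unstable somewhere outside, but also stably
            # expressed in one non-brain tissue: fails the default reading,
            # passes the lenient "any" reading
            for t in brain_ids:
                egenes[t].add(gid)
            stable_t, unstable_t = rng.choice(len(other_ids), size=2, replace=False)
            egenes[other_ids[int(stable_t)]].add(gid)
            egenes[other_ids[int(unstable_t)]].add(gid)
            eqtl[other_ids[int(unstable_t)]].add(gid)
        else:  # never_unstable: stable in brain, no unstable non-brain tissue
            for t in brain_ids:
                egenes[t].add(gid)
            if rng.random() < 0.5:
                egenes[other_ids[int(rng.integers(len(other_ids)))]].add(gid)
        truth[gid] = {"es_brain_only": False, "violation": v}

    tissues = [
        TissueEvidence(t, True, frozenset(egenes[t]), frozenset(eqtl[t]))
        for t in brain_ids
    ] + [
        TissueEvidence(t, False, frozenset(egenes[t]), frozenset(eqtl[t]))
        for t in other_ids
    ]
    return tissues, truth


def write_expression_tables(
    tissues: Sequence[TissueEvidence], outdir: str | Path
) -> None:
    """Write GTEx-v6p-style file pairs for each tissue."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t in tissues:
        with open(outdir / f"{t.tissue_id}_Analysis.v6p.egenes.txt", "w") as fh:
            fh.write("gene_id\tgene_name\tqval\n")
            for g in sorted(t.egenes):
                fh.write(f"{g}\t{g}\t0.01\n")
        with open(
            outdir / f"{t.tissue_id}_Analysis.v6p.signif_snpgene_pairs.txt", "w"
        ) as fh:
            fh.write("variant_id\tgene_id\tpval_nominal\n")
            for g in sorted(t.eqtl_genes):
                fh.write(f"var_{g}\t{g}\t1e-8\n")


# ---------------------------------------------------------------------------
# cohorts


def _draw_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    while True:
        l = int(np.exp(rng.normal(cfg.size_log_mean, cfg.size_log_sd)))
        if l >= cfg.min_sim_size_bp:
            return l


def _place_interval(
    rng: np.random.Generator, cfg: SimulationConfig, length: int
) -> GenomicInterval:
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    chrom = chroms[int(rng.choice(len(chroms), p=probs))]
    L = cfg.chrom_sizes[chrom]
    if length >= L:
        length = L - 1
    start = int(rng.integers(0, L - length))
    return GenomicInterval(chrom, start, start + length)


def simulate_cohort(
    cfg: SimulationConfig,
    genes: Sequence[GeneRecord],
    target_subset: set[str] | frozenset[str] = frozenset(),
) -> tuple[list[CNVCall], list[SampleQCMetrics], dict[str, str], CohortTruth]:
    """Simulate case/control CNV calls, sample QC metrics and phenotypes.

    Control calls are placed uniformly on the genome; case calls land on
    windows containing a target-subset gene at relative rate ``rho`` via
    rejection sampling. ``qc_violation_rates`` plant sample- and call-level
    QC failures, all recorded in the returned :class:`CohortTruth`.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    from .enrichment import GeneIndex

    index = GeneIndex(genes) if genes else None
    target = frozenset(target_subset)
    if target and index is not None:
        missing = target - index.by_id.keys()
        if missing:
            raise ValueError(f"{len(missing)} target ids not in the annotation")

    rates = cfg.qc_violation_rates
    calls: list[CNVCall] = []
    metrics: list[SampleQCMetrics] = []
    phenotypes: dict[str, str] = {}
    truth = CohortTruth()

    sample_plan = [("case", i) for i in range(cfg.n_cases)] + [
        ("control", i) for i in range(cfg.n_controls)
    ]
    for cohort, i in sample_plan:
        sid = f"{cohort}_{i:04d}"
        phenotypes[sid] = cohort
        n_calls = int(rng.poisson(cfg.cnv_rate))

        violations: list[str] = []
        lrr = float(np.clip(abs(rng.normal(0.12, 0.05)), 0.01, 0.29))
        baf = float(rng.uniform(0.0, 0.008))
        count_metric = n_calls
        if rng.random() < rates.get("sample_lrr", 0.0):
            lrr = float(rng.uniform(0.31, 0.5))
            violations.append("lrr_sd")
        if rng.random() < rates.get("sample_baf", 0.0):
            baf = float(rng.uniform(0.012, 0.05))
            violations.append("baf_drift")
        if rng.random() < rates.get("sample_count", 0.0):
            count_metric = int(rng.integers(101, 300))
            violations.append("cnv_call_count")
        if violations:
            truth.sample_violations[sid] = violations
        metrics.append(SampleQCMetrics(sid, lrr, baf, count_metric))

        biased = cohort == "case" and cfg.rho > 1 and target
        for _ in range(n_calls):
            length = _draw_length(rng, cfg)
            for _attempt in range(1000):
                iv = _place_interval(rng, cfg, length)
                hits_target = bool(
                    index is not None and index.overlapping(iv) & target
                )
                if not biased or hits_target or rng.random() < 1.0 / cfg.rho:
                    break
            cn = 3 if rng.random() < cfg.p_dup else 1
            n_probes = max(
                10, int(iv.length * cfg.probe_per_bp * np.exp(rng.normal(0, 0.2)))
            )
            call_idx = len(calls)
            if rng.random() < rates.get("call_low_probes", 0.0):
                n_probes = int(rng.integers(1, 10))
                truth.call_violations.append((call_idx, "low_probes"))
            calls.append(
                CNVCall(
                    sid,
                    iv,
                    DUPLICATION if cn > 2 else DELETION,
                    n_probes,
                    cn,
                )
            )
            truth.target_hits.append(hits_target)
    return calls, metrics, phenotypes, truth


# ---------------------------------------------------------------------------
# scenarios


def planted_qc_scenario(
    seed: int,
    n_clean_calls: int = 30,
    n_cases: int = 100,
    n_controls: int = 100,
) -> dict:
    """A slotted fixture in which each QC filter has exactly one set of victims.

    Every call occupies its own disjoint 1-Mb genome slot, so no accidental
    reciprocal overlaps can inflate frequencies; the only planted
    violations are one entity per stated rule (three QC-failing samples,
    a low-probe call, a sub-30 kb call, a masked call, a 100 kb call that
    fails the strict size selection, and a trio of identical calls whose
    frequency reaches 1.5 %). Returns calls, metrics, mask, phenotypes,
    thresholds-compatible layout, and the exact expected exclusions.
    """
    rng = np.random.default_rng(seed)
    n_samples = n_cases + n_controls
    sample_ids = [f"case_{i:04d}" for i in range(n_cases)] + [
        f"control_{i:04d}" for i in range(n_controls)
    ]
    phenotypes = {
        sid: ("case" if sid.startswith("case") else "control") for sid in sample_ids
    }

    # slot k occupies chr1:[k Mb, k Mb + 1 Mb); the mask lives far downstream
    def slot_interval(k: int, length: int) -> GenomicInterval:
        base = k * 1_000_000
        return GenomicInterval("chr1", base, base + length)

    def clean_metrics(sid: str, count: int) -> SampleQCMetrics:
        return SampleQCMetrics(
            sid, float(rng.uniform(0.05, 0.25)), float(rng.uniform(0, 0.008)), count
        )

    calls: list[CNVCall] = []
    expected: dict[str, list] = {
        "excluded_samples": [],
        "excluded_call_idx": {},
        "kept_call_idx": [],
    }
    slot = 0

    def add_call(sid: str, length: int, n_probes: int, cn: int = 3, interval=None):
        nonlocal slot
        iv = interval if interval is not None else slot_interval(slot, length)
        slot += 1
        calls.append(
            CNVCall(sid, iv, DUPLICATION if cn > 2 else DELETION, n_probes, cn)
        )
        return len(calls) - 1

    carriers = rng.permutation(n_samples)
    # clean calls: pass every filter
    for j in range(n_clean_calls):
        sid = sample_ids[int(carriers[j % n_samples])]
        length = int(rng.integers(150_000, 400_000))
        idx = add_call(sid, length, n_probes=max(10, length // 2000), cn=3)
        expected["kept_call_idx"].append(idx)

    # planted call-level violations, one per rule
    v_sids = [sample_ids[int(carriers[(n_clean_calls + k) % n_samples])] for k in range(8)]
    idx = add_call(v_sids[0], 150_000, n_probes=5)
    expected["excluded_call_idx"][idx] = "low_probes"
    idx = add_call(v_sids[1], 20_000, n_probes=15)
    expected["excluded_call_idx"][idx] = "small_size"
    idx = add_call(v_sids[2], 100_000, n_probes=50)  # exactly 100 kb: not > 100 kb
    expected["excluded_call_idx"][idx] = "size_le_100kb"
    # three identical calls in one slot: frequency 3/200 = 1.5 % >= 1 %
    common_iv = slot_interval(slot, 150_000)
    slot += 1
    for k in range(3):
        idx = add_call(v_sids[3 + k], 150_000, n_probes=75, interval=common_iv)
        expected["excluded_call_idx"][idx] = "common"
    # masked call: mask sits at 150 Mb, pad 500 kb reaches [149.5, 151.5] Mb
    mask = [GenomicInterval("chr1", 150_000_000, 151_000_000)]
    masked_iv = GenomicInterval("chr1", 149_600_000, 149_800_000)
    idx = add_call(v_sids[6], 200_000, n_probes=100, interval=masked_iv)
    expected["excluded_call_idx"][idx] = "masked"

    # planted sample-level violations, one per rule, each carrying one call
    bad_samples = {
        "bad_lrr": SampleQCMetrics("bad_lrr", 0.35, 0.005, 10),
        "bad_baf": SampleQCMetrics("bad_baf", 0.1, 0.02, 10),
        "bad_count": SampleQCMetrics("bad_count", 0.1, 0.005, 150),
    }
    metrics = [clean_metrics(sid, 2) for sid in sample_ids]
    for sid, m in bad_samples.items():
        phenotypes[sid] = "control"
        metrics.append(m)
        idx = add_call(sid, 200_000, n_probes=100)
        expected["excluded_call_idx"][idx] = "failed_sample_qc"
        expected["excluded_samples"].append(sid)

    return {
        "calls": calls,
        "metrics": metrics,
        "mask": mask,
        "phenotypes": phenotypes,
        "n_samples": n_samples,  # pooled QC-passing cohort size
        "expected": expected,
    }


def shared_region_scenario(
    seed: int,
    diseases: tuple[str, ...] = ("disease_A", "disease_B"),
    n_cases_per_disease: int = 50,
    n_controls: int = 150,
) -> dict:
    """Plant one case-only duplication locus shared by several diseases.

    Each disease contributes a handful of case duplications over a common
    locus (absent from controls), on top of sparse background calls, to
    exercise the region-discovery stages end to end.
    """
    cfg = SimulationConfig(
        seed=seed, n_cases=n_cases_per_disease, n_controls=n_controls, cnv_rate=2.0
    )
    genes, classes, _ = simulate_genes(cfg)
    # the planted locus: a 400 kb window on chr2 starting mid-chromosome
    locus = GenomicInterval("chr2", 20_000_000, 20_400_000)
    rng = np.random.default_rng(seed + 10)

    case_calls: dict[str, list[CNVCall]] = {}
    control_calls: list[CNVCall] = []
    for d_i, disease in enumerate(diseases):
        sub_cfg = SimulationConfig(
            seed=seed + 100 + d_i,
            n_cases=n_cases_per_disease,
            n_controls=0,
            cnv_rate=1.0,
            qc_violation_rates={},
        )
        calls, _, phen, _ = simulate_cohort(sub_cfg, genes)
        calls = [
            CNVCall(f"{disease}_{c.sample_id}", c.interval, c.cnv_type, c.n_probes, c.copy_number)
            for c in calls
            if c.length > 100_000
        ]
        # plant 3 carriers of the shared locus, jittered within +/- 50 kb
        for k in range(3):
            jitter = int(rng.integers(-50_000, 50_000))
            iv = GenomicInterval(
                locus.chrom, locus.start + jitter, locus.end + jitter
            )
            calls.append(
                CNVCall(f"{disease}_case_{k:04d}", iv, DUPLICATION, 200, 3)
            )
        case_calls[disease] = calls

    ctrl_cfg = SimulationConfig(
        seed=seed + 500,
        n_cases=0,
        n_controls=n_controls,
        cnv_rate=1.0,
        qc_violation_rates={},
    )
    ctrl, _, _, _ = simulate_cohort(ctrl_cfg, genes)
    control_calls = [
        c
        for c in ctrl
        if c.length > 100_000
        and not (c.interval.chrom == locus.chrom and c.cnv_type == DUPLICATION
                 and c.interval.start < locus.end + 60_000
                 and c.interval.end > locus.start - 60_000)
    ]
    return {
        "genes": genes,
        "classes": classes,
        "case_calls": case_calls,
        "control_calls": control_calls,
        "locus": locus,
    }


# ---------------------------------------------------------------------------
# full-study writer


def write_study(cfg: SimulationConfig, outdir: str | Path, diseases: Sequence[str],
                target_subset: set[str] | frozenset[str] = frozenset()) -> dict:
    """Generate and write a complete multi-disease study to ``outdir``.

    One shared control cohort and one case cohort per disease; all pipeline
    input formats are written (gene BED, ohnolog table, expression tables,
    rawcnv per disease, metrics and phenotype TSVs, artifact mask BED) plus
    a ground-truth manifest JSON.
    """
    from .cnv import write_rawcnv
    from .intervals import write_bed
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, classes, ds_truth = simulate_genes(cfg)
    tissues, es_truth = simulate_expression_tables(cfg, genes)

    with open(outdir / "genes.bed", "w") as fh:
        for g in genes:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.gene_id}\n"
            )
    pd.DataFrame(
        {"gene_id": list(classes), "dosage_class": list(classes.values())}
    ).to_csv(outdir / "ohnolog_classes.tsv", sep="\t", index=False)
    write_expression_tables(tissues, outdir / "gtex")

    # one artifact region per chromosome end (telomere-like)
    mask = [GenomicInterval(c, 0, 10_000) for c in cfg.chrom_sizes]
    write_bed(mask, outdir / "artifact_mask.bed")

    manifest: dict = {
        "seed": cfg.seed,
        "diseases": list(diseases),
        "ds_truth_n": sum(ds_truth.values()),
        "es_truth_n": sum(1 for v in es_truth.values() if v["es_brain_only"]),
    }
    for d_i, disease in enumerate(diseases):
        sub = SimulationConfig(**{**asdict(cfg), "seed": cfg.seed + 1000 + d_i})
        calls, metrics, phenotypes, truth = simulate_cohort(sub, genes, target_subset)
        write_rawcnv(calls, outdir / f"{disease}.rawcnv")
        pd.DataFrame(
            [
                {
                    "sample_id": m.sample_id,
                    "lrr_sd": m.lrr_sd,
                    "baf_drift": m.baf_drift,
                    "cnv_call_count": m.cnv_call_count,
                }
                for m in metrics
            ]
        ).to_csv(outdir / f"{disease}.metrics.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"sample_id": s, "cohort": c} for s, c in phenotypes.items()]
        ).to_csv(outdir / f"{disease}.phenotypes.tsv", sep="\t", index=False)
        manifest[disease] = {
            "n_calls": len(calls),
            "n_planted_sample_violations": len(truth.sample_violations),
            "n_planted_call_violations": len(truth.call_violations),
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
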