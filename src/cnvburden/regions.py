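"""Patient-only CNV region discovery and candidate-region tests.

Starting from the rare large test calls, each disease's case footprint is
the merged union of its case call intervals with every base covered by a
same-type control call subtracted. Regions where footprints of two or more
diseases overlap become shared candidates: the *core* is the multi-disease
overlap and the *span* is the union footprint of the contributing calls.

Candidates are screened with three criteria — (i) overlap with previously
reported regions, (ii) sharing between >= 2 diseases, (iii) more than six
dosage-sensitive genes — and two exact tests: a two-sided Fisher test of
the region's dosage-sensitive gene density against the genome-wide ratio,
and a one-sided Fisher test of case vs control carrier counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .cnv import CNVCall
from .enrichment import GeneIndex
from .genesets import DS_CLASSES
from .intervals import (
    GenomicInterval,
    merge_intervals,
    overlap_bp,
    subtract_intervals,
)

__all__ = [
    "TypedFootprint",
    "RegionCandidate",
    "patient_only_regions",
    "shared_regions",
    "fisher_exact_2x2",
    "ds_density_fisher",
    "carrier_fisher",
    "count_region_genes",
    "count_carriers",
    "annotation_overlap_counts",
    "classify_candidates",
    "DS_GENOME_DEFAULT",
    "TOTAL_GENOME_DEFAULT",
]

# genome-wide dosage-classified gene tallies (DS and DS+DinS)
DS_GENOME_DEFAULT = 11_927
TOTAL_GENOME_DEFAULT = 11_927 + 8_360

MIN_FRAGMENT_BP = 1_000
DS_RICH_THRESHOLD = 6  # "more than six" => >= 7


@dataclass(frozen=True)
class TypedFootprint:
    interval: GenomicInterval
    cnv_type: str  # "deletion" or "duplication"


@dataclass
class RegionCandidate:
    region: GenomicInterval  # overlap core
    span: GenomicInterval  # union footprint
    diseases: set[str]
    cnv_type: str  # "deletion", "duplication", or "mixed"
    carriers: dict[str, int] = field(default_factory=dict)
    ds_genes: list[str] = field(default_factory=list)
    total_genes: int = 0
    previously_reported: bool = False  # criterion (i)
    shared: bool = False  # criterion (ii)
    ds_rich: bool = False  # criterion (iii)
    fisher_density_p: float | None = None
    fisher_carrier_p: float | None = None

    def __post_init__(self) -> None:
        if overlap_bp(self.region, self.span) != self.region.length:
            raise ValueError("core must lie within the span")


def patient_only_regions(
    case_calls: Sequence[CNVCall],
    control_calls: Sequence[CNVCall],
    min_fragment_bp: int = MIN_FRAGMENT_BP,
) -> list[TypedFootprint]:
    """Case-only footprint of one disease.

    Per CNV type: merge the case call intervals, subtract every base
    covered by a control call of the same type, and drop fragments shorter
    than ``min_fragment_bp``.
    """
    out: list[TypedFootprint] = []
    for cnv_type in ("deletion", "duplication"):
        case_ivs = [c.interval for c in case_calls if c.cnv_type == cnv_type]
        if not case_ivs:
            continue
        ctrl_ivs = [c.interval for c in control_calls if c.cnv_type == cnv_type]
        for frag in subtract_intervals(case_ivs, ctrl_ivs):
            if frag.length >= min_fragment_bp:
                out.append(TypedFootprint(frag, cnv_type))
    return out


def shared_regions(
    footprints: Mapping[str, Sequence[TypedFootprint]],
    min_diseases: int = 2,
) -> list[RegionCandidate]:
    """Regions covered by case-only footprints of >= ``min_diseases`` diseases.

    Each maximal interval with multi-disease coverage becomes a candidate;
    its span is the union of every contributing footprint, its type is
    ``mixed`` when contributors disagree.
    """
    if len(footprints) < 2:
        raise ValueError("need footprints from >= 2 diseases")
    by_chrom: dict[str, list[tuple[str, TypedFootprint]]] = {}
    for disease, fps in footprints.items():
        for fp in fps:
            by_chrom.setdefault(fp.interval.chrom, []).append((disease, fp))

    candidates: list[RegionCandidate] = []
    for chrom, entries in sorted(by_chrom.items()):
        # sweep: coverage by number of distinct diseases
        events: list[tuple[int, int, str]] = []
        for disease, fp in entries:
            events.append((fp.interval.start, 1, disease))
            events.append((fp.interval.end, -1, disease))
        events.sort(key=lambda e: (e[0], e[1]))
        active: dict[str, int] = {}
        cores: list[GenomicInterval] = []
        open_start: int | None = None
        for pos, delta, disease in events:
            n_before = sum(1 for v in active.values() if v > 0)
            if n_before >= min_diseases and open_start is None:
                pass
            active[disease] = active.get(disease, 0) + delta
            n_after = sum(1 for v in active.values() if v > 0)
            if open_start is None and n_after >= min_diseases:
                open_start = pos
            elif open_start is not None and n_after < min_diseases:
                if pos > open_start:
                    cores.append(GenomicInterval(chrom, open_start, pos))
                open_start = None
        cores = merge_intervals(cores)
        for core in cores:
            contributing = [
                (d, fp)
                for d, fp in entries
                if overlap_bp(fp.interval, core) > 0
            ]
            diseases = {d for d, _ in contributing}
            types = {fp.cnv_type for _, fp in contributing}
            span = GenomicInterval(
                chrom,
                min(fp.interval.start for _, fp in contributing),
                max(fp.interval.end for _, fp in contributing),
            )
            candidates.append(
                RegionCandidate(
                    region=core,
                    span=span,
                    diseases=diseases,
                    cnv_type=types.pop() if len(types) == 1 else "mixed",
                )
            )
    return candidates


def _check_table(a: int, b: int, c: int, d: int) -> None:
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in 2x2 table [[{a},{b}],[{c},{d}]]")


_TIE_SLACK = 1 + 1e-7  # relative tolerance when comparing tied pmf values


def _hypergeom_pmf(a: int, b: int, c: int, d: int) -> tuple[np.ndarray, int, int]:
    """Hypergeometric pmf over the support of a 2x2 table's margins.

    Returns ``(pmf, lo, a)`` where ``pmf[k - lo]`` is the probability of
    top-left cell ``k`` given the table's fixed margins.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return np.exp(logpmf), lo, a


def fisher_exact_2x2(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher exact p for a 2x2 table by direct hypergeometric summation.

    ``two-sided`` sums every outcome no more probable than the observed one
    (with a tiny relative slack for floating-point ties, the usual
    convention); ``greater`` is the upper tail on the top-left cell.
    """
    _check_table(a, b, c, d)
    pmf, lo, obs = _hypergeom_pmf(a, b, c, d)
    if alternative == "two-sided":
        mask = pmf <= pmf[obs - lo] * _TIE_SLACK
        p = 1.0 if mask.all() else float(pmf[mask].sum())
    elif alternative == "greater":
        p = 1.0 if obs == lo else float(pmf[obs - lo :].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(p, 1.0)


def ds_density_fisher(
    ds_in_region: int,
    total_in_region: int,
    ds_genome: int = DS_GENOME_DEFAULT,
    total_genome: int = TOTAL_GENOME_DEFAULT,
) -> float:
    """Two-sided Fisher exact p for region DS density vs the genome-wide ratio.

    The table contrasts the region's DS / dosage-insensitive counts with
    the remainder of the genome; genome totals include the region.
    """
    nonds_in = total_in_region - ds_in_region
    a, b = ds_in_region, nonds_in
    c = ds_genome - ds_in_region
    d = (total_genome - ds_genome) - nonds_in
    if total_in_region == 0:
        _check_table(a, b, c, d)
        return 1.0
    return fisher_exact_2x2(a, b, c, d, alternative="two-sided")


def carrier_fisher(
    case_carriers: int,
    n_cases: int,
    control_carriers: int,
    n_controls: int,
) -> float:
    """One-sided Fisher exact p for carrier excess in cases."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("cohort sizes must be positive")
    a, b = case_carriers, n_cases - case_carriers
    c, d = control_carriers, n_controls - control_carriers
    return fisher_exact_2x2(a, b, c, d, alternative="greater")


def count_region_genes(
    candidate: RegionCandidate,
    genes: GeneIndex,
    use_span: bool = True,
) -> None:
    """Tally DS and total genes overlapping the candidate (>= 1 bp).

    Genes are counted against the span (the drawn union footprint) by
    default; ``use_span=False`` counts against the core only.
    """
    target = candidate.span if use_span else candidate.region
    hit_ids = genes.overlapping(target)
    candidate.total_genes = len(hit_ids)
    candidate.ds_genes = sorted(
        g for g in hit_ids if genes.by_id[g].dosage_class in DS_CLASSES
    )
    candidate.ds_rich = len(candidate.ds_genes) > DS_RICH_THRESHOLD


def count_carriers(
    candidate: RegionCandidate,
    calls_by_cohort: Mapping[str, Sequence[CNVCall]],
) -> None:
    """Count samples per cohort with a matching-type call overlapping the core."""
    for cohort, calls in calls_by_cohort.items():
        carriers = {
            c.sample_id
            for c in calls
            if (candidate.cnv_type == "mixed" or c.cnv_type == candidate.cnv_type)
            and overlap_bp(c.interval, candidate.region) > 0
        }
        candidate.carriers[cohort] = len(carriers)


def annotation_overlap_counts(
    candidates: Sequence[RegionCandidate],
    annotations: Sequence[GenomicInterval],
    use_span: bool = True,
) -> list[int]:
    """Number of annotation entries (e.g. curated CNV reports) overlapping
    each candidate by >= 1 bp. A reporting join only; no fetching."""
    out = []
    for cand in candidates:
        target = cand.span if use_span else cand.region
        out.append(sum(1 for a in annotations if overlap_bp(target, a) > 0))
    return out


def classify_candidates(
    candidates: Sequence[RegionCandidate],
    reported_regions: Sequence[GenomicInterval],
    ds_genome: int = DS_GENOME_DEFAULT,
    total_genome: int = TOTAL_GENOME_DEFAULT,
    carrier_counts: Mapping[int, tuple[int, int, int, int]] | None = None,
) -> tuple[list[RegionCandidate], list[RegionCandidate]]:
    """Apply the three screening criteria and split candidates into lists.

    Flags: (i) >= 1 bp overlap of the span with a previously reported
    region; (ii) footprints of >= 2 diseases; (iii) more than six
    dosage-sensitive genes. ``shared`` = (i and ii) or (ii and iii);
    ``disease-specific`` = (iii and not i) or carrier-test p < 0.05.

    ``carrier_counts`` optionally maps ``id(candidate)`` to
    ``(case_carriers, n_cases, control_carriers, n_controls)`` for the
    carrier Fisher test; without it the carrier clause cannot fire.
    """
    shared_list: list[RegionCandidate] = []
    specific_list: list[RegionCandidate] = []
    for cand in candidates:
        cand.previously_reported = any(
            overlap_bp(cand.span, r) > 0 for r in reported_regions
        )
        cand.shared = len(cand.diseases) >= 2
        cand.ds_rich = len(cand.ds_genes) > DS_RICH_THRESHOLD
        if cand.total_genes:
            cand.fisher_density_p = ds_density_fisher(
                len(cand.ds_genes), cand.total_genes, ds_genome, total_genome
            )
        if carrier_counts and id(cand) in carrier_counts:
            cand.fisher_carrier_p = carrier_fisher(*carrier_counts[id(cand)])
        i, ii, iii = cand.previously_reported, cand.shared, cand.ds_rich
        if (i and ii) or (ii and iii):
            shared_list.append(cand)
        carrier_sig = (
            cand.fisher_carrier_p is not None and cand.fisher_carrier_p < 0.05
        )
        if (iii and not i) or carrier_sig:
            specific_list.append(cand)
    return shared_list, specific_list
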