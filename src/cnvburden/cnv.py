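"""CNV call ingestion and the quality-control cascade.

The pipeline applied to raw array CNV calls is, in order:

1. sample-level QC (log R ratio SD, B-allele-frequency drift, call count),
2. call-level QC (probe support and minimum size),
3. artifact-region masking (centromeres/telomeres/immunoglobulin loci,
   each padded by 500 kb; any overlapping call is dropped whole),
4. cohort frequency estimation by same-type reciprocal-overlap carrier
   counting on the pooled case+control cohort,
5. the rare/large selection used by every downstream test
   (size > 100 kb and frequency < 1 %).

Every exclusion carries machine-readable reasons so planted-truth fixtures
can assert that each filter removes exactly what it should.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from intervaltree import IntervalTree

from .intervals import GenomicInterval, merge_intervals, overlap_bp, parse_region

__all__ = [
    "CNVCall",
    "SampleQCMetrics",
    "QCThresholds",
    "read_rawcnv",
    "write_rawcnv",
    "read_sample_metrics",
    "read_phenotypes",
    "filter_samples",
    "filter_calls",
    "apply_artifact_mask",
    "call_frequency",
    "select_test_set",
    "qc_pipeline",
    "QCResult",
]

logger = logging.getLogger(__name__)

DELETION = "deletion"
DUPLICATION = "duplication"

_CN_RE = re.compile(r"state\d+,cn=(\d+)")


@dataclass(frozen=True)
class CNVCall:
    """One copy-number event in one sample."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str  # "deletion" or "duplication"
    n_probes: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.copy_number == 2:
            raise ValueError("copy number 2 is diploid, not a CNV")
        expected = DELETION if self.copy_number < 2 else DUPLICATION
        if self.cnv_type != expected:
            raise ValueError(
                f"cnv_type {self.cnv_type!r} inconsistent with cn={self.copy_number}"
            )

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class SampleQCMetrics:
    sample_id: str
    lrr_sd: float
    baf_drift: float
    cnv_call_count: int

    def __post_init__(self) -> None:
        if self.lrr_sd < 0:
            raise ValueError("lrr_sd must be >= 0")
        if not 0 <= self.baf_drift <= 1:
            raise ValueError("baf_drift must be in [0, 1]")
        if self.cnv_call_count < 0:
            raise ValueError("cnv_call_count must be >= 0")


@dataclass(frozen=True)
class QCThresholds:
    """All knobs of the QC cascade; defaults match standard array practice.

    The wording of every rule is an *exclusion* condition (a sample is
    dropped when lrr_sd > 0.3, a call when it has < 10 probes, ...), so the
    kept side of each comparison is inclusive of the boundary except the
    size/frequency selection which is strict (> 100 kb, < 1 %).
    """

    max_lrr_sd: float = 0.3
    max_baf_drift: float = 0.01
    max_cnv_count: int = 100
    min_probes: int = 10
    min_call_size_bp: int = 30_000
    test_min_size_bp: int = 100_000
    max_frequency: float = 0.01
    mask_pad_bp: int = 500_000
    reciprocal_overlap: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")
        if self.test_min_size_bp < self.min_call_size_bp:
            raise ValueError("test_min_size_bp must be >= min_call_size_bp")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QCThresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _cnv_type_for(cn: int) -> str:
    return DELETION if cn < 2 else DUPLICATION


def read_rawcnv(path: str | Path) -> list[CNVCall]:
    """Read PennCNV ``rawcnv`` text output.

    Expected whitespace-separated layout per line::

        chr4:39500375-39784412  numsnp=120  length=284,038  state5,cn=3  SAMPLE  startsnp=...  endsnp=...

    Coordinates are 1-based inclusive and converted to the internal 0-based
    half-open convention. Diploid records (``cn=2``) are rejected and
    logged, not returned. A malformed line raises with its line number.
    """
    calls: list[CNVCall] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: expected >= 5 fields")
            try:
                interval = parse_region(parts[0])
                numsnp = int(parts[1].split("=", 1)[1].replace(",", ""))
                m = _CN_RE.match(parts[3])
                if m is None:
                    raise ValueError(f"cannot parse copy-number token {parts[3]!r}")
                cn = int(m.group(1))
                sample_id = parts[4]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{ln}: malformed rawcnv line: {exc}") from exc
            if cn == 2:
                logger.warning("%s:%d: rejected diploid record (cn=2)", path, ln)
                continue
            calls.append(
                CNVCall(sample_id, interval, _cnv_type_for(cn), numsnp, cn)
            )
    return calls


def write_rawcnv(calls: Iterable[CNVCall], path: str | Path) -> None:
    """Write calls back out in the PennCNV rawcnv text layout."""
    with open(path, "w") as fh:
        for c in calls:
            state = 5 if c.copy_number > 2 else 2
            fh.write(
                f"{c.interval.to_region_string()}\t"
                f"numsnp={c.n_probes}\tlength={c.length:,}\t"
                f"state{state},cn={c.copy_number}\t{c.sample_id}\t"
                f"startsnp=.\tendsnp=.\n"
            )


def read_sample_metrics(path: str | Path) -> list[SampleQCMetrics]:
    """Read a sample-metrics TSV (sample_id, lrr_sd, baf_drift, cnv_call_count)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        SampleQCMetrics(
            str(r.sample_id), float(r.lrr_sd), float(r.baf_drift), int(r.cnv_call_count)
        )
        for r in df.itertuples(index=False)
    ]


def read_phenotypes(path: str | Path) -> dict[str, str]:
    """Read a phenotype TSV (sample_id, cohort) into a mapping."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {str(r.sample_id): str(r.cohort) for r in df.itertuples(index=False)}


def filter_samples(
    metrics: Sequence[SampleQCMetrics], t: QCThresholds
) -> tuple[list[str], dict[str, list[str]]]:
    """Apply sample-level QC.

    A sample is excluded iff ``lrr_sd > max_lrr_sd`` OR
    ``baf_drift > max_baf_drift`` OR ``cnv_call_count > max_cnv_count``;
    each exclusion carries every rule it triggered.
    """
    seen: set[str] = set()
    kept: list[str] = []
    excluded: dict[str, list[str]] = {}
    for m in metrics:
        if m.sample_id in seen:
            raise ValueError(f"duplicate sample_id {m.sample_id!r}")
        seen.add(m.sample_id)
        reasons = []
        if m.lrr_sd > t.max_lrr_sd:
            reasons.append("lrr_sd")
        if m.baf_drift > t.max_baf_drift:
            reasons.append("baf_drift")
        if m.cnv_call_count > t.max_cnv_count:
            reasons.append("cnv_call_count")
        if reasons:
            excluded[m.sample_id] = reasons
        else:
            kept.append(m.sample_id)
    return kept, excluded


def filter_calls(
    calls: Sequence[CNVCall], t: QCThresholds
) -> tuple[list[CNVCall], list[tuple[CNVCall, list[str]]]]:
    """Call-level QC: keep calls with >= ``min_probes`` probes and
    length >= ``min_call_size_bp``."""
    kept: list[CNVCall] = []
    excluded: list[tuple[CNVCall, list[str]]] = []
    for c in calls:
        reasons = []
        if c.n_probes < t.min_probes:
            reasons.append("low_probes")
        if c.length < t.min_call_size_bp:
            reasons.append("small_size")
        (kept.append(c) if not reasons else excluded.append((c, reasons)))
    return kept, excluded


def apply_artifact_mask(
    calls: Sequence[CNVCall],
    mask: Sequence[GenomicInterval],
    pad: int = 500_000,
) -> tuple[list[CNVCall], list[CNVCall]]:
    """Drop any call overlapping an artifact region expanded by ``pad`` bp.

    Calls are dropped whole (not trimmed). An empty mask is the identity
    transform, with a warning.
    """
    if not mask:
        logger.warning("empty artifact mask: no calls removed")
        return list(calls), []
    expanded = merge_intervals([m.expand(pad) for m in mask])
    tree_by_chrom: dict[str, IntervalTree] = {}
    for m in expanded:
        tree_by_chrom.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end)
    kept: list[CNVCall] = []
    dropped: list[CNVCall] = []
    for c in calls:
        tree = tree_by_chrom.get(c.interval.chrom)
        if tree is not None and tree.overlaps(c.interval.start, c.interval.end):
            dropped.append(c)
        else:
            kept.append(c)
    return kept, dropped


def call_frequency(
    calls: Sequence[CNVCall],
    n_samples: int,
    reciprocal: float = 0.5,
) -> list[float]:
    """Cohort frequency of each call by same-type reciprocal-overlap carriers.

    A sample carries call ``c`` when it has a call ``d`` of the same type
    with ``overlap_bp(c, d) >= reciprocal * length(c)``. The call's own
    sample counts once, so every frequency is in ``[1/n_samples, 1]``.
    Calls must be pooled across all cohorts surviving QC.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for i, c in enumerate(calls):
        trees.setdefault((c.interval.chrom, c.cnv_type), IntervalTree()).addi(
            c.interval.start, c.interval.end, i
        )
    freqs: list[float] = []
    for c in calls:
        need = reciprocal * c.length
        carriers = {c.sample_id}
        tree = trees.get((c.interval.chrom, c.cnv_type))
        if tree is not None:
            for hit in tree.overlap(c.interval.start, c.interval.end):
                d = calls[hit.data]
                if d.sample_id in carriers:
                    continue
                if overlap_bp(c.interval, d.interval) >= need:
                    carriers.add(d.sample_id)
        freqs.append(len(carriers) / n_samples)
    return freqs


def select_test_set(
    calls: Sequence[CNVCall],
    frequencies: Sequence[float],
    t: QCThresholds,
) -> tuple[list[CNVCall], list[tuple[CNVCall, list[str]]]]:
    """Rare/large selection: keep calls with size > ``test_min_size_bp``
    (strict) and frequency < ``max_frequency`` (strict)."""
    if len(calls) != len(frequencies):
        raise ValueError("calls and frequencies must align")
    kept: list[CNVCall] = []
    excluded: list[tuple[CNVCall, list[str]]] = []
    for c, f in zip(calls, frequencies):
        reasons = []
        if c.length <= t.test_min_size_bp:
            reasons.append("size_le_100kb")
        if f >= t.max_frequency:
            reasons.append("common")
        (kept.append(c) if not reasons else excluded.append((c, reasons)))
    return kept, excluded


@dataclass
class QCResult:
    """Full provenance of one run of the QC cascade."""

    test_calls: list[CNVCall]
    kept_samples: list[str]
    excluded_samples: dict[str, list[str]] = field(default_factory=dict)
    excluded_calls: list[tuple[CNVCall, list[str]]] = field(default_factory=list)
    frequencies: dict[int, float] = field(default_factory=dict)

    def exclusion_reasons(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for _, reasons in self.excluded_calls:
            for r in reasons:
                tally[r] = tally.get(r, 0) + 1
        return tally


def qc_pipeline(
    calls: Sequence[CNVCall],
    metrics: Sequence[SampleQCMetrics],
    mask: Sequence[GenomicInterval],
    t: QCThresholds,
    n_samples: int | None = None,
) -> QCResult:
    """Run the full cascade: samples -> calls -> mask -> frequency -> selection.

    ``n_samples`` defaults to the number of QC-passing samples and is the
    denominator of the frequency estimate (the pooled cohort size).
    """
    kept_samples, excluded_samples = filter_samples(metrics, t)
    kept_set = set(kept_samples)
    excluded_calls: list[tuple[CNVCall, list[str]]] = [
        (c, ["failed_sample_qc"]) for c in calls if c.sample_id not in kept_set
    ]
    surviving = [c for c in calls if c.sample_id in kept_set]

    surviving, dropped = filter_calls(surviving, t)
    excluded_calls.extend(dropped)

    surviving, masked = apply_artifact_mask(surviving, mask, t.mask_pad_bp)
    excluded_calls.extend((c, ["masked"]) for c in masked)

    n = n_samples if n_samples is not None else len(kept_samples)
    freqs = call_frequency(surviving, n, t.reciprocal_overlap)
    test_calls, too_common = select_test_set(surviving, freqs, t)
    excluded_calls.extend(too_common)

    result = QCResult(
        test_calls=test_calls,
        kept_samples=kept_samples,
        excluded_samples=excluded_samples,
        excluded_calls=excluded_calls,
        frequencies={id(c): f for c, f in zip(surviving, freqs)},
    )
    assert len(test_calls) + len(excluded_calls) == len(calls)
    return result
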