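"""Case-control gene-overlap burden and enrichment tests.

For each sample we count, over its rare large CNVs, how many genes of a
tested subset the calls overlap (``s``) and how many annotated genes in
total (``t``); the counting is per call, so a gene hit by two calls of the
same sample counts twice. The headline statistic is the ratio of the mean
subset count in cases over controls; its significance is assessed by a
one-sided label-permutation test, with a logistic-regression analogue
(cohort ~ s adjusted for total burden ``t`` and/or total CNV length ``L``)
reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .cnv import CNVCall
from .genesets import GeneRecord
from .intervals import GenomicInterval, overlap_bp

__all__ = [
    "GeneIndex",
    "SampleGeneCounts",
    "EnrichmentResult",
    "ModelResult",
    "genes_overlapped",
    "per_sample_counts",
    "ratio_statistic",
    "permutation_test",
    "model_test",
    "run_enrichment",
]

STRATA = ("all", "deletion", "duplication")


class GeneIndex:
    """Interval-tree index over gene records for fast overlap queries."""

    def __init__(self, genes: Sequence[GeneRecord]):
        self.genes = list(genes)
        self.by_id = {g.gene_id: g for g in self.genes}
        if len(self.by_id) != len(self.genes):
            raise ValueError("duplicate gene ids")
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.interval.chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end, g.gene_id
            )

    def overlapping(self, interval: GenomicInterval, border: int = 0) -> set[str]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return set()
        start = max(0, interval.start - border)
        end = interval.end + border
        return {hit.data for hit in tree.overlap(start, end)}

    def __len__(self) -> int:
        return len(self.genes)


def genes_overlapped(
    call: CNVCall, genes: GeneIndex | Sequence[GeneRecord], border: int = 0
) -> set[str]:
    """Gene ids whose interval shares >= 1 bp with the call expanded by ``border``."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.overlapping(call.interval, border)


@dataclass(frozen=True)
class SampleGeneCounts:
    sample_id: str
    cohort: str  # "case" or "control"
    s: int  # subset genes overlapped (per call)
    t: int  # all annotated genes overlapped (per call)
    L: float  # total CNV length, kb
    stratum: str = "all"

    def __post_init__(self) -> None:
        if not 0 <= self.s <= self.t:
            raise ValueError("need 0 <= s <= t")
        if self.L < 0:
            raise ValueError("L must be >= 0")


@dataclass
class ModelResult:
    beta1: float | None
    p_model: float | None
    converged: bool
    flag: str | None = None


@dataclass
class EnrichmentResult:
    subset_name: str
    stratum: str
    mean_case: float
    mean_control: float
    ratio: float | None
    p_perm: float
    p_model: float | None
    beta1: float | None
    n_perm: int
    seed: int
    flag: str | None = None


def per_sample_counts(
    calls: Sequence[CNVCall],
    genes: GeneIndex,
    subset: Iterable[str],
    phenotypes: Mapping[str, str],
    stratum: str = "all",
    border: int = 0,
    distinct: bool = False,
) -> list[SampleGeneCounts]:
    """Per-sample subset and total gene counts over the test CNVs.

    Every sample in ``phenotypes`` appears in the output; samples without
    test calls get ``s = t = 0``. By default counting is per call (PLINK
    count semantics); ``distinct=True`` counts each gene once per sample.
    Subset ids unknown to the gene index are ignored with a warning.
    """
    import logging

    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    subset = set(subset)
    unknown = subset - genes.by_id.keys()
    if unknown:
        logging.getLogger(__name__).warning(
            "%d subset gene ids not in the annotation; ignored", len(unknown)
        )
        subset -= unknown

    per_sample: dict[str, list[CNVCall]] = {sid: [] for sid in phenotypes}
    for c in calls:
        if stratum != "all" and c.cnv_type != stratum:
            continue
        if c.sample_id not in per_sample:
            raise KeyError(f"call sample {c.sample_id!r} missing from phenotypes")
        per_sample[c.sample_id].append(c)

    out: list[SampleGeneCounts] = []
    for sid, cohort in phenotypes.items():
        sample_calls = per_sample[sid]
        if distinct:
            hit_all: set[str] = set()
            for c in sample_calls:
                hit_all |= genes.overlapping(c.interval, border)
            s, t = len(hit_all & subset), len(hit_all)
        else:
            s = t = 0
            for c in sample_calls:
                hits = genes.overlapping(c.interval, border)
                s += len(hits & subset)
                t += len(hits)
        L = sum(c.length for c in sample_calls) / 1000.0
        out.append(SampleGeneCounts(sid, cohort, s, t, L, stratum))
    return out


def _cohort_arrays(counts: Sequence[SampleGeneCounts]) -> tuple[np.ndarray, np.ndarray]:
    s = np.array([c.s for c in counts], dtype=float)
    is_case = np.array([c.cohort == "case" for c in counts], dtype=bool)
    return s, is_case


def _safe_ratio(mean_case: float, mean_control: float) -> float:
    if mean_control > 0:
        return mean_case / mean_control
    return math.inf if mean_case > 0 else 1.0


def ratio_statistic(
    counts: Sequence[SampleGeneCounts],
) -> tuple[float, float, float | None]:
    """Mean subset counts per cohort and their case/control ratio.

    Zero-CNV samples are included in the means. When the control mean is
    zero the ratio is undefined and returned as ``None`` (the permutation
    test remains computable).
    """
    s, is_case = _cohort_arrays(counts)
    if is_case.all() or (~is_case).all():
        raise ValueError("both cohorts must be non-empty")
    mean_case = float(s[is_case].mean())
    mean_control = float(s[~is_case].mean())
    ratio = mean_case / mean_control if mean_control > 0 else None
    return mean_case, mean_control, ratio


def permutation_test(
    counts: Sequence[SampleGeneCounts],
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> float:
    """One-sided label-permutation p-value for the case/control ratio.

    Cohort labels are shuffled ``n_perm`` times holding counts fixed;
    ``p = (1 + #{permuted ratio >= observed}) / (1 + n_perm)``. With
    ``alternative="two-sided"`` the comparison is on ``|log ratio|``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    s, is_case = _cohort_arrays(counts)
    n = len(s)
    n_case = int(is_case.sum())
    if n_case == 0 or n_case == n:
        raise ValueError("both cohorts must be non-empty")

    total = s.sum()
    obs = _safe_ratio(float(s[is_case].mean()), float(s[~is_case].mean()))

    rng = np.random.default_rng(seed)
    # vectorized label shuffles: the first n_case order statistics of random
    # keys give a uniform random subset of size n_case per permutation.
    # Sampling from the sorted counts makes the p-value a function of the
    # count multiset alone (invariant to relabeling at a fixed seed).
    s_sorted = np.sort(s)
    keys = rng.random((n_perm, n))
    case_idx = np.argpartition(keys, n_case - 1, axis=1)[:, :n_case]
    case_sums = s_sorted[case_idx].sum(axis=1)
    mean_case = case_sums / n_case
    mean_ctrl = (total - case_sums) / (n - n_case)
    with np.errstate(divide="ignore", invalid="ignore"):
        perm = np.where(
            mean_ctrl > 0, mean_case / mean_ctrl, np.where(mean_case > 0, np.inf, 1.0)
        )
    if alternative == "greater":
        hits = int(np.sum(perm >= obs))
    elif alternative == "two-sided":
        with np.errstate(divide="ignore"):
            hits = int(np.sum(np.abs(np.log(perm)) >= abs(math.log(obs))))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + hits) / (1 + n_perm)


def model_test(
    counts: Sequence[SampleGeneCounts],
    covariates: Sequence[str] = ("t",),
) -> ModelResult:
    """Logistic regression of cohort on the subset count ``s``.

    ``covariates`` selects adjustment columns from ``{"t", "L"}`` (total
    gene burden and total CNV length). Returns the coefficient on ``s``
    and a one-sided p-value for enrichment in cases (beta1 > 0).
    Rank-deficient designs (e.g. subset = all genes, where s == t) and
    separation are flagged rather than reported as converged.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    for cov in covariates:
        if cov not in ("t", "L"):
            raise ValueError(f"unknown covariate {cov!r}")
    s, is_case = _cohort_arrays(counts)
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need >= 2 samples per cohort")
    cols = [np.ones_like(s), s]
    for cov in covariates:
        cols.append(
            np.array([getattr(c, cov) for c in counts], dtype=float)
        )
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return ModelResult(None, None, False, flag="collinear")
    try:
        fit = sm.Logit(is_case.astype(float), X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return ModelResult(None, None, False, flag="separation")
    if not fit.mle_retvals.get("converged", False):
        return ModelResult(None, None, False, flag="non_convergence")
    beta1 = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se == 0 or se > 1e4 * max(abs(beta1), 1e-12):
        return ModelResult(beta1, None, False, flag="unstable_se")
    from scipy.stats import norm

    p_one = float(norm.sf(beta1 / se))
    return ModelResult(beta1, p_one, True)


def run_enrichment(
    counts: Sequence[SampleGeneCounts],
    subset_name: str,
    stratum: str = "all",
    n_perm: int = 999,
    seed: int = 0,
    covariates: Sequence[str] = ("t",),
) -> EnrichmentResult:
    """Ratio statistic, permutation p, and model p for one comparison."""
    mean_case, mean_control, ratio = ratio_statistic(counts)
    p_perm = permutation_test(counts, n_perm=n_perm, seed=seed)
    model = model_test(counts, covariates=covariates)
    return EnrichmentResult(
        subset_name=subset_name,
        stratum=stratum,
        mean_case=mean_case,
        mean_control=mean_control,
        ratio=ratio,
        p_perm=p_perm,
        p_model=model.p_model,
        beta1=model.beta1,
        n_perm=n_perm,
        seed=seed,
        flag="ratio_undefined" if ratio is None else model.flag,
    )
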