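# Methods

## Coordinate model

All internal coordinates are 0-based half-open. PennCNV-style locus
strings (`chrN:start-end`) are 1-based inclusive and converted at the
parse boundary (`start − 1`, `end` unchanged); BED input is already
half-open. Chromosome labels are normalized to `chrN` at parse time. Sex
chromosomes are carried through unchanged; nothing in the pipeline
excludes them, and a user who wants autosome-only analysis can filter the
call list before the cascade.

## QC cascade

Stages run in a fixed order — sample QC, call QC, artifact masking,
frequency estimation, rare/large selection — though the two per-call
filters commute (asserted by test). All thresholds live in one
`QCThresholds` record (YAML-loadable):

| parameter | default | kept side |
|---|---|---|
| LRR SD | 0.3 | ≤ 0.3 |
| BAF drift | 0.01 | ≤ 0.01 |
| CNV calls per sample | 100 | ≤ 100 |
| probes per call | 10 | ≥ 10 |
| call size | 30 kb | ≥ 30 kb |
| artifact pad | 500 kb | no overlap with padded mask |
| test-set size | 100 kb | **> 100 kb (strict)** |
| test-set frequency | 1 % | **< 1 % (strict)** |

Every threshold is worded as an exclusion condition, so boundary values
survive the first six filters and fail the last two. Masked calls are
dropped whole rather than trimmed — conservative for burden testing, and
the simpler semantics given that the artifact loci are call-quality
artifacts rather than biology.

**CNV frequency** has no universal definition for fragmented calls; we
count carriers by same-type overlap covering ≥ 50 % of the target call's
length (configurable `reciprocal_overlap`), on the pooled case + control
cohort (within-cohort counting is available by passing per-cohort calls
and `n_samples`). The carrier's own sample always counts once, so
frequencies live in `[1/n, 1]`; note the 1 % filter therefore removes
*everything* when the pooled cohort has ≤ 100 samples.

## Gene sets

Dosage sensitivity is a lookup into the four-class ohnolog table; genes
absent from the table are `unclassified` and excluded from both DS and
DinS (they still count as "total genes" in overlap tallies).

For brain-only expression sensitivity, per-tissue evidence is pure set
membership: eGene lists give expression, significant-pair lists give
eQTL presence; q-values are not re-thresholded. "Stable" = expressed
without eQTL; "unstable" = expressed with ≥ 1 eQTL; an unexpressed gene
is neither. The brain clause is unambiguous (stable in **all** brain
tissues); the non-brain clause ("unstable in the other tissues") admits
three readings, all implemented:

- `all_expressed` (default): unstable in every non-brain tissue *where
  expressed*, and unstable in ≥ 1 non-brain tissue. This is the only
  reading that is simultaneously literal about "only in brain" and
  well-defined for genes not expressed everywhere.
- `all_strict`: unstable in all 16 non-brain tissues.
- `any`: unstable in ≥ 1 non-brain tissue.

The readings are nested (`all_strict ⊆ all_expressed ⊆ any`), which the
property tests assert on random evidence tables. The four combined
categories partition the universe of genes carrying both annotations;
genes lacking either annotation are kept for DS-only tests but excluded
from combined-category tests.

## Enrichment testing

Gene–CNV overlap is ≥ 1 bp with an optional symmetric border (default
0 kb; 20 kb reproduces PLINK-style reach). Counting is per call: a gene
hit by two calls of one sample counts twice (PLINK count semantics); a
distinct-gene mode is available. Zero-CNV samples stay in the cohort
means. With subset = all genes, `s ≡ t` and the machinery reduces to
total burden.

Inference is one-sided toward enrichment in cases throughout (two-sided
by flag):

- **Permutation test** (headline): cohort labels are shuffled holding
  counts fixed; `p = (1 + #{ratio* ≥ ratio}) / (1 + n_perm)` with
  `n_perm = 999` by default. The null draws are made from the *sorted*
  count vector so the p-value at a fixed seed depends only on the count
  multiset, not on sample ordering. Ratios with a zero denominator are
  taken as +∞ when the numerator is positive and 1 when both means are
  zero, which makes degenerate cohorts compare sanely and guarantees
  `p = 1` when all counts are equal.
- **Model test**: logistic regression of cohort on `s`, adjusted by
  choice of `t` (total gene burden, default) and/or `L` (total CNV
  length in kb); one-sided Wald p on the `s` coefficient.
  Rank-deficient designs, separation, non-convergence and exploding
  standard errors are flagged, not reported as converged p-values.

No multiple-testing correction is applied per test (results are reported
per comparison, as is conventional for these burden analyses); the
enrichment driver appends a Benjamini–Hochberg column for transparency.

## Region discovery

Per disease and CNV type, the case-only footprint is
`merge(case intervals) − coverage(control intervals of the same type)`,
with fragments < 1 kb discarded as unreportable slivers. Shared
candidates are the maximal intervals covered by footprints of ≥ 2
diseases (the *core*), with the *span* being the union of contributing
footprints; contributor types disagreeing ⇒ `mixed`. DS and total genes
are tallied against the span by ≥ 1 bp overlap (core-only counting by
flag), since the drawn union region is what a reader inspects; carriers
are counted against the core. "More than six DS genes" is read strictly
as ≥ 7.

The DS-density test is a two-sided Fisher exact test of the region's
DS : DinS split against the genome-wide remainder (defaults 11,927 :
8,360); the carrier test is one-sided toward case excess (regions are
case-only by construction). Both are computed by direct hypergeometric
summation in log-factorial space with a 1e-7 relative tie tolerance in
the two-sided rule — the standard "sum of outcomes no more probable than
observed" convention — and are cross-checked in the tests against
scipy's implementation and against an integer-exact enumeration oracle
(agreement < 1e-12 on every 2×2 table with N ≤ 60).

Candidate screening: shared = (reported ∧ shared-by-≥2) ∨
(shared-by-≥2 ∧ DS-rich); disease-specific = (DS-rich ∧ ¬reported) ∨
(carrier p < 0.05). The previously-reported flag is a ≥ 1 bp overlap of
the span with a user-supplied literature BED; curating that list is out
of scope.

## Synthetic data

The generator's defaults define the reference study conditions:

- **Genome**: 4 chromosomes, 200 Mb, 800 non-overlapping genes
  (≈ 1 gene / 250 kb, near genomic density). Gene lengths are lognormal
  (median 30 kb, clipped to 5–300 kb); placement uses sorted uniform
  gaps, so arrangements are exchangeable.
- **Dosage classes**: DS probability 11,927/20,287 ≈ 0.588, split 60/40
  between ohnologs-without-SSD and singletons; DinS split evenly.
- **Expression**: 10 brain + 16 non-brain tissues; 30 % of genes planted
  as brain-only ES (close to the ≈ 0.30 fraction seen in real eQTL
  catalogues); qualifying genes are expressed in 80 % of non-brain
  tissues. Non-ES genes each violate exactly one clause of the
  definition (brain eQTL, missing brain expression, a stable non-brain
  tissue, or no unstable non-brain tissue), so the default-mode
  round trip is an exact identity and the lenient mode a strict
  superset.
- **Cohorts**: 200 cases / 200 controls; Poisson(5) calls per sample;
  lognormal lengths (median 80 kb, log-SD 0.8, floor 5 kb) chosen so a
  realistic share of calls fails the 30 kb filter and straddles the
  100 kb selection; 50 % duplications; probes ≈ 1/2 kb with 20 %
  lognormal noise. Case targeting: a candidate placement not overlapping
  a target gene is accepted with probability 1/ρ (rejection sampling),
  giving relative placement rate ρ on target windows while keeping
  covariates (`t`, `L`) honestly confounded. ρ < 1 is rejected — deplete
  a subset by targeting its complement.
- **Planted QC violations**: default rates 2 %/2 %/1 % for the three
  sample rules and 3 % for low-probe calls, recorded per entity in the
  ground-truth manifest.

Exact planted-truth recovery through the QC cascade is asserted on a
dedicated *slotted* scenario in which every call occupies a disjoint
1 Mb slot (so no accidental reciprocal overlap can trip the frequency
rule) and each filter has exactly one planted victim set. Under fully
random placement, accidental overlap doubletons can legitimately exceed
the 1 % frequency cut, so for the stochastic generator only the planted
⊆ excluded direction is asserted.

What the generator does **not** emulate: LRR/BAF signal itself, linkage
disequilibrium, recurrent mutation hotspots, gene-length/dosage-class
correlation, and population structure. Passing tests therefore
demonstrate the pipeline's statistical behaviour under clean placement
models, not robustness to array artifacts beyond the planted kinds.

## Simulation studies and problem sizes

`cnvburden.studies` runs the replicated experiments: 500 null cohorts
for type-I-error calibration (rejection at α = 0.05 stays inside the
exact binomial 95 % band; the permutation test is mildly conservative
because count ties propagate into ratio ties) and 100 cohorts at ρ = 2
targeting DS&ES for effect recovery (the DS&ES category shows the
largest of the four category ratios in ~98 % of replicates; spillover
onto the other categories is limited because a diverted case call also
*removes* background hits elsewhere). Both studies fix the gene catalog
across replicates and redraw cohorts; replicate seeds are derived from
the study seed by fixed offsets. These sizes — 800 genes, 400 samples,
500/100 replicates — were chosen as the smallest configuration at which
the binomial bands of the two studies are informative.

## Known limitations

- Frequency filtering is undefined (everything removed) for pooled
  cohorts of ≤ 100 samples; the pipeline does not special-case this.
- The carrier Fisher test treats carriers as independent; recurrent CNVs
  in related samples would violate this (relatedness QC is assumed done
  upstream).
- Region spans can be much larger than cores when contributing calls are
  long; DS tallies over spans are correspondingly liberal. Core-only
  counting is one flag away.
- The logistic model test can be unstable at small counts; flagged
  results should be read as "no adjusted estimate", with the permutation
  p standing alone.
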