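# Methods

This note documents the models, conventions and numerical choices behind
`isoshift`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic benchmarks do and do not
demonstrate.

## Coordinate conventions

GTF input is 1-based and inclusive on both ends; every spliced (mRNA)
offset inside the package is 0-based. Exons are stored in transcript
(5'→3') orientation regardless of how the input orders them; minus-strand
exon sequences are reverse-complemented on extraction. The last exon-exon
junction of a transcript is reported as the mRNA offset of the first base
of the last exon. Zero-length, duplicated or overlapping exons, and
transcripts mixing strands or chromosomes, are rejected as invariant
violations rather than repaired.

## ORF annotation and the 50-nt rule

Assembled transcripts usually lack CDS records, so the open reading frame
is anchored to the reference annotation: among all reference start codons
whose first base is exonic in the query transcript (with ≥ 3 nt of spliced
sequence downstream), the most upstream one — the smallest mRNA offset —
wins. By default only reference records of the same gene are searched; a
genome-wide scope is available for id-mismatched assemblies. The frame
fixed by that start is translated to the first in-frame stop (TAA/TAG/TGA;
codons containing N never terminate). Internal upstream ATGs are not
considered: the ORF is annotation-anchored, not predicted de novo.

A transcript is **PTC-positive** when the stop codon's end lies strictly
more than `ptc_distance` nt (default 50) upstream of the last exon-exon
junction; a distance of exactly 50 nt, and any mono-exonic transcript, is
PTC-negative. The distance is measured from the base immediately after the
stop codon; because the biological rule is sometimes quoted from the
stop's first base, which shifts the boundary by 2 nt, `ptc_distance` is a
parameter rather than a constant. Transcripts with no compatible start or
no in-frame stop are **NO_ORF**: they carry no UTR lengths and are excluded
from all length analyses (a 3'UTR is undefined without a stop).

## Expression processing

* **Quantile normalization** (units: normFPKM) equalizes the per-sample
  distributions: the reference is the across-sample mean of the sorted
  columns, each value is replaced by the reference value at its
  within-column rank, and tied values receive the mean of the reference
  values over their tied ranks (the behaviour of the standard
  preprocessCore implementation). Note a consequence of tie averaging:
  columns containing ties do not reproduce the reference multiset exactly —
  they conserve its total instead. Normalization happens at transcript
  level, before gene summation.
* **Gene expression** is the per-sample sum of member transcripts;
  condition-level expression is the arithmetic mean over that condition's
  replicate columns (the replicate-pooling summary is the mean throughout;
  per-replicate analysis is not implemented).
* **Isoform fraction** IFᵢ = eᵢ/e_G per condition; genes with zero
  condition expression are excluded, never divided.
* **Filters.** Genes below 1 (strictly) in either condition mean are
  dropped; "expressed isoform" means a condition mean strictly above the
  cutoff; multi-isoform genes have ≥ 2 such isoforms. Values exactly at
  the cutoff survive the gene filter but do not count as "above" for the
  primary-expression classes, which therefore label them `neither`.
* **Primary expression**: above cutoff in one genotype and below it in the
  other, evaluated on condition means.
* **MA summaries** use A = log2(mean expression + ε) and
  M = log2((KO + ε)/(WT + ε)) with ε = 0.01 normFPKM by default (the
  pseudocount only matters near zero); the per-ORF-class trend is a
  centred 50-point rolling mean of M along A.
* The built-in **differential-expression test** (two-sided rank-sum on
  log-values + Benjamini–Hochberg) is plumbing for simulated data with
  enough replicates. With 2 replicates per condition the exact two-sided
  rank-sum p-value can never fall below 1/3, so no call can pass an FDR of
  0.05 — by design the pipeline consumes externally produced DE tables
  (e.g. cuffdiff output) whenever they exist, and the generator emits
  truth-derived calls for synthetic runs.

## Usage subsets and weighted 3'UTR length

The per-gene average weighted 3'UTR length is Σ lᵢ·eᵢ/e_G (the
`weighted_mean` variant, default): the isoform fractions already sum to 1,
so the quantity is a proper weighted mean bounded by [min lᵢ, max lᵢ]. A
`printed_formula` variant that additionally divides by the isoform count n
is provided because the formula is sometimes written with that extra
division; it equals `weighted_mean`/n and is not a mean of lengths — the
default is the self-consistent variant.

Subset classification uses |dIF| ≥ 0.20 in absolute percentage points of
isoform fraction (not relative change): a = no changing isoform, b = only
increases, c = only decreases, d = both. For the weighted-3'UTR shift the
gene universe is restricted to genes whose ORF-bearing isoforms are all
above the cutoff in both conditions (with ≥ 2 of them); NO_ORF isoforms
are removed and their expression subtracted from e_G before weighting, so
fractions are renormalized over the isoforms that have a defined 3'UTR.
Expression stratification bins genes at 1, 5 and 50 normFPKM — low,
midrange, high.

## Statistical tests

Rank comparisons are two-sided Mann-Whitney U tests: the exact null
distribution when both groups have ≤ 50 observations and the pooled sample
is tie-free, otherwise the normal approximation with tie and continuity
correction. Percentiles use linear interpolation between order statistics.
Pairwise length comparisons report raw and BH-adjusted p-values side by
side. The exact branch is validated in the test suite against a
brute-force enumeration of all rank assignments for group sizes ≤ 6, and
the binomial consistency checks use Clopper-Pearson intervals.

## Synthetic scenarios

The generator emulates the data structure the analysis assumes, not
RNA-seq reads:

* **Structure.** Each gene's isoforms share a 5'UTR (lognormal, median
  150 nt, σ = 0.5, floor 20) and ORF (uniform 300–3000 nt, multiple of 3,
  single planted stop) spread over 1–4 exons with 100–500 nt introns. APA
  isoforms differ only in final-exon 3' extent (3'UTR lognormal, median
  400 nt, σ = 0.7, floor 60); one isoform per multi-isoform gene gains an
  extra 500–2000 nt (the long-APA variant). PTC isoforms are 3'UTR-splice
  variants: an extra junction is placed 51–500 nt downstream of the stop,
  the remaining 3'UTR sitting in a downstream exon. This keeps the 3'UTR
  length distribution of PTC and non-PTC isoforms exchangeable, so PTC
  content is independent of which isoform is longest — the property that
  makes the "no PTC enrichment among upregulated transcripts" null check
  meaningful.
* **Expression.** Gene expression is lognormal (median 8, σ = 1.2 —
  broad enough to populate the sub-1, midrange 5–50 and high strata);
  isoform fractions are Dirichlet (concentration 2, a realistic usage
  spread). In KO, each effect gene (20% of multi-isoform genes by default)
  moves `planted_dif` = +0.25 of usage onto its longest-3'UTR isoform,
  other isoforms shrinking proportionally, so gene totals are conserved in
  expectation. Replicates (default 2 per condition) get multiplicative
  lognormal noise (σ = 0.2, unit mean) and per-sample scale factors drawn
  from U(0.7, 1.4) — the latter exist purely to exercise quantile
  normalization.
* **Truth-derived DE calls.** Expected fold changes from the planted
  fractions, thresholded at 1.5-fold, stand in for the external DE table a
  real run would consume.

What passing these benchmarks shows: the coordinate arithmetic, the PTC
rule, the normalization and the shift statistics are exact or correctly
powered on data with the assumed structure. What it does not show:
robustness to assembly artifacts, fragment-level biases, incomplete
reference annotation, or isoform families more complex than APA plus one
3'UTR splice — none of which the generator models.

## Known limitations

* **Cutoff-conditioning bias.** The "primarily expressed" classes are
  defined by condition means straddling the expression cutoff, so under
  replicate noise the class-conditional mean dIF is biased away from zero
  even with no true effect (≈ ±0.03 at σ = 0.2 with 2 replicates):
  a transcript lands in `KO_only` partly *because* its KO draw was high.
  The unconditioned classes (`both`, `neither`) are unbiased. Class-level
  dIF summaries for the cutoff-crossing classes should therefore be read
  against a matched null simulation, not against zero.
* Selenocysteine recoding, stop-codon readthrough, uORFs and de novo
  coding-potential prediction are out of scope; ORFs exist only where the
  reference annotation places a compatible start.
* The weighted-3'UTR gene universe ("all isoforms above cutoff in both
  conditions") deliberately drops genes whose shifted isoform is absent in
  one condition; strong on/off switches are captured by the
  primary-expression analysis instead.
* Problem sizes in the test and acceptance runs (500–1,000 genes,
  10,000-transcript oracle sweeps) were chosen as the smallest scales at
  which every statistic is well-powered; all scenario parameters are
  configurable upward.
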