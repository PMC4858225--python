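# isoshift

Isoform-level analysis of 3'UTR length control and premature-termination-codon
(PTC) content in a WT-vs-knockout transcriptome comparison — the computational
signature of losing UPF2-dependent nonsense-mediated mRNA decay (NMD).

When NMD is disabled in a tissue, two things can happen to the transcriptome:
the canonical outcome (PTC-bearing splice variants accumulate) and the
non-canonical one (isoforms with long 3'UTRs accumulate, because long 3'UTRs
are themselves an NMD trigger). `isoshift` quantifies both from standard
inputs — assembled transcript models (GTF), a reference annotation carrying
CDS records, a genome FASTA and a transcript × sample expression table — and
is aimed at RNA-seq analysts studying alternative polyadenylation, NMD
substrates, or differential transcript usage.

## What it computes

**ORF / PTC annotation.** Each assembled transcript is anchored to the most
upstream compatible reference start codon, the reading frame is translated to
the first in-frame stop, and the transcript is classified by the 50-nt rule:

> PTC-positive ⇔ the stop codon ends more than 50 nt upstream of the last
> exon-exon junction of the spliced transcript.

This yields per-transcript 5'UTR, ORF and 3'UTR lengths.

**Isoform fractions and their shifts.** Expression is quantile-normalized
across samples (units: normFPKM), summed to gene level
(e_G = Σᵢ eᵢ), and each isoform's fraction IFᵢ = eᵢ / e_G is computed per
condition; dIF = IF(KO) − IF(WT). Genes below 1 normFPKM in either condition
are dropped, and analyses use genes with ≥ 2 expressed isoforms.

**Average weighted 3'UTR length.** For a gene with isoform 3'UTR lengths
l₁…lₙ and expressions e₁…eₙ,

    L_w = Σᵢ lᵢ · eᵢ / e_G

computed per condition; Δ L_w = L_w(KO) − L_w(WT). Genes are split into four
usage subsets by whether any isoform changes its fraction by ≥ 20 percentage
points: (a) none, (b) only increases, (c) only decreases, (d) both; subsets
b–d are compared to a with two-sided Mann-Whitney tests, overall and
stratified by gene expression (1–5, 5–50, > 50 normFPKM).

**Classes and tallies.** Transcripts above 1 normFPKM in one genotype and
below 1 in the other are "primarily expressed" in that genotype; length
distributions and dIF shifts are summarized per class, and PTC content is
tallied across differential-expression groups (up/down/non) with MA-plot
summaries.

A synthetic-data generator (`isoshift.simulate`) builds fully self-contained
scenarios — genome, reference + assembled GTFs, replicate expression tables
and a ground-truth table — with shared-ORF APA isoform families, a
configurable fraction of PTC-positive 3'UTR-splice variants, and a planted
KO-specific usage gain on long-3'UTR isoforms, so the entire pipeline is
testable without any external data.

## Worked example

```python
from isoshift import (ScenarioConfig, simulate_scenario, IsoformUsageModel,
                      annotate_transcripts, weighted_utr_length)
from isoshift.orf import annotations_to_frame

# one gene, two isoforms: l = (100, 500) nt, e = (3, 1) FPKM
print(weighted_utr_length([100, 500], [3, 1]))   # -> 200.0

sc = simulate_scenario(ScenarioConfig(n_genes=200, seed=3))
ann = annotations_to_frame(
    annotate_transcripts(sc.transcripts, sc.reference, sc.genome))
results = IsoformUsageModel(sc.expression, ann, sc.de_calls).fit()
print(results.summary())
```

prints (abridged):

```
Primary-expression classes (transcripts with ORF, analyzed genes):
   KO_only: n=   21  mean dIF=+0.167  median dIF=+0.226  p(WT vs KO IF)=0.000106
   WT_only: n=   25  mean dIF=-0.095  median dIF=-0.073  p(WT vs KO IF)=0.00348
      both: n=  286  mean dIF=-0.002  median dIF=-0.005  p(WT vs KO IF)=0.601
Median 3'UTR length (nt) by class:
   KO_only: 1451
   WT_only: 428
      both: 544
Gene usage subsets (|dIF| >= 0.2): a=44  b=9  c=0  d=5
Delta weighted 3'UTR (KO - WT, nt) by subset:
  b: n=    9  median=+217.6  p vs a=8.57e-09
```

Transcripts that become expressed only in the knockout carry a far longer
median 3'UTR than those lost from it (1451 vs 428 nt here), and genes whose
isoform usage shifts upward (subset b) gain weighted 3'UTR length — the
planted NMD-loss signature, read back out by the pipeline.

The same analysis runs from the shell:

```bash
isoshift simulate --out-dir scenario --n-genes 200 --seed 3
isoshift annotate --gtf scenario/assembled.gtf --reference-gtf scenario/reference.gtf \
                  --genome scenario/genome.fa --out annotation.tsv
isoshift usage --expression scenario/expression.tsv --samples scenario/samples.yaml \
               --annotation annotation.tsv --de scenario/de_calls.tsv --out-dir analysis
isoshift report --out-dir analysis
```

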