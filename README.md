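# u1seq

Downstream analysis of bulk RNA-seq from *Drosophila melanogaster* strains
in which a single U1 snRNA gene has been deleted.

The fly genome carries five U1 snRNA genes — *21D* on chromosome arm 2L
and *82Eb*, *95Ca*, *95Cb*, *95Cc* on 3R.  Three of them encode the
canonical 164-nt U1; *95Cc* carries a U123C change and *82Eb* a G134U
change in or near the Sm-protein binding site.  Because U1 snRNP both
initiates splicing at 5′ splice sites and suppresses premature
cleavage/polyadenylation on nascent transcripts (telescripting), deleting
one U1 gene perturbs transcription output and 3′-end formation genome-wide.
`u1seq` implements the downstream analyses such a six-strain design needs
(wild type + five deletion strains, replicated larval RNA-seq), plus a
fully seeded synthetic-data generator with ground truth so every stage is
testable without sequencing data.

## What it computes

| stage | method | screen |
|---|---|---|
| differential expression | median-of-ratios normalization; NB Wald contrast with gene-pooled method-of-moments dispersion | fold change > 2 and BH FDR < 0.05 |
| DEG structure | per-strain down/up sets; common / unique / shared-by-*k* overlap partition | — |
| feature enrichment | Fisher exact per bin vs transcribed background (intron count 0 / 1–2 / ≥3; gene length < 2 kb; mean intron length < 0.5 kb; GC quartiles) | BH within feature |
| 3′-UTR APA | per-sample PDUI (fraction of transcripts using the distal polyA site) from an exhaustive two-mean change-point fit of UTR coverage; ΔPDUI = KO − WT with a Welch t across replicates | \|ΔPDUI\| > 0.25 and FDR < 0.05; ΔPDUI > 0 ⇒ distal, < 0 ⇒ proximal |
| U1-binding sites | 5′SS-like 9-mer scan (`CAG|GTAAGT`, invariant GT, ≤1 mismatch, or a PWM) counted in ±200-nt windows around both polyA sites; proximal/distal hit-load comparison per event direction (aggregate ratio + Wilcoxon signed-rank) | — |
| trans-splicing | isoform usage = isoform-specific junction reads / common-exon reads (depth cancels; CPM reported for context), KO/WT ratio with Welch t | BH within gene |
| qPCR validation | ΔCt = Ct(target) − Ct(*gapdh*), ΔΔCt vs WT mean, fold = 2^(−ΔΔCt); distal/common amplicon double ratio for APA validation | Ct < 40 required |

In PDUI terms, coverage upstream of the proximal cleavage site carries
both the short and the long 3′-UTR isoform while coverage beyond it
carries only the long one, so for a two-segment fit with segment means
m₁, m₂ the estimator is PDUI = clamp(m₂/m₁, 0, 1) with the breakpoint at
the fitted change point.

## Worked example

Simulate the default study design (300 genes, six strains × 3 replicates)
and run every stage:

```python
from u1seq import PipelineConfig, SimConfig, run_pipeline

report = run_pipeline(PipelineConfig(simulate=SimConfig(seed=20231102)))
print(report["degs"]["82Ebdel"])
print(report["apa_events"]["82Ebdel"])
print(report["u1_site_ratios"]["distal_activated"])
print(report["recovery"]["pdui_recovery"])
```

prints

```
{'down': 24, 'up': 6, 'tested': 300, 'ns': 270}
{'distal': 45, 'proximal': 50, 'ns': 32}
{'n_events': 134, 'ratio_smoothed': 269.0, 'wilcoxon_p': 5.463547495741806e-31, 'low_n': False}
{'n_pairs': 2286, 'fraction_within_tol': 0.9996, 'median_abs_error': 0.005}
```

Reading the numbers: in the simulated *82Eb* deletion, 24 genes pass the
down-regulation screen against 6 up (the generator plants a 4:1
down-bias), and 95 3′-UTR APA events pass the ΔPDUI screen.  Among
distal-activated events — genes whose knockout response is a shift toward
the distal polyA site — the ±200-nt windows around the proximal sites
carry overwhelmingly more U1-binding sites than the distal windows
(smoothed aggregate ratio 269, signed-rank p ≈ 5e-31), while
proximal-activated events carry balanced site counts (ratio 1.0).  PDUI
estimates land within 0.05 of the planted truth for 99.96% of
gene × sample pairs.

The same pipeline runs from files (FASTA + GTF + polyA BED + count TSV +
bedGraph coverage + junction TSV) via the CLI:

```bash
u1seq simulate --seed 20231102 --n-genes 300 dataset/
u1seq run dataset/ --out results/        # report.json + stage TSVs
u1seq qpcr ct.tsv --target gfp --wt-samples WT_1,WT_2,WT_3
u1seq registry                           # the five U1 loci and variants
```

## Layout

```
src/u1seq/core_io.py            domain types, GTF/BED/bedGraph/FASTA/TSV I/O,
                                U1 locus registry
src/u1seq/synthetic_data.py     seeded six-strain dataset generator + truth
src/u1seq/diffexpr.py           normalization, NB screen, DEG overlaps
src/u1seq/feature_enrichment.py gene-feature strata and Fisher tests
src/u1seq/apa.py                PDUI change-point fit, event calling,
                                motif scanning, window ratios
src/u1seq/trans_splicing.py     junction-based isoform usage
src/u1seq/validation_report.py  qPCR arithmetic, pipeline, run report
src/u1seq/cli.py                command-line interface
docs/methods.md                 model and design notes
```
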