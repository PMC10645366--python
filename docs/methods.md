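# Methods

This note records the models behind each stage, the defaults that matter,
what the synthetic data does and does not emulate, and the numerical
choices a maintainer would otherwise have to reverse-engineer.

## Study design and coordinates

The unit of analysis is a six-condition bulk RNA-seq design: a wild-type
*Drosophila* strain and five strains each lacking one U1 snRNA gene
(labels `21Ddel`, `82Ebdel`, `95Cadel`, `95Cbdel`, `95Ccdel`), with ≥2
replicates per strain (default 3).  All interval arithmetic is 0-based
half-open internally; GTF is converted losslessly from/to its 1-based
inclusive dialect, BED and bedGraph are native 0-based half-open.
Minus-strand coverage is stored in genomic orientation and reversed on
demand for transcript-oriented work.  "Proximal" polyA site always means
nearer the stop codon, so on the minus strand the proximal coordinate is
the numerically larger one.

The U1 locus registry encodes the five fly U1 genes (21D on 2L; 82Eb,
95Ca, 95Cb, 95Cc on 3R), the 164-nt snRNA length, and the two sequence
variants (95Cc U123C, 82Eb G134U, both in or near the Sm binding site).
No computation uses the variants; they are reference facts with tests.

## Differential expression

Normalization is median-of-ratios: per gene, counts are divided by the
geometric mean across samples (genes containing any zero are excluded from
the reference set) and the per-sample factor is the median of those
ratios.

The test is a deliberately simple negative-binomial contrast, not a
reimplementation of any published DE package.  Per gene and group, a
method-of-moments dispersion is computed as α = max(0, (s² − m)/m²) and
pooled across the two groups.  Because a 3-replicate moment estimate is
extremely noisy, dispersions are then pooled **across genes**: genes are
split into 20 mean-quantile bins and each gene receives its bin's median
raw dispersion (a trended estimate; below 100 genes a single global median
is used).  When the sample variance does not exceed the mean the estimate
collapses to 0 — the Poisson limit.  The statistic is a Wald z on the
log ratio of pseudocounted normalized group means,

    z = [ln(m_KO + ½) − ln(m_WT + ½)] / se,
    se² = Σ_g [ 1/(n_g (m_g + ½)) + α/n_g ],

with a standard-normal reference.  The gene-pooled dispersion is what
makes the normal reference defensible at n = 3: with a per-gene-only
dispersion the statistic needs a t(4) reference and loses roughly a
quarter of its power against 4-fold effects, while with pooling the null
p-values are near-uniform (KS ≈ 0.05–0.07 against U(0,1) on a 2000-gene
null simulation) and the full screen's false-call rate stays ≤0.1%.

Genes with normalized base mean < 1 are excluded from testing (FDR set
to 1); the same ≥1 floor over wild-type samples defines the "transcribed"
background for enrichment.  The screen itself is fixed by the published
thresholds: |fold change| > 2 (strict) and BH FDR < 0.05.  Log2 fold
changes use pseudocount 0.5 so zero-count genes stay finite.  The overlap
partition classifies every gene in the union of per-strain DEG sets by
membership multiplicity; "common" is the 5-strain class and "unique" the
1-strain classes.

## Feature enrichment

Genes are binned by intron count (0, 1–2, ≥3), span length (< 2 kb vs
≥ 2 kb), mean intron length (< 0.5 kb vs ≥ 0.5 kb, intronless as its own
bin) and GC quartiles.  Gene length is TSS→TES span and GC content is
computed over the span rather than the spliced transcript — the choice is
arbitrary but fixed and documented; "short introns" is read as a
gene-level property via the mean intron length.  Each DEG set (down and up
analyzed separately) is tested per bin against the transcribed background
with a two-sided Fisher exact test on the 2×2 in-bin × DEG table; odds
ratios get a Haldane +0.5 correction when a cell is empty, and a DEG set
equal to its background is reported as trivially unenriched (OR 1, p 1).
BH adjustment runs within each feature.  A histogram-density export is
provided for distribution-style plots.

## 3′-UTR APA and PDUI

For a two-polyA-site gene, coverage over the 3′-UTR upstream of the
proximal cleavage site contains short + long isoforms and coverage beyond
it only the long isoform.  PDUI (percentage of distal site usage) is
estimated per sample by an exhaustive two-mean change-point fit on the
transcript-oriented depth vector: every interior breakpoint is scored by
the residual sum of squares of a two-segment piecewise-constant fit
(computed with cumulative sums), ties break toward the most proximal
breakpoint, and PDUI = clamp(m₂/m₁, 0, 1).  A fit with m₂ ≥ m₁ (flat or
rising) is flagged degenerate and reported as PDUI 1.  The estimator is
scale-invariant by construction.  Eligibility floors: mean UTR depth ≥ 5,
UTR length ≥ 100 nt, non-zero coverage; these are pipeline choices, not
published values.

Events are called per strain: ΔPDUI is the difference of replicate-mean
PDUIs (KO − WT), the p-value a two-sided Welch t on replicate PDUIs
(identically constant groups are given p = 1 for equal means, p = 0
otherwise), BH across genes.  Direction follows the published screen:
distal iff ΔPDUI > 0.25 ∧ FDR < 0.05, proximal iff ΔPDUI < −0.25 ∧
FDR < 0.05, else ns.  Events are classified `three_prime_utr` when both
sites fall inside the annotated 3′-UTR, otherwise
`terminal_exon_intron`.

"U1-binding site" is modelled as a 5′-splice-site-like 9-mer: three exonic
positions plus the first six intronic positions, consensus `CAG|GTAAGT`,
the GT dinucleotide invariant and at most one mismatch over the other
seven positions (both the consensus string and the mismatch budget are
configurable; a PWM mode with a log-odds threshold is available).  Hits
are counted in ±200-nt windows around each polyA site; when the two sites
are closer than 400 nt a hit can be counted in both windows — window
membership is per site by design.  The direction-group comparison reports,
for distal-activated and proximal-activated events separately, the
aggregate Σproximal/Σdistal hit ratio, a Haldane-smoothed version (+0.5
each side, finite when one side is empty), and a Wilcoxon signed-rank test
(normal approximation, zeros dropped) on per-event count differences;
groups under 5 events are flagged low-n without a p-value.

The qPCR validation ratio for an APA event is
(distal/common)_strain / (distal/common)_WT, where the distal amplicon
covers only the long-UTR isoform and the common amplicon covers both.

## Trans-splicing

Isoform usage is specific-junction reads over common-exon reads,
J_i / common.  Sequencing depth appears in both numerator and denominator
of any per-million formulation and cancels, so usage is depth-free; CPM of
the specific reads is reported alongside purely for cross-sample context.
Which junctions are isoform-specific and which are common is taken from
the junction table's label column (annotation-driven, no junction
discovery).  Strain comparisons are per-isoform KO/WT ratios of mean
usage with Welch t-tests, BH within gene.

## qPCR arithmetic

ΔCt = Ct(target) − Ct(reference, default *gapdh*); ΔΔCt subtracts the
mean wild-type ΔCt; fold = 2^(−ΔΔCt), the standard comparative-Ct
transform.  Records with Ct ≥ 40 cycles are rejected with a diagnostic.
Group tests are Welch t on replicate ΔCts; report tables annotate
p < 0.05/0.01/0.001 as \*/\*\*/\*\*\*.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, with
one master seed feeding four independent child streams (genome,
expression, coverage, junctions) so regenerating one output leaves the
others untouched.

* **Genome/annotation** — 300 genes by default, round-robin across four
  synthetic chromosome arms, random strands, intron-count mixture
  0.29/0.36/0.35 over {0, 1–2 (uniform), ≥3 (uniform 3..8)} roughly
  matching the ~29% intronless share of the fly genome; gene spans
  1–6 kb, introns 60–800 nt, base composition at GC 0.43.  Every gene has
  an annotated 3′-UTR (300–600 nt); 40% get two polyA sites, the proximal
  at 45% of the UTR, the distal at the UTR end.  Infeasible geometry
  (introns that cannot fit the span) raises a config error.
* **Expression** — NB counts with variance m + αm² (α = 0.05 default;
  α → 0 degenerates to Poisson), lognormal baseline means (median 150),
  lognormal per-sample size factors (σ = 0.12).  Per deletion strain a
  configurable fraction of genes (4–10%, largest in the 82Eb- and
  95Cb-like strains) gets |log2FC| = 2, 80% down; down-regulated genes
  are drawn so the 1–2-intron stratum reaches twice its background share,
  mirroring the enrichment the analysis must detect.
* **3′-UTR coverage** — per-base Poisson around depth D (default 50×,
  ±15% per replicate) before the proximal site and PDUI × D after it.
  APA genes carry a response class: `distal_shift` genes (low baseline
  PDUI) gain +0.5 PDUI in the three affected strains, `proximal_shift`
  genes (high baseline) lose 0.5, `null` genes do not move.  Baselines
  are drawn so the shifted value stays inside [0, 1] without clamping and
  the true |ΔPDUI| is exactly 0.5.
* **Motif coupling** — classes map to planting rules: distal-shift genes
  get the consensus 9-mer planted 150 nt upstream of the proximal site
  only; proximal-shift genes get one motif near each site (proximal −150,
  distal +50, both > 200 nt from the other site); null genes get none.
  This encodes the mechanistic picture in which a U1 site near the
  proximal region suppresses proximal cleavage in the wild type and its
  loss of protection on knockout shifts usage distally.  After planting,
  the ±200-nt windows of every APA gene are scrubbed of *chance* 5′SS-like
  matches (planted motifs are never touched; a background match is
  destroyed by rewriting bases outside any planted footprint), so window
  hit counts equal the recorded truth exactly and the window-ratio
  properties are deterministic given the seed.
* **Junctions** — two trans-spliced genes with three isoforms at
  proportions (0.5, 0.3, 0.2); common-exon reads Poisson(1000), total
  specific reads Poisson(activity × 1000) split multinomially.  Activity
  is 0.8 in WT and 1.2 (a 1.5× increase) in the three strains emulating
  mildly increased trans-splicing.

What the simulation does **not** emulate: mapping artifacts, positional
coverage bias along transcripts, overlapping genes, >2 polyA sites per
UTR, intronic/CDS premature-cleavage events, dispersion trends with mean,
batch effects, and biological correlation between DE, APA and
trans-splicing responses of the same gene.  Passing tests therefore
demonstrate correctness of the estimators and screens under their own
model assumptions, and end-to-end recovery at realistic depths and effect
sizes — not robustness to alignment- or library-level artifacts of real
data.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale designs chosen to make the
statistical properties sharp: 2000 genes for null calibration (type-I
≤1%, p-uniformity KS < 0.1), 1000 genes for screen power (≥90% recovery
of 4-fold effects at base mean ≥100), ~100 two-site genes at 50× UTR
depth for PDUI recovery (|error| ≤ 0.05 in ≥95% of gene × sample pairs)
and direction calling (≥90% correct, ≥98% of null genes ns).  Fisher
p-values are checked against exact hypergeometric enumeration to 1e-12;
the change-point fit, motif scanner and overlap partition are checked
against brute-force oracles exactly.  Determinism is byte-level: one seed
⇒ identical FASTA/GTF/BED/TSV/bedGraph outputs and an identical JSON
report.

## Known limitations

* The DE test's normal reference relies on the gene-pooled dispersion
  trend; on data with strong per-gene dispersion heterogeneity it will be
  mildly anticonservative for outlier genes.  The screen's fold-change
  filter absorbs most of this in practice.
* The PDUI estimator models exactly one change point; genes with >2 used
  polyA sites or strong within-UTR coverage trends violate the model and
  surface as degenerate or biased fits.
* The APA replicate test (Welch t on 3 replicates) has limited power;
  the planted-effect properties hold at |ΔPDUI| = 0.5 and say nothing
  about marginal events near the 0.25 threshold.
* Window hit counting double-counts motifs between polyA sites closer
  than 400 nt; this is intentional (membership is per site) and logged.
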