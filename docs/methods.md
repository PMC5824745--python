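# Methods

## Quantification

Counts are gene-level integers per library, with libraries identified by
(condition ∈ {base, alt}, assay ∈ {RPF, mRNA}, replicate). RPKM is
`count / (length/10³) / (total/10⁶)` where the library total is the
column sum of the table itself — the pipeline is self-contained and uses
no external mapped-read figure. Effective length is the full transcript
for mRNA libraries and the CDS for footprint libraries (footprints
derive from translated sequence); `effective_lengths(rpf_use_cds=False)`
switches both to the full transcript.

The read filter discards a gene unless **every** (condition, assay)
group — replicates summed — reaches 128 reads. Filtering per group,
rather than on a single grand total, guarantees that each of the four
quantities entering the TE contrast is supported, preventing division by
near-zero RPKM. The threshold sits exactly at the boundary: 128 reads is
kept.

Replicates are averaged by geometric mean, which is the natural mean for
ratio-scale quantities like RPKM and TE and makes TE of averages equal
the average of log-TEs. The geometric mean is undefined at zero; genes
that reach a zero group mean after filtering are excluded with a logged
warning, mirroring the exclusion of undefined log values before PCA.

## The sliding-window statistic

The variance of a count ratio shrinks with expression, so a global
z-score would over-call abundant genes and under-call rare ones. The
statistic therefore standardizes each gene only against genes of similar
abundance: genes are ordered by log10 intensity (product of the two
condition values), windows of 100 genes advance 50 ranks at a time, and
each window records its mean intensity and the mean/SD (sample SD,
ddof = 1 — windows are samples of a local null) of its log2 ratios. A
gene is assigned the window whose mean intensity is nearest its own
(ties to the lower window index), and

z = (log2 ratio − window mean) / window SD, p = 2·Φ(−|z|).

Design choices where the procedure is under-determined:

- **Window edges.** Full windows start at ranks 0, 50, 100, … as long as
  a full window fits; a single truncated window is appended only when
  genes would otherwise remain uncovered. With exactly 100 genes there
  is one window; 260 genes give [0,100), [50,150), [100,200), [150,250),
  [200,260). Fewer than 100 genes form one window over everything; fewer
  than 3 raise an error (no SD).
- **Sidedness.** Two-sided p-values are the default since both down- and
  up-regulation are biologically meaningful; `sided="one"` gives the
  literal lower-tail quantile Φ(z).
- **Degenerate windows.** A window SD of 0 means the window offers no
  evidence against window-typical behaviour; its genes get z = 0, p = 1
  with a warning rather than an error.
- **Ties and order.** Intensity ties are broken by gene id, so results
  are invariant to input gene order (asserted by test).
- p is clamped to [1e-300, 1] so the step-up adjustment never sees 0.

Benjamini–Hochberg is implemented directly (sort, `m·p/rank`, reverse
cumulative minimum, cap at 1) and is checked in the tests against both an
O(m²) transcription of the step-up definition and statsmodels'
`multipletests`. Classification uses ratio ≤ 0.75 / ≥ 1.5 (boundaries
inclusive) with p < 0.05, all configurable. The control-group selector
draws a seeded sample of clearly unregulated genes (|log2 ratio| < 0.2,
p > 0.5, label unchanged), stratified across intensity deciles so
controls match the regulated groups' abundance span; it defaults to 325
genes.

Computed on TE the statistic tests translation; `mode="RPKM"` applies the
identical machinery to mRNA RPKM and tests transcription.

## Synthetic experiments

The generator emulates a two-condition, two-replicate brain ribosome
profiling study. Per gene, baseline expression is log-normal(ln 50, 1.5)
and baseline TE log-normal(0, 0.3), spreading genes over several decades
of intensity so every window stratum is exercised. Counts are negative
binomial with var = μ + a·μ², a single shared dispersion a = 0.003 and
expected library totals equal to the configured depth (default 5·10⁶
reads). The dispersion default is calibrated to the one reproducibility
figure such libraries are expected to meet — replicate r² of log RPKM
above 0.99 — and is the largest (noisiest) value that satisfies it at
the default depth; at a = 0.01 simulated r² drops to ≈ 0.98.

Planted effects use fixed quotas: round(frac·n) genes, chosen by seeded
shuffle, get their RPF mean multiplied by the fold change in the alt
condition only, so truth counts are exact for recovery tests. Defaults
(frac_down = 0.05, frac_up = 0.005, folds 0.5 and 2.0) mirror the
asymmetry typical of translational regulators that mostly repress.
Region lengths are uniform — 5′UTR 50–500 nt, CDS 300–3000 nt (multiple
of 3), 3′UTR 100–2000 nt.

Footprint records (one per read of a designated RPF library) carry
lengths from a configurable distribution peaked on 28–32 nt and 5′-end
offsets placed on codon boundaries such that a `frame_bias` fraction
(default 0.8) lies in frame 0, the remainder split over frames 1 and 2.
Frame is `(start − utr5_len) mod 3` with 0-based starts; the footprint
file uses half-open BED-like intervals on the sense strand.

Sequences are i.i.d. uniform ACGT backgrounds *scrubbed* of the scanned
motifs (no ATG in 5′UTRs, no CPE consensus in 3′UTRs, first 5′UTR base
never C), into which a seeded number of complete uORFs, a TOP prefix and
CPE copies are spliced with insulating flank bases. The element census
is therefore exact by construction and independent of the scanners —
what the generator does **not** emulate is the composition bias, motif
co-occurrence and secondary structure of real UTRs, so scanner tests
prove correctness of the pattern rules, not biological discovery power.
Likewise the count model has no rRNA contamination, positional bias
along transcripts, or per-gene dispersion, so passing recovery tests
demonstrate the statistic's behaviour under its own assumptions, not
performance on any particular real library.

## QC

Footprint length selection keeps 28–32 nt inclusive. Frame fractions are
computed over records whose 5′ end lies in the CDS; upstream records are
excluded and counted (the window is the whole CDS — the exact start-codon
window is a parameter with no canonical value). Replicate r² is the
squared Pearson correlation of log10(RPKM + 1) — the +1 log stabilizes
the heavy right tail; a raw-scale option exists. PCA standardizes each
gene to mean 0, SD 1 (ddof 1), eigendecomposes the sample-space Gram form
of the covariance (eigenvalue sum = number of genes used), and fixes
component signs so the largest-magnitude gene loading is positive.
Complete-linkage clustering runs on Euclidean distances of the same
standardized matrix; dendrograms serialize as nested parentheses with
merge heights.

## UTR elements

Element definitions are explicit, literature-standard pattern rules:

- **uORF** — every 5′UTR ATG whose reading frame reaches an in-frame
  stop (TAA/TAG/TGA) ending at or before the CDS start; in-frame ATGs
  sharing a stop count separately; minimum length 0 codons; ATGs that
  run into the CDS without a stop do not count. All exposed as
  parameters.
- **TOP** — position 0 is C and the next ≥ 4 bases are pyrimidines; the
  sequence must begin at the transcription start.
- **CPE** — non-overlapping left-to-right matches of TTTTAT/TTTTAAT
  (overlap-allowed mode available).

GAIT and IRES elements require RNA secondary structure and are ingestion
only, via a (gene, region, label) table with a declared vocabulary and
per-region validity (GAIT/CPE on 3′UTRs, TOP/uORF/IRES on 5′UTRs).
Group comparison reports, per element, percent-of-genes-with-element and
a two-proportion z-test of each group against the control group
(underrepresentation flagged at p < 0.05 — the test behind the "#"-style
marks on incidence bar charts); per length/GC metric it reports group
mean ± SEM, one-way ANOVA and Tukey HSD p-values versus control. GC%
excludes N from the denominator.

## Problem sizes and determinism

The test suite and acceptance script run simulations of 300–6000 genes at
depths up to 5·10⁶ reads — sizes at which every distributional guarantee
(null calibration within [0.03, 0.07] for p < 0.05, KS < 0.05; pooled
3-seed sensitivity ≥ 70% with empirical FDR ≤ 0.2 for 2-fold planted
effects) is measurable in seconds. All randomness flows from explicit
seeds through `numpy.random.Generator`; identical configs give
bit-identical counts, footprints, sequences and output files (floats are
written with `%.10g`).

## Known limitations

- One pairwise comparison; no interaction or ΔTE designs, no
  replicate-aware variance shrinkage (each gene's variance comes from
  its abundance window, not from its own replicates).
- Gene-level only: no isoform resolution, no multimapping handling, no
  P-site offsetting or metagene profiles.
- The window statistic assumes the great majority of genes in every
  abundance stratum are unchanged; dense true regulation inflates window
  SDs and costs power (visible in the recovery tests, where sensitivity
  is ~75% rather than the no-contamination ideal).
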