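# Methods

## The problem

A handful of genes — the Drosophila Y-linked fertility factors (kl-5, kl-3,
kl-2, ORY, CCY) and a few autosomal counterparts (Pzl, Myo81F, Mitf) — carry
introns of hundreds of kilobases to megabases, with introns making up more
than 99% of a 4+ Mb gene span. They are transcribed across nearly the whole
~85 h of spermatocyte (SC) development, 5'→3', and spliced
co-transcriptionally: each intron is removed essentially as soon as its 3'
splice site has been transcribed. When splicing is perturbed (e.g. by
knockdown of a splicing factor), transcription of exactly these
gigantic-intron genes attenuates: read depth collapses downstream of the
gigantic introns and the genes fail to produce mature mRNA, while ordinary
genes — even ones that are themselves mis-spliced — keep normal expression.

This package implements the quantitative side of that analysis as a reusable
pipeline, driven by a generative simulator with closed-form expectations so
every estimator can be checked against ground truth.

## Gene architecture metrics (`gene_models`)

- **Intron proportion** = 1 − (Σ exon lengths)/(genomic span), computed on
  the gene's *largest isoform*. "Largest" is defined as greatest genomic
  span, with ties broken by summed exon length and then transcript id — the
  denominator is a span-like quantity, so numerator and denominator come
  from the same isoform. The chosen isoform id is recorded in the output so
  the alternative (longest mature transcript) is auditable.
- **Max intron size** = longest intron over *all* isoforms.
- **Size bins**: `average` = max intron in [0, 100) bp (captures the mode of
  the distribution for typical genes), `large` = [50 000, 100 001) bp (big
  but far below the gigantic class), everything else `unbinned`. Gigantic
  genes are designated by an explicit id list, not by a size threshold,
  because their annotated introns span assembly gaps that defeat size
  inference. All intervals are half-open; a gene with a 100 bp max intron is
  deliberately unbinned.
- Coordinates are 0-based half-open internally; GTF/GFF3 I/O is 1-based
  closed. Book-ended or overlapping exon records within one transcript are
  merged with a logged warning (annotation-dialect tolerance).
- The **exon-span projection** maps every exonic base to an index 0…L−1
  along the concatenated exons, 5'→3' (index 0 = genomic rightmost base for
  minus-strand genes). All coverage profiles live on this coordinate.

## Strand-specific coverage (`coverage`)

Reads are assigned a transcript strand from paired-end flags. The default
protocol is `reverse` (dUTP chemistry): a first mate mapped to the genomic
minus strand implies a plus-strand transcript; `forward` is the mirror;
`unstranded` matches both. Unpaired reads under a paired protocol are
treated as first mates (dUTP semantics are carried by mate role) and
counted, never silently dropped.

Coverage is **read-level**: each mate contributes independently (overlapping
mates may double-cover), only primary alignments count, and duplicates are
not removed. Depth is normalized by `1e7 / library_total` where
`library_total` is the number of primary aligned records in the library.
Per-gene bedGraph output is restricted to exons and round-trips losslessly.

## Attenuation statistics (`attenuation`)

- **Ratio profile**: mutant/control normalized depth along the exon span.
  The default aggregates the span into 200 bp windows and takes the ratio
  of window sums; `window=1` gives a per-base ratio. The windowed default
  is a deliberate choice: the per-base ratio of Poisson counts is biased
  upward by ≈ 1/depth, and because control depth declines toward the 3' end
  (drop-off plus the cell-age factor), that bias grows along the span and
  tilts fitted slopes upward by an amount comparable to their sampling
  error at realistic depths. Summing windows first makes the bias
  negligible. Windows with zero control signal are masked (not
  pseudocounted) and the masked span fraction is reported; a pseudocount
  mode exists for sensitivity analysis.
- **Attenuation fit**: ordinary least squares of ratio on span position
  scaled to [0, 1] (`numpy.polyfit`, degree 1), so the slope reads as
  "change in relative expression over the full gene". The 95% CI comes from
  a moving-block bootstrap over contiguous position blocks (default 50
  blocks, 400 resamples): neighboring positions are strongly dependent at
  the fragment scale, so single-position resampling would understate
  uncertainty. The CI quantifies read-sampling noise conditional on the
  underlying transcript population; block lengths should comfortably exceed
  the fragment length for the interval to be well calibrated (the
  calibration test uses a 100 kb exon span with 100 bp fragments, i.e.
  2 kb blocks, for exactly this reason).
- **Intron drop**: mean normalized depth of the exon immediately 5' of an
  intron divided by that of the exon immediately 3' ("drop fold change");
  a zero downstream mean flags the statistic undefined instead of
  propagating infinity. **Exacerbation** is the mutant fold change over the
  control fold change; values above 1 mean the drop deepened.
- No p-value is attached to a single gene's slope; inference is by CI.

## Junction classes and splicing efficiency (`junctions`)

Each intron defines three junction classes, oriented 5'→3' in transcript
direction: exon–intron (nascent, at the 5' boundary), intron–exon
(unspliced, at the 3' boundary), exon–exon (spliced). A contiguous block
supports a boundary class when it spans the boundary with ≥ `min_flank`
aligned bases on each side (default 15, mirroring ~15 nt junction-probe
half-lengths); exon–exon support requires two consecutive blocks abutting
donor and acceptor *exactly* (zero tolerance keeps misaligned splice
junctions out), each with ≥ `min_flank` bases at the junction. For a given
intron, a single read can never support both exon–exon and intron–exon.

Splicing efficiency of an intron is read from its 3' splice site:
`s_hat = spliced / (spliced + unspliced)` with a Wilson 95% CI
(statsmodels). The nascent exon–intron class is reported separately and is
not in the denominator. The Wilson interval assumes approximately
independent reads; when few long RNAs receive many reads each, spliced
status is shared within a molecule and the interval will undercover — the
recovery tests therefore use populations with ≫ more molecules than
informative reads.

The gene-level **aberrant-splicing flag** (any intron whose upper CI bound
falls below a threshold, default 0.5) is a deliberately simple emulation of
an external splice-graph aberrance call, provided so the binned analyses
run without external tooling; it is labeled as such and never presented as
that tool's output. Real per-sample flag tables can be supplied instead.

## Binned differential expression (`expression_bins`)

Counts are normalized with median-of-ratios size factors (the standard
size-factor construction; formal dispersion/Wald inference is intentionally
out of scope — fold-change point estimates suffice for the binned analysis,
and external DE tables can be imported). Per-gene
log2FC = log2((mean norm condition + pc)/(mean norm control + pc)),
pseudocount 0.5.

Each intron-size bin's log2FC distribution is compared with the reference
`average` bin by a Mann–Whitney U test (pair-counting U; exact two-sided p
by complete enumeration when min(n1,n2) ≤ 8 and the pooled sample is
tie-free, otherwise normal approximation with tie and continuity
corrections; p-values via scipy, which implements exactly this rule). The
reference bin anchors the comparison because it is the most populous,
most typical bin; all-pairs comparisons are a straightforward extension.

The **splicing-burden regression** bins genes by intron proportion into 10
equal-width bins on [0,1], computes each bin's aberrantly-spliced fraction,
and fits OLS of fraction on bin midpoint with a two-sided slope t-test. A
per-gene logistic regression is a noted alternative; per-bin OLS is what is
implemented.

## The generative model (`synthetic_data`)

The simulator emulates a testis RNA-seq library drawn from SCs of mixed
developmental age:

- **Ages** t ~ Uniform(0, T), default T = 85 h ("SCs develop over 80–90 h"
  motivates the range; uniform mixing is the simplest conveyor-belt
  assumption and yields the closed form below).
- **Initiation**: Poisson(r·t) polymerases per cell (default r = 2/h/cell),
  start times uniform over the cell's life, so elapsed transcription times
  are Uniform(0, t).
- **Elongation** at v bp/h; the default configuration sets v so the largest
  gene takes ~90% of T to transcribe (~60 kb/h for a 4.6 Mb gene —
  within the plausible Pol II range). v and r are free parameters of the
  model, not biological estimates.
- **Drop-off**: on *entering* a gigantic intron a polymerase terminates
  with probability d (a point event, matching a drop localized "after a
  gigantic intron"); the truncated transcript — the RNA actually made — is
  retained in the cell, ending at the donor site.
- **Splicing**: once an intron is fully transcribed it is removed with
  probability s (Bernoulli per intron per transcript; instantaneous
  on-availability, no kinetic delay parameter). Spliced intron RNA
  disappears immediately; retained introns persist and contribute RNA.

With τ_x = (template distance from TSS to x)/v, the expected number of
transcripts covering exonic position x per cell is

    E[C(x)] = S_x · r (T − τ_x)² / (2T)   for τ_x < T,  else 0,

with S_x = Π (1 − d) over gigantic introns 5' of x. Expected drop fold
changes, expected exonic mass (hence expected log2FC between genotypes) and
expected ratio-slope signs all derive from this expression and are exposed
as `GroundTruth`.

The **sequencing layer** samples fragments uniformly over all existing RNA
(molecules weighted by their number of valid fragment start positions) and
emits two mates per fragment with dUTP-consistent orientation; reads
crossing a spliced-out intron become split alignments abutting donor and
acceptor exactly. SAM output is coordinate-sorted with a proper header.
`n_reads` counts fragments, so a library holds 2·n_reads primary records.

**Count tables** are sampled Poisson around the closed-form expected exonic
mass per gene × genotype (with mildly lognormal per-replicate library
factors), scaled so a median gene gets ~500 counts; read-to-count
tabulation is the job of external counters and is not re-implemented.
Read-level SAM output is emitted for a configurable subset of genes
(default: the gigantic ones), mirroring an analysis that plots coverage
only for selected genes.

**Default study conditions** (`paper_like_config`): 5 gigantic genes
(16 exons, ~14 kb exonic, three Mb-scale introns after exons 1, 5, 10, a
short 250 bp first exon so most exonic mass lies downstream of the first
gigantic intron), 200 average genes, 20 large genes; control d = 0.55,
s = 0.95; mutant d = 0.9, s = 0.2. Under the elongation calibration above,
the (T − τ)² age factor damps downstream-exon signal in both genotypes, and
the closed-form expected gigantic-gene depletion is ≈ −1.5 log2 units,
with average/large bins centered at 0. The mutant drop probability is the
one free "exacerbated" parameter; 0.9 places the expected binned pattern
(gigantic median below −1) robustly inside the regime the analysis is
designed to detect, which weaker exacerbation (d ≈ 0.75) does not reach
under the same age damping.

### What the simulator does and does not emulate

It captures: mixed-age cell populations, 5'→3' elongation with premature
termination at gigantic introns, probabilistic co-transcriptional splicing,
retained-intron RNA, strand-specific paired-end read geometry, split reads
at spliced junctions, and library-size differences. It does **not**
emulate: nucleotide sequence or base quality (alignment-level only),
mapping ambiguity or repeat-induced mis-mapping (a major real-world issue
inside gigantic introns), fragment-length variability, lariat decay
intermediates, cryptic polyadenylation, or Y-loop spatial geometry. Tests
passing on this simulator therefore validate the *estimators* under the
stated model, not robustness to alignment artifacts in real repetitive
introns.

## Numerical choices and problem sizes

- All randomness flows from numpy Generators seeded explicitly; bundles and
  pipeline outputs are byte-identical for a fixed seed.
- Degenerate inputs: zero-control windows are masked; zero downstream exon
  means flag drop statistics undefined; empty junction denominators and
  empty reference bins raise typed errors rather than returning NaN.
- Exact Mann–Whitney enumeration is limited to min(n) ≤ 8 without ties;
  tied exact requests fall back to the corrected normal approximation with
  a log message.
- Statistical checks run at deliberately chosen scales: drop-fold recovery
  uses one 300 kb-intron gene at 10⁵ fragments (recovery within a few
  percent of the closed form); slope calibration uses a 100 kb exon span,
  1500 cells, 50 bp reads and 6 k fragments per library so that read noise
  dominates population noise and bootstrap blocks (2 kb) far exceed the
  fragment correlation length; splicing-efficiency recovery uses 500 cells
  and 3 k fragments so informative reads are ~independent across molecules.
  These sizes are part of the study design and are stated here so they can
  be scaled up or down consciously.

## Known limitations

- The aberrant-splicing flag is a stand-in with one tunable threshold; its
  operating point has no external calibration.
- The attenuation CI is conditional on the transcript population (see
  above); with small cell populations the replicate-to-replicate spread of
  slopes exceeds the CI width.
- Read-level double counting of overlapping mates mildly inflates depth;
  a fragment-collapse option is available but off by default to match
  plain per-read pileup.
- The pipeline loads each sample's alignments into memory; it is sized for
  targeted gene panels, not whole-transcriptome BAMs.
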