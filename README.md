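# gigasplice

Quantifying how splicing perturbation attenuates transcription of genes
with *gigantic* introns.

A small number of genes — the Drosophila Y-linked fertility genes (*kl-5*,
*kl-3*, *kl-2*, *ORY*, *CCY*) are the canonical case — span megabases, with
introns of hundreds of kb occupying >99% of the gene body. They are
transcribed 5'→3' across nearly the entire ~85 h of spermatocyte
development and spliced co-transcriptionally. When splicing factors are
depleted, transcription of precisely these genes attenuates: read depth
drops sharply downstream of each gigantic intron and declines along the
gene span relative to controls, while typical genes are unaffected even
when mis-spliced.

`gigasplice` is a library + CLI for the quantitative analysis behind that
observation, for people analyzing strand-specific RNA-seq of tissues with
gigantic-intron genes:

- **gene_models** — GTF/GFF3 → gene models; intron proportion
  (1 − Σexon/span on the largest isoform), max intron size, intron-size
  bins (`average` < 100 bp, `large` 50–100 kb, explicit `gigantic` list),
  and the exon-span coordinate (gene span, exons only).
- **coverage** — strand-specific per-base read depth over the exon span
  (dUTP decoding), normalized by 10⁷/aligned-reads; bedGraph output.
- **attenuation** — mutant/control ratio profiles, degree-1 regression of
  the ratio on span position in [0,1] with a block-bootstrap 95% CI, and
  per-intron read-depth **drop fold changes** (mean depth of the exon 5'
  of an intron over the exon 3' of it) with mutant/control exacerbation.
- **junctions** — read support for exon–intron (nascent), intron–exon
  (unspliced) and exon–exon (spliced) junctions (≥15 bp flanks, exact
  splice boundaries), per-intron splicing efficiency
  ŝ = spliced/(spliced+unspliced) with Wilson CIs, and a gene-level
  aberrant-splicing flag.
- **expression_bins** — median-of-ratios size factors, per-gene log2 fold
  changes, Mann–Whitney U comparison of each intron-size bin against the
  `average` bin, and the regression of per-bin aberrantly-spliced fraction
  on intron proportion.
- **synthetic_data** — a generative spermatocyte simulator (uniform cell
  ages, Poisson initiation, 5'→3' elongation, Bernoulli drop-off at
  gigantic introns, Bernoulli co-transcriptional splicing) with
  closed-form expected coverage `S_x · r(T−τ_x)²/2T`, paired strand-aware
  read emission, SAM/GTF/count-table output and exact ground truth.
- **cli** — `gigasplice` console script (`simulate`, `metrics`, `coverage`,
  `attenuate`, `junctions`, `bins`, `run-all`) over a YAML config, with a
  reproducibility manifest.

## Worked example

Simulate one gene with a 300 kb gigantic intron under a control genotype
(drop-off d = 0.55, splicing efficiency s = 0.95) and a splicing-deficient
mutant (d = 0.9, s = 0.2), then measure the read-depth drop across the
intron and the intron's splicing efficiency from junction reads:

```python
import numpy as np
from gigasplice import (
    SimGeneSpec, GenotypeParams, SimConfig, simulate_cells, emit_alignments,
    expected_profile, exon_span_projection, exon_coverage, normalize_profile,
    intron_drop, exacerbation, enumerate_junctions, count_junctions,
    splicing_efficiency,
)

gene = SimGeneSpec("giga", exon_lengths=[5000, 5000],
                   intron_lengths=[300_000], gigantic_flags=[True])
gm = gene.to_gene_model()
proj = exon_span_projection(gm.transcripts[0])
specs = enumerate_junctions(gm.transcripts[0])

drops = {}
for label, d, s in (("control", 0.55, 0.95), ("mutant", 0.9, 0.2)):
    gt = GenotypeParams(label, drop_prob=d, splice_prob=s)
    cfg = SimConfig(genes=[gene], genotypes=[gt], elongation_rate=60_000,
                    n_cells=50, read_length=150, fragment_length=300,
                    n_reads=50_000, seed=1)
    rng = np.random.default_rng(1)
    pop = simulate_cells(cfg, gene, gt, rng)
    recs = emit_alignments(pop, gene, cfg, rng)
    prof = normalize_profile(exon_coverage(recs, gm, proj, library_total=len(recs)))
    drops[label] = intron_drop(prof, 0)
    eff = splicing_efficiency(count_junctions(recs, specs), 0)
    truth = expected_profile(gene, gt, cfg)
    print(f"{label}: drop fold {drops[label].fold_change:.2f} "
          f"(expected {truth.drop_folds[0]:.2f}), "
          f"s_hat {eff.s_hat:.2f} CI ({eff.ci[0]:.2f}, {eff.ci[1]:.2f})")
print(f"exacerbation: {exacerbation(drops['mutant'], drops['control']):.2f}")
```

Output:

```
control: drop fold 2.35 (expected 2.51), s_hat 0.93 CI (0.90, 0.96)
mutant: drop fold 10.35 (expected 11.31), s_hat 0.22 CI (0.11, 0.39)
exacerbation: 4.39
```

The control's ~2.4× drop combines the mixed-age population (younger cells
have not yet transcribed past the intron) with its baseline drop-off; the
mutant's ~12× drop and collapsed splicing efficiency are the attenuation
signature, and both match the model's closed-form expectations. The same
quantities are available from the shell:

```bash
gigasplice simulate --outdir sim --seed 1
gigasplice attenuate --annotation sim/genes.gtf \
    --mutant-sam sim/mutant.sam --control-sam sim/control.sam \
    --genes gigantic_1 --out attenuation.tsv
```

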