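"""The spermatocyte-transcription simulator against its own closed forms."""

import math
from pathlib import Path

import numpy as np
import pytest

from gigasplice.coverage import read_alignments
from gigasplice.gene_models import intron_proportion
from gigasplice.junctions import (
    EXON_EXON,
    INTRON_EXON,
    count_junctions,
    enumerate_junctions,
)
from gigasplice.synthetic_data import (
    GenotypeParams,
    SimConfig,
    SimGeneSpec,
    SimulationError,
    emit_alignments,
    expected_profile,
    paper_like_config,
    simulate_cells,
    simulate_count_table,
    simulate_experiment,
    write_bundle,
    write_sam,
)


def small_gene(intron=400, gigantic=False, strand="+"):
    return SimGeneSpec(
        "g", [1000, 1000], [intron], [gigantic], strand=strand, offset=100
    )


def config_for(gene, genotype, **kw):
    kw.setdefault("elongation_rate", 60_000.0)
    kw.setdefault("n_cells", 20)
    kw.setdefault("read_length", 100)
    kw.setdefault("fragment_length", 200)
    return SimConfig(genes=[gene], genotypes=[genotype], **kw)


CONTROL = GenotypeParams("control", 0.0, 0.95)


class TestSpecValidation:
    def test_intron_exon_count_mismatch_rejected(self):
        with pytest.raises(SimulationError):
            SimGeneSpec("g", [100, 100], [50, 50], [False, False])

    def test_flag_alignment_enforced(self):
        with pytest.raises(SimulationError):
            SimGeneSpec("g", [100, 100], [50], [])

    def test_gene_model_round_trip_minus_strand(self):
        spec = small_gene(strand="-")
        gene = spec.to_gene_model()
        assert gene.strand == "-"
        assert intron_proportion(gene) == pytest.approx(400 / 2400)


class TestSimulateCells:
    def test_certain_drop_stops_everything_at_first_gigantic_intron(self):
        gene = small_gene(intron=5000, gigantic=True)
        gt = GenotypeParams("m", 1.0, 0.9)
        pop = simulate_cells(config_for(gene, gt), gene, gt, np.random.default_rng(0))
        assert pop.n_transcripts > 50
        assert (pop.fronts <= 1000).all()  # nothing past the exon-1 donor

    def test_developmental_timing_limits_reach_without_drop(self):
        # v*T smaller than the distance to exon 2: no coverage beyond exon 1
        gene = small_gene(intron=50_000)
        cfg = config_for(gene, CONTROL, elongation_rate=100.0, max_age=10.0)
        pop = simulate_cells(cfg, gene, CONTROL, np.random.default_rng(1))
        assert (pop.fronts <= 1000).all()

    def test_survival_fraction_is_binomial_around_one_minus_d(self):
        gene = small_gene(intron=5000, gigantic=True)
        gt = GenotypeParams("m", 0.4, 0.9)
        cfg = config_for(gene, gt, n_cells=300)
        pop = simulate_cells(cfg, gene, gt, np.random.default_rng(2))
        crossed = pop.fronts >= 1000  # reached the donor at all
        survived = pop.fronts > 1000
        n = int(crossed.sum())
        assert n > 5000
        frac = survived.sum() / n
        sigma = math.sqrt(0.6 * 0.4 / n)
        assert abs(frac - 0.6) < 3 * sigma

    def test_monte_carlo_profile_matches_closed_form(self):
        gene = SimGeneSpec("g", [500, 500, 500], [150_000, 100_000],
                           [True, False], offset=0)
        gt = GenotypeParams("m", 0.5, 0.9)
        # v*T ~ 3x the span so the age factor varies but stays well populated
        cfg = config_for(gene, gt, elongation_rate=10_000.0, n_cells=1200)
        pop = simulate_cells(cfg, gene, gt, np.random.default_rng(3))
        assert pop.n_transcripts > 80_000
        truth = expected_profile(gene, gt, cfg)
        # transcript covers exonic template position t iff front > t
        fronts = np.sort(pop.fronts)
        empirical = []
        for (e0, e1) in gene.exon_template:
            for t in range(e0, e1, 25):
                empirical.append(len(fronts) - np.searchsorted(fronts, t, "right"))
        empirical = np.array(empirical, dtype=float)
        expected = []
        offs = np.concatenate([[0], np.cumsum(gene.exon_lengths)])
        for k, (e0, e1) in enumerate(gene.exon_template):
            idx = np.arange(0, e1 - e0, 25) + offs[k]
            expected.append(truth.span_profile[idx])
        expected = np.concatenate(expected)
        scale = empirical.sum() / expected.sum()
        rel = np.abs(empirical - expected * scale) / (expected * scale)
        assert rel.max() < 0.02

    def test_monotone_drop_probability_decreases_expected_fold_survival(self):
        gene = small_gene(intron=100_000, gigantic=True)
        folds = []
        for d in (0.2, 0.5, 0.8):
            gt = GenotypeParams("m", d, 0.9)
            folds.append(expected_profile(gene, gt, config_for(gene, gt))
                         .drop_folds[0])
        assert folds[0] < folds[1] < folds[2]

    def test_no_gigantic_introns_give_no_survival_entries(self):
        gene = small_gene(gigantic=False)
        truth = expected_profile(gene, CONTROL, config_for(gene, CONTROL))
        assert truth.survival == {}


class TestEmitAlignments:
    def emit(self, gene, gt, seed=0, n_reads=2000, **kw):
        cfg = config_for(gene, gt, n_reads=n_reads, **kw)
        rng = np.random.default_rng(seed)
        pop = simulate_cells(cfg, gene, gt, rng)
        return cfg, pop, emit_alignments(pop, gene, cfg, rng)

    def test_fully_spliced_population_has_no_intron_coverage(self):
        # near-instant elongation: every polymerase has finished, so s = 1
        # leaves no intronic RNA at all
        gene = small_gene()
        gt = GenotypeParams("c", 0.0, 1.0)
        _, _, recs = self.emit(gene, gt, elongation_rate=1e12)
        intron = (gene.offset + 1000, gene.offset + 1400)
        for rec in recs:
            for a, b in rec.blocks:
                assert b <= intron[0] or a >= intron[1]

    def test_junction_crossing_reads_are_split_when_spliced(self):
        gene = small_gene()
        gt = GenotypeParams("c", 0.0, 1.0)
        _, _, recs = self.emit(gene, gt, elongation_rate=1e12)
        split = [r for r in recs if len(r.blocks) == 2]
        assert split
        donor, acceptor = gene.offset + 1000, gene.offset + 1400
        for r in split:
            assert r.blocks[0][1] == donor and r.blocks[1][0] == acceptor

    def test_unspliced_regime_has_no_split_reads(self):
        gene = small_gene()
        gt = GenotypeParams("m", 0.0, 0.0)
        _, _, recs = self.emit(gene, gt)
        assert all(len(r.blocks) == 1 for r in recs)

    def test_reads_stay_within_simulated_rna(self):
        gene = small_gene(strand="-")
        gt = GenotypeParams("c", 0.0, 0.5)
        cfg, pop, recs = self.emit(gene, gt)
        lo, hi = gene.offset, gene.offset + gene.span
        for rec in recs:
            assert lo <= rec.start and rec.end <= hi

    def test_strand_decoding_recovers_origin_for_both_strands(self, tmp_path):
        for strand in "+-":
            gene = small_gene(strand=strand)
            gt = GenotypeParams("c", 0.0, 0.9)
            cfg, _, recs = self.emit(gene, gt, n_reads=500)
            sam = tmp_path / f"s{strand == '+'}.sam"
            write_sam(recs, {gene.chrom: gene.offset + gene.span + 100}, sam)
            back = list(read_alignments(sam, protocol="reverse"))
            assert len(back) == len(recs)
            assert all(r.assigned_strand == strand for r in back)

    def test_splicing_efficiency_recoverable_from_reads(self):
        gene = small_gene()
        s = 0.8
        gt = GenotypeParams("c", 0.0, s)
        cfg, _, recs = self.emit(gene, gt, n_reads=4000, read_length=250,
                                 fragment_length=500)
        tx = gene.to_gene_model().transcripts[0]
        counts = count_junctions(recs, enumerate_junctions(tx))
        per = counts.by_intron(0)
        n = per[EXON_EXON] + per[INTRON_EXON]
        assert n > 300
        s_hat = per[EXON_EXON] / n
        assert s_hat == pytest.approx(s, abs=0.08)


class TestExperimentBundle:
    def tiny_config(self, seed=5):
        return paper_like_config(
            seed=seed, n_gigantic=1, n_average=8, n_large=2,
            n_reads=600, n_cells=6,
        )

    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        cfg = self.tiny_config()
        for d in ("a", "b"):
            write_bundle(simulate_experiment(cfg), tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            other = tmp_path / "b" / f.name
            assert f.read_bytes() == other.read_bytes(), f.name

    def test_bundle_is_sufficient_for_upstream_modules(self, tmp_path):
        cfg = self.tiny_config()
        bundle = simulate_experiment(cfg)
        paths = write_bundle(bundle, tmp_path / "bundle")
        assert Path(paths["annotation"]).exists()
        assert bundle.counts.counts.shape == (11, 6)
        for label in ("control", "mutant"):
            assert len(bundle.alignments[label]) > 0

    def test_gigantic_gene_expected_downregulation(self):
        cfg = self.tiny_config()
        bundle = simulate_experiment(cfg)
        t_c = bundle.truths[("gigantic_1", "control")]
        t_m = bundle.truths[("gigantic_1", "mutant")]
        assert math.log2(t_m.exonic_mass / t_c.exonic_mass) < -1

    def test_count_table_shrinks_gigantic_genes_only(self):
        cfg = self.tiny_config(seed=9)
        bundle = simulate_experiment(cfg)
        tab = bundle.counts
        gig = tab.counts.loc["gigantic_1"]
        ctrl_mean = gig[[c for c in tab.counts if c.startswith("control")]].mean()
        mut_mean = gig[[c for c in tab.counts if c.startswith("mutant")]].mean()
        assert mut_mean < 0.75 * ctrl_mean

    def test_sampling_error_shrinks_with_read_depth(self):
        gene = small_gene()
        s = 0.7
        gt = GenotypeParams("c", 0.0, s)
        errors = []
        for n_reads in (400, 8000):
            errs = []
            for seed in range(8):
                cfg = config_for(gene, gt, n_reads=n_reads, read_length=250,
                                 fragment_length=500)
                rng = np.random.default_rng(seed)
                pop = simulate_cells(cfg, gene, gt, rng)
                recs = emit_alignments(pop, gene, cfg, rng)
                tx = gene.to_gene_model().transcripts[0]
                per = count_junctions(
                    recs, enumerate_junctions(tx)
                ).by_intron(0)
                n = per[EXON_EXON] + per[INTRON_EXON]
                errs.append(abs(per[EXON_EXON] / n - s))
            errors.append(np.mean(errs))
        assert errors[1] < errors[0]
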