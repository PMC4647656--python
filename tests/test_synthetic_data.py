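import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pysam
import pytest

from rdipkit.genomic_context import methylation_contrast, overlap_proportion
from rdipkit.synthetic_data import (
    SimulationConfig,
    run_simulation,
    simulate_expression_and_tracks,
    simulate_genome,
    simulate_peaks_and_reads,
    simulate_window_density,
    write_sam,
)


def file_hashes(directory):
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(Path(directory).iterdir())
        if p.is_file()
    }


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_strand": 0.4},
            {"p_strand": 1.2},
            {"purine_delta": 0.7},
            {"promoter_multiplier": 0.5},
            {"zero_inflation": 1.0},
            {"chrom_lengths": {"chr1": 0}},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSimulateGenome:
    def test_zero_genes_empty_track(self):
        config = SimulationConfig(
            seed=0, chrom_lengths={"chr1": 100_000}, n_genes=0, n_peaks=5
        )
        _, features = simulate_genome(config)
        assert features["gene"].intervals == []
        assert features["promoter"].intervals == []

    def test_same_seed_identical_sequence(self):
        config = SimulationConfig(seed=4, chrom_lengths={"chr1": 50_000}, n_genes=5)
        g1, _ = simulate_genome(config)
        g2, _ = simulate_genome(config)
        assert g1.sequences == g2.sequences

    def test_background_composition_near_uniform(self):
        config = SimulationConfig(seed=9, chrom_lengths={"chr1": 1_000_000}, n_genes=0)
        genome, _ = simulate_genome(config)
        seq = genome.sequences["chr1"]
        for base in "ACGT":
            assert abs(seq.count(base) / len(seq) - 0.25) < 0.01

    def test_genes_within_chromosome_and_nonoverlapping(self, small_config):
        genome, features = simulate_genome(small_config)
        genes = features["gene"].intervals
        for g in genes:
            genome.validate_interval(g)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for glist in by_chrom.values():
            glist.sort(key=lambda g: g.start)
            for a, b in zip(glist, glist[1:]):
                assert a.end <= b.start


class TestSimulatePeaksAndReads:
    def test_p_strand_one_planted_top_all_163(self):
        config = SimulationConfig(
            seed=2,
            chrom_lengths={"chr1": 400_000},
            n_genes=20,
            n_peaks=40,
            reads_per_peak=10,
            p_strand=1.0,
        )
        genome, features = simulate_genome(config)
        peaks, sam_lines, truth = simulate_peaks_and_reads(config, genome, features)
        flags_by_peak = {}
        for line in sam_lines:
            if line.startswith("@"):
                continue
            qname, flag = line.split("\t")[0], int(line.split("\t")[1])
            if flag in (163, 147):  # the RNA-derived read
                flags_by_peak.setdefault(qname.rsplit("_", 1)[0], []).append(flag)
        for _, row in truth.iterrows():
            expected = 163 if row["planted_strand"] == "+" else 147
            assert all(f == expected for f in flags_by_peak[row["peak"]])

    def test_delta_zero_null_purine_fraction(self):
        config = SimulationConfig(
            seed=3,
            chrom_lengths={"chr1": 500_000},
            n_genes=10,
            n_peaks=60,
            purine_delta=0.0,
        )
        genome, features = simulate_genome(config)
        peaks, _, truth = simulate_peaks_and_reads(config, genome, features)
        from rdipkit.skew_stats import skew

        fracs = []
        for peak, strand in zip(peaks, truth["planted_strand"]):
            f = skew(genome.sequence(peak)).purine_fraction
            fracs.append(f if strand == "+" else 1 - f)
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.5) < 3 * se

    def test_promoter_enrichment_mixture_arithmetic(self):
        # promoters ~10% of genome, multiplier 5 -> P(peak in promoter)
        # = 5*f / (5*f + (1-f)) evaluated at the realized promoter fraction
        config = SimulationConfig(
            seed=6,
            chrom_lengths={"chr1": 1_000_000},
            n_genes=50,
            promoter_width=2_000,
            n_peaks=500,
            reads_per_peak=1,
            peak_length_mean=200.0,
            promoter_multiplier=5.0,
        )
        genome, features = simulate_genome(config)
        peaks, _, _ = simulate_peaks_and_reads(config, genome, features)
        f = features["promoter"].occupancy / genome.size
        expected = 5 * f / (5 * f + (1 - f))
        observed, _ = overlap_proportion(peaks, features["promoter"])
        assert observed == pytest.approx(expected, abs=0.07)

    def test_emitted_sam_is_valid(self, small_dataset, tmp_path):
        path = tmp_path / "reads.sam"
        write_sam(small_dataset["sam_lines"], path)
        n = 0
        with pysam.AlignmentFile(str(path), "r") as handle:
            for aln in handle:
                n += 1
                assert aln.is_paired and aln.is_proper_pair
                if aln.is_read2:
                    assert aln.flag in (163, 147)
                else:
                    assert aln.flag in (99, 83)
                # mate fields consistent: read and mate on opposite strands
                assert aln.is_reverse != aln.mate_is_reverse
                assert aln.next_reference_name == aln.reference_name
        config = small_dataset["config"]
        assert n == 2 * config.n_peaks * config.reads_per_peak

    def test_planted_strand_bias_recoverable(self, small_dataset):
        truth = small_dataset["truth"]
        p_hat = truth["n_reads_on_planted"].sum() / truth["n_reads"].sum()
        p = small_dataset["config"].p_strand
        n = truth["n_reads"].sum()
        assert abs(p_hat - p) < 3 * np.sqrt(p * (1 - p) / n)


@pytest.fixture(scope="module")
def tracks(small_dataset):
    config = small_dataset["config"]
    return simulate_expression_and_tracks(
        config, small_dataset["features"]["gene"].intervals, small_dataset["peaks"]
    )


class TestExpressionAndTracks:
    def test_zero_inflation_fraction(self):
        config = SimulationConfig(
            seed=10, chrom_lengths={"chr1": 2_000_000}, n_genes=400, n_peaks=5,
            zero_inflation=0.3,
        )
        genome, features = simulate_genome(config)
        expression, _, _ = simulate_expression_and_tracks(
            config, features["gene"].intervals
        )
        frac_zero = (expression["expression"] == 0).mean()
        assert frac_zero == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / 400))

    def test_methylation_decrement_recovered(self, small_dataset, tracks):
        _, methylation, _ = tracks
        peak_mean, genome_mean, diff, p = methylation_contrast(
            small_dataset["peaks"], methylation
        )
        config = small_dataset["config"]
        # genome-wide mean is itself pulled down by in-peak sites
        in_peak = sum(
            1
            for row in methylation
            if any(
                p_.chrom == row[0] and p_.start <= row[1] < p_.end
                for p_ in small_dataset["peaks"]
            )
        )
        contamination = in_peak / len(methylation)
        expected = -config.methylation_decrement * (1 - contamination)
        assert diff == pytest.approx(expected, abs=0.02)

    def test_transcribed_covers_expressed_genes(self, small_dataset, tracks):
        expression, _, transcribed = tracks
        names = {t.name for t in transcribed}
        expressed = set(expression.loc[expression["expression"] > 0, "gene"])
        assert expressed <= names

    def test_planted_expression_peak_association(self):
        config = SimulationConfig(
            seed=20,
            chrom_lengths={"chr1": 3_000_000},
            n_genes=300,
            n_peaks=250,
            reads_per_peak=1,
            expression_peak_boost=8.0,
        )
        genome, features = simulate_genome(config)
        peaks, _, _ = simulate_peaks_and_reads(config, genome, features)
        expression, _, _ = simulate_expression_and_tracks(
            config, features["gene"].intervals, peaks
        )
        genes = features["gene"].intervals
        expr = dict(zip(expression["gene"], expression["expression"]))
        expressed = [g for g in genes if expr[g.name] > 0]
        values = np.array([expr[g.name] for g in expressed])
        top = values >= np.quantile(values, 0.75)

        def tss_region(g):
            from rdipkit.genome_io import GenomicInterval

            if g.strand == "+":
                return GenomicInterval(g.chrom, g.start, g.start + config.tss_proximal_bp)
            return GenomicInterval(g.chrom, max(0, g.end - config.tss_proximal_bp), g.end)

        def frac_with_peak(gene_list):
            return np.mean(
                [any(p.overlaps(tss_region(g)) for p in peaks) for g in gene_list]
            )

        top_frac = frac_with_peak([g for g, t in zip(expressed, top) if t])
        bottom_frac = frac_with_peak([g for g, t in zip(expressed, top) if not t])
        assert top_frac > bottom_frac


class TestWindowDensity:
    def test_all_zero_coefficients_pure_noise(self):
        config = SimulationConfig(seed=1, covariate_effects=(), noise_sd=1.0)
        table, response, truth = simulate_window_density(config, 500)
        assert truth["active"] == []
        # response uncorrelated with every covariate
        X = table.to_numpy()
        corr = np.abs(
            [np.corrcoef(X[:, j], response)[0, 1] for j in range(X.shape[1])]
        )
        assert np.max(corr) < 0.2

    def test_single_strong_covariate_enters_first(self):
        config = SimulationConfig(
            seed=2, covariate_effects=(10.0,), noise_sd=0.5, n_covariates=8
        )
        table, response, truth = simulate_window_density(config, 100)
        from rdipkit.density_regression import lars_lasso_path, standardize

        d = standardize(table.to_numpy(), response, list(table.columns))
        path = lars_lasso_path(d, max_events=2)
        assert d.names[path.entry_order[0]] == "cov00"

    def test_same_seed_identical_table(self):
        config = SimulationConfig(seed=3)
        t1, r1, _ = simulate_window_density(config, 40)
        t2, r2, _ = simulate_window_density(config, 40)
        assert t1.equals(t2) and np.array_equal(r1, r2)

    def test_singular_correlation_is_error(self):
        config = SimulationConfig(seed=0, covariate_correlation=1.0)
        with pytest.raises(ValueError, match="singular"):
            simulate_window_density(config, 10)

    def test_too_many_effects_is_error(self):
        config = SimulationConfig(
            seed=0, n_covariates=2, covariate_effects=(1.0, 1.0, 1.0)
        )
        with pytest.raises(ValueError):
            simulate_window_density(config, 10)


class TestRunSimulation:
    def test_fixed_seed_byte_identical_outputs(self, small_config, tmp_path):
        config = dataclasses.replace(
            small_config,
            chrom_lengths={"chr1": 200_000},
            n_genes=20,
            n_peaks=30,
            reads_per_peak=5,
            n_cpg_sites=300,
        )
        run_simulation(config, tmp_path / "a")
        run_simulation(config, tmp_path / "b")
        assert file_hashes(tmp_path / "a") == file_hashes(tmp_path / "b")

    def test_all_artifacts_written(self, small_config, tmp_path):
        config = dataclasses.replace(
            small_config,
            chrom_lengths={"chr1": 200_000},
            n_genes=15,
            n_peaks=20,
            reads_per_peak=5,
            n_cpg_sites=200,
        )
        paths = run_simulation(config, tmp_path)
        for name in (
            "genome", "gene", "promoter", "peaks", "reads", "expression",
            "methylation", "transcribed", "window_density", "density_truth",
        ):
            assert paths[name].exists(), name
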