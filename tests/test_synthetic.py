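"""Tests for the synthetic-data generator: determinism, planted structure,
noise calibration, and absence of truth leakage."""

import re

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from rbscreen import synthetic as syn
from rbscreen.counts import normalize_total


class TestSimulateGenome:
    def test_genes_disjoint_and_inside_chromosome(self):
        spec = syn.SyntheticGenomeSpec(
            n_chromosomes=1, chromosome_lengths=(10_000,), n_genes=5,
            gene_length_range=(500, 500), seed=7,
        )
        g = syn.simulate_genome(spec)
        assert len(g.genes) == 5
        intervals = sorted((x.start, x.end) for x in g.genes)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 < s2
        assert intervals[0][0] >= 1 and intervals[-1][1] <= 10_000

    def test_same_seed_byte_identical(self):
        spec = syn.SyntheticGenomeSpec(seed=42)
        g1, g2 = syn.simulate_genome(spec), syn.simulate_genome(spec)
        assert g1.to_fasta_string() == g2.to_fasta_string()
        assert g1.genes == g2.genes

    def test_gc_content_within_binomial_tolerance(self):
        spec = syn.SyntheticGenomeSpec(
            n_chromosomes=1, chromosome_lengths=(100_000,), n_genes=0,
            gc_content=0.5, seed=3,
        )
        seq = syn.simulate_genome(spec).chromosomes["chr1"]
        gc = sum(c in "GC" for c in seq) / len(seq)
        assert abs(gc - 0.5) < 0.02

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError):
            syn.simulate_genome(
                syn.SyntheticGenomeSpec(
                    n_chromosomes=1, chromosome_lengths=(1_000,), n_genes=5,
                    gene_length_range=(500, 500), seed=0,
                )
            )


class TestSimulateInsertions:
    def test_single_insertion(self, small_genome):
        truth = syn.simulate_insertions(small_genome, 1, seed=1)
        assert len(truth.insertions) == 1
        row = truth.insertions.iloc[0]
        assert 1 <= row.position <= len(small_genome.chromosomes[row.chromosome])

    def test_uniform_across_equal_chromosomes(self, small_genome):
        """Per-chromosome counts over 20 seeds are consistent with a
        uniform law (chi-square on the pooled counts)."""
        counts = np.zeros(2)
        for seed in range(20):
            truth = syn.simulate_insertions(small_genome, 100, seed=seed)
            vc = truth.insertions["chromosome"].value_counts()
            counts[0] += vc.get("chr1", 0)
            counts[1] += vc.get("chr2", 0)
        p = scipy.stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_hotspot_is_modal_bin(self, small_genome):
        hotspot = syn.Hotspot("chr1", 10_001, 20_000, enrichment=20.0)
        truth = syn.simulate_insertions(small_genome, 500, hotspot=hotspot, seed=9)
        ins = truth.insertions
        bins = (
            ins.groupby(["chromosome", (ins["position"] - 1) // 10_000])
            .size()
            .sort_values()
        )
        assert bins.index[-1] == ("chr1", 1)  # the 10-kb hotspot window

    def test_hotspot_outside_genome_errors(self, small_genome):
        with pytest.raises(ValueError):
            syn.simulate_insertions(
                small_genome, 10,
                hotspot=syn.Hotspot("chr1", 1, 60_000), seed=0,
            )

    def test_barcodes_unique_uniform_length(self, small_genome):
        truth = syn.simulate_insertions(small_genome, 200, seed=4)
        bcs = truth.insertions["barcode"]
        assert bcs.is_unique
        assert {len(b) for b in bcs} == {20}

    def test_same_gene_mutants_share_abundance_factor(self, small_genome):
        """Hierarchical baselines: within-gene spread is much smaller than
        between-gene spread."""
        genome, truth = syn.calibration_scenario(seed=8, n_genes=50, n_planted=0)
        df = truth.insertions.copy()
        df["log_base"] = np.log([truth.baseline_abundances[b] for b in df["barcode"]])
        within = df.groupby("gene_id")["log_base"].std(ddof=1).mean()
        between = df.groupby("gene_id")["log_base"].mean().std(ddof=1)
        assert within < 0.5 < between


class TestSimulateTnseqReads:
    def test_error_free_reads_contain_exact_junction_and_flank(self, small_genome):
        truth = syn.simulate_insertions(small_genome, 1, seed=2)
        params = syn.ReadSimulationParams(substitution_rate=0.0, reads_per_insertion=3, seed=1)
        reads, log = syn.simulate_tnseq_reads(truth, small_genome, params)
        assert len(reads) == 3
        row = truth.insertions.iloc[0]
        for rec in reads:
            seq = str(rec.seq)
            assert params.junction_sequence in seq
            flank = seq.split(params.junction_sequence, 1)[1]
            assert len(flank) == params.flank_length
            chrom = small_genome.chromosomes[row.chromosome]
            if row.strand == "+":
                assert flank == chrom[row.position - 1 : row.position - 1 + 50]
            else:
                from rbscreen.genome import reverse_complement
                assert flank == reverse_complement(chrom[row.position - 50 : row.position])

    def test_minus_strand_flank_is_reverse_complement(self, small_genome):
        from rbscreen.genome import reverse_complement

        truth = syn.simulate_insertions(small_genome, 30, seed=6)
        minus = truth.insertions[truth.insertions["strand"] == "-"]
        assert len(minus) > 0
        params = syn.ReadSimulationParams(substitution_rate=0.0, reads_per_insertion=1, seed=1)
        reads, _ = syn.simulate_tnseq_reads(truth, small_genome, params)
        by_barcode = {str(r.seq)[:20]: str(r.seq) for r in reads}
        for row in minus.itertuples(index=False):
            flank = by_barcode[row.barcode].split(params.junction_sequence, 1)[1]
            chrom = small_genome.chromosomes[row.chromosome]
            ref = chrom[max(row.position - 50, 0) : row.position]
            assert flank == reverse_complement(ref)

    def test_substitution_rate_binomial_check(self, small_genome):
        truth = syn.simulate_insertions(small_genome, 40, seed=3)
        clean_params = syn.ReadSimulationParams(substitution_rate=0.0, reads_per_insertion=3, seed=5)
        noisy_params = syn.ReadSimulationParams(substitution_rate=0.01, reads_per_insertion=3, seed=5)
        clean, _ = syn.simulate_tnseq_reads(truth, small_genome, clean_params)
        noisy, _ = syn.simulate_tnseq_reads(truth, small_genome, noisy_params)
        mismatches = sum(
            a != b
            for c, n in zip(clean, noisy)
            for a, b in zip(str(c.seq), str(n.seq))
        )
        total = sum(len(r.seq) for r in clean)
        mean, sd = total * 0.01, (total * 0.01 * 0.99) ** 0.5
        assert abs(mismatches - mean) <= 3 * sd

    def test_read_names_leak_no_truth(self, small_genome):
        truth = syn.simulate_insertions(small_genome, 5, seed=1)
        params = syn.ReadSimulationParams(reads_per_insertion=2, seed=1)
        reads, _ = syn.simulate_tnseq_reads(truth, small_genome, params)
        for rec in reads:
            assert re.fullmatch(r"read_\d+", rec.id)
            assert rec.description in ("", rec.id)

    def test_flank_longer_than_shortest_chromosome_errors(self, small_genome):
        truth = syn.simulate_insertions(small_genome, 2, seed=1)
        with pytest.raises(ValueError):
            syn.simulate_tnseq_reads(
                truth, small_genome,
                syn.ReadSimulationParams(flank_length=60_000, seed=0),
            )

    def test_truncated_flanks_flagged(self):
        genome = syn.simulate_genome(
            syn.SyntheticGenomeSpec(
                n_chromosomes=1, chromosome_lengths=(500,), n_genes=0, seed=1
            )
        )
        truth = syn.SyntheticTruth(
            insertions=pd.DataFrame(
                [{"barcode": "A" * 20, "chromosome": "chr1", "position": 490,
                  "strand": "+", "gene_id": "intergenic"}]
            ),
            gene_effects={},
            baseline_abundances={"A" * 20: 1.0},
        )
        params = syn.ReadSimulationParams(flank_length=50, reads_per_insertion=2, seed=1)
        reads, log = syn.simulate_tnseq_reads(truth, genome, params)
        assert len(log["truncated_reads"]) == 2


class TestSimulateBarseqCounts:
    def test_columns_sum_to_depth(self, small_genome):
        truth = syn.simulate_insertions(small_genome, 100, seed=5)
        params = syn.CountSimulationParams(sequencing_depth=100_000, seed=2)
        table = syn.simulate_barseq_counts(truth, params)
        assert (table.counts.sum(axis=0) == 100_000).all()
        assert table.counts.shape == (100, 6)

    def test_determinism_byte_identical(self, small_genome):
        truth = syn.simulate_insertions(small_genome, 100, seed=5)
        params = syn.CountSimulationParams(sequencing_depth=1_000_000, seed=7)
        t1 = syn.simulate_barseq_counts(truth, params)
        t2 = syn.simulate_barseq_counts(truth, params)
        assert t1.counts.to_csv() == t2.counts.to_csv()

    def test_null_case_proportions_equal_across_temperatures(self, small_genome):
        """No planted effects, no replicate noise: hot and cold expected
        proportions coincide (within multinomial sampling bounds)."""
        truth = syn.simulate_insertions(small_genome, 50, seed=5)
        params = syn.CountSimulationParams(
            sequencing_depth=2_000_000, abundance_noise=0.0,
            replicates_per_temperature=1, seed=3,
        )
        table = syn.simulate_barseq_counts(truth, params)
        p = table.counts["37_1"] / 2e6
        q = table.counts["50_1"] / 2e6
        sd = np.sqrt(p * (1 - p) / 2e6 + q * (1 - q) / 2e6)
        assert (np.abs(p - q) <= 4 * sd + 1e-9).all()

    def test_planted_effect_renormalization_closed_form(self):
        """Two barcodes, one gene at effect +2 with baseline proportion p:
        the hot expected proportion is p*4 / (p*4 + (1-p))."""
        ins = pd.DataFrame(
            [
                {"barcode": "A" * 20, "chromosome": "chr1", "position": 10,
                 "strand": "+", "gene_id": "geneX"},
                {"barcode": "C" * 20, "chromosome": "chr1", "position": 500,
                 "strand": "+", "gene_id": "intergenic"},
            ]
        )
        p = 0.3
        truth = syn.SyntheticTruth(
            insertions=ins, gene_effects={"geneX": 2.0},
            baseline_abundances={"A" * 20: p, "C" * 20: 1 - p},
        )
        depth = 4_000_000
        params = syn.CountSimulationParams(
            sequencing_depth=depth, abundance_noise=0.0,
            replicates_per_temperature=1, seed=11,
        )
        table = syn.simulate_barseq_counts(truth, params)
        expected = p * 4 / (p * 4 + (1 - p))
        observed = table.counts.loc["A" * 20, "50_1"] / depth
        sd = np.sqrt(expected * (1 - expected) / depth)
        assert abs(observed - expected) <= 4 * sd
        cold = table.counts.loc["A" * 20, "37_1"] / depth
        assert abs(cold - p) <= 4 * np.sqrt(p * (1 - p) / depth)

    def test_missing_baseline_errors(self, small_genome):
        truth = syn.simulate_insertions(small_genome, 3, seed=1)
        truth.baseline_abundances.pop(truth.insertions["barcode"].iloc[0])
        with pytest.raises(ValueError):
            syn.simulate_barseq_counts(truth, syn.CountSimulationParams(seed=0))

    def test_replicate_concordance_matches_real_screens(self):
        """Default noise reproduces the high replicate reproducibility of
        real pooled screens (pairwise Pearson r > 0.99)."""
        from rbscreen.counts import replicate_concordance

        genome, truth = syn.calibration_scenario(seed=21, n_planted=0)
        table = syn.simulate_barseq_counts(truth, syn.CountSimulationParams(seed=22))
        conc = replicate_concordance(normalize_total(table))
        assert conc["pearson_r"].min() > 0.99


def test_truth_round_trip(tmp_path, small_genome):
    truth = syn.simulate_insertions(small_genome, 25, seed=13)
    syn.plant_effects(truth, 2, 2.0, seed=14)
    ins, eff = tmp_path / "truth.tsv", tmp_path / "effects.tsv"
    syn.write_truth(truth, str(ins), str(eff))
    back = syn.read_truth(str(ins), str(eff))
    pd.testing.assert_frame_equal(
        truth.insertions.reset_index(drop=True), back.insertions
    )
    assert back.gene_effects == truth.gene_effects
    assert back.baseline_abundances == pytest.approx(truth.baseline_abundances)
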