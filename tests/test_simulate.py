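"""The synthetic-data generator: determinism, truth structure, sampling
convergence, occupancy shape, and truth recovery through the analysis path."""

import numpy as np
import pandas as pd
import pytest

import endzone as ez
from endzone.clusters import detect_clusters
from endzone.config import YEAST
from endzone.io import write_genome
from endzone.simulate import (make_genome, make_intron_genome,
                              simulate_endpoint_counts, simulate_enetseq,
                              simulate_flat_coverage, simulate_polya_reads)


class TestMakeGenome:
    def test_zero_genes_empty(self):
        genome, genes, truth = make_genome(0, seed=0)
        assert genome.chromosomes == []
        assert genes == {}
        assert truth.genes == {}

    def test_seed_determinism_byte_identical_fasta(self, tmp_path):
        fastas = []
        for name in ("a.fa", "b.fa"):
            genome, _, _ = make_genome(5, gc_coupling=0.4, seed=123)
            write_genome(genome, tmp_path / name)
            fastas.append((tmp_path / name).read_bytes())
        assert fastas[0] == fastas[1]

    def test_default_utr_covers_end_zone_scale(self):
        _, genes, _ = make_genome(1, seed=1)
        assert genes["g0000"].utr_window[1] == 200

    def test_endpoints_on_non_a_bases(self, small_synth):
        genome, genes, truth = small_synth
        for g in truth.genes.values():
            gene = genes[g.gene_id]
            for off in g.endpoints:
                assert gene.base_at_offset(genome, int(off)) != "A"
                assert gene.base_at_offset(genome, int(off) + 1) != "A"

    def test_endpoints_strictly_increasing(self, small_synth):
        _, _, truth = small_synth
        for g in truth.genes.values():
            assert np.all(np.diff(g.endpoints) > 0)

    def test_truth_clusters_respect_gap_structure(self, small_synth):
        """Truth clusters re-detected at gap 4 match the generative layout."""
        _, _, truth = small_synth
        for g in truth.genes.values():
            detected = detect_clusters(g.endpoints, 4)
            assert [c.members for c in detected] == \
                [c.offsets for c in g.clusters]

    def test_gc_coupling_positively_couples_gc_to_tilt(self):
        genome, genes, truth = make_genome(80, gc_coupling=0.5, seed=9)
        gcs, tilts = [], []
        for g in truth.genes.values():
            gene = genes[g.gene_id]
            for c in g.clusters:
                lo = c.offsets[-1] + 13
                seq = gene.fetch_offsets(genome, lo, lo + 17)
                gcs.append(sum(b in "GC" for b in seq) / 18)
                tilts.append(abs(np.log(c.tilt_r)))
        assert np.corrcoef(gcs, tilts)[0, 1] > 0.5

    def test_unsatisfiable_cluster_spec_is_error(self):
        with pytest.raises(ValueError, match="utr_len"):
            make_genome(1, utr_len=50, cluster_spec=[[8, 8, 8]], seed=0)

    def test_explicit_offsets_spec(self):
        _, _, truth = make_genome(1, cluster_spec=[[(20, 22), (70,)]],
                                  seed=0)
        g = truth.genes["g0000"]
        assert [c.offsets for c in g.clusters] == [(20, 22), (70,)]

    def test_minus_strand_genes_supported(self):
        genome, genes, truth = make_genome(6, minus_strand_fraction=1.0,
                                           seed=2)
        assert all(g.strand == "-" for g in genes.values())
        for g in truth.genes.values():
            gene = genes[g.gene_id]
            for off in g.endpoints:
                assert gene.base_at_offset(genome, int(off)) != "A"


class TestUsageWeights:
    def test_mutant_tilt_is_geometric_within_cluster(self):
        _, _, truth = make_genome(1, cluster_spec=[[(20, 21, 22, 23, 24)]],
                                  tilt_r=0.9, tilt_spread=0.0, seed=3)
        g = truth.genes["g0000"]
        wt = g.usage_weights("wt")
        mut = g.usage_weights("mutant")
        ratio = (mut / wt)
        ratio /= ratio[0]
        np.testing.assert_allclose(ratio, 0.9 ** np.arange(5), rtol=1e-12)

    def test_boundary_drop_is_between_cluster_factor(self):
        _, _, truth = make_genome(1, cluster_spec=[[(20, 22), (60, 61)]],
                                  tilt_r=0.9, tilt_spread=0.0, seed=4)
        g = truth.genes["g0000"]
        u = g.usage_weights("mutant") / g.usage_weights("wt")
        # ratio across the boundary (last of c1 -> first of c2) = 0.98
        assert u[2] / u[1] == pytest.approx(0.98, rel=1e-9)

    def test_r_override_keeps_cluster_exponent(self):
        _, _, truth = make_genome(1, cluster_spec=[[(20, 21, 22, 23)]],
                                  tilt_r=0.9, seed=5)
        g = truth.genes["g0000"]
        s = g.clusters[0].tilt_exponent
        u = g.usage_weights("mutant", r_override=0.8) / g.usage_weights("wt")
        assert u[1] / u[0] == pytest.approx(0.8 ** s, rel=1e-9)


class TestEndpointSampling:
    def test_depth_zero_empty(self, small_synth):
        _, _, truth = small_synth
        assert simulate_endpoint_counts(truth, "wt", 0, seed=1).empty

    def test_weighted_sampling_binomial_oracle(self):
        """Two endpoints weighted 3:1: observed proportion within 3
        Monte-Carlo SD of 0.75 at depth 200,000."""
        genome, genes, truth = make_genome(1, cluster_spec=[[(20,), (60,)]],
                                           seed=6)
        g = truth.genes["g0000"]
        g.clusters[0].weights = (3.0,)
        g.clusters[1].weights = (1.0,)
        depth = 200_000
        df = simulate_endpoint_counts(truth, "wt", depth, seed=7)
        n20 = df.loc[df.offset == 20, "count"].sum()
        p = 0.75
        sd = np.sqrt(p * (1 - p) / depth)
        assert abs(n20 / depth - p) <= 3 * sd

    def test_seed_determinism(self, small_synth):
        _, _, truth = small_synth
        a = simulate_endpoint_counts(truth, "mutant", 1000, seed=8)
        b = simulate_endpoint_counts(truth, "mutant", 1000, seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestPolyAReads:
    def test_depth_zero_empty(self, small_synth):
        genome, genes, truth = small_synth
        reads, bed = simulate_polya_reads(truth, genes, genome, "wt", 0,
                                          seed=0)
        assert reads == [] and bed.empty

    def test_read_structure(self, small_synth):
        genome, genes, truth = small_synth
        reads, bed = simulate_polya_reads(truth, genes, genome, "wt", 5,
                                          seed=1)
        for (rid, seq), row in zip(reads, bed.itertuples(index=False)):
            body = seq[4:]
            assert body[0] == "T"
            t = len(body) - len(body.lstrip("T"))
            assert t == row.t_count >= 1

    def test_mutant_reweighting_matches_generator_definition(self):
        """Mutant endpoint frequencies follow the r^offset reweighting."""
        _, _, truth = make_genome(1, cluster_spec=[[(20, 21, 22, 23, 24)]],
                                  tilt_r=0.9, tilt_spread=0.0, seed=10)
        g = truth.genes["g0000"]
        g.clusters[0].weights = (1.0,) * 5
        df = simulate_endpoint_counts(truth, "mutant", 500_000,
                                      seed=11).set_index("offset")
        w = 0.9 ** np.arange(5)
        expected = w / w.sum()
        observed = df["count"].to_numpy() / 500_000
        np.testing.assert_allclose(observed, expected, atol=0.005)

    def test_truth_recovery_through_catalog(self, small_synth):
        """Catalog + cluster detection on simulated data recover >=95% of
        true endpoints whose weight is >=5% of the gene maximum."""
        _, _, truth = small_synth
        cat = ez.build_catalog(
            simulate_endpoint_counts(truth, "wt", 100_000, seed=12), YEAST)
        n_expected = n_found = 0
        for g in truth.genes.values():
            w = g.usage_weights("wt")
            majors_true = g.endpoints[w >= 0.05 * w.max()]
            flagged = ez.select_major_isoforms(cat[g.gene_id], YEAST)
            found = set(flagged.major_offsets().tolist())
            n_expected += majors_true.size
            n_found += sum(int(o) in found for o in majors_true)
        assert n_found / n_expected >= 0.95

    def test_truth_recovery_through_full_read_path(self, small_synth):
        genome, genes, truth = small_synth
        reads, _ = simulate_polya_reads(truth, genes, genome, "wt",
                                        depth=600, artifact_rate=0.2,
                                        seed=13)
        tagged, _ = ez.preprocess_reads(reads, YEAST)
        mapped = ez.naive_align(tagged, genome)
        kept, _ = ez.filter_internal_priming(mapped, genome)
        scaled = ez.consolidate_and_scale([kept], 25_000_000)
        eps, _ = ez.assign_to_genes(scaled, genes, YEAST)
        cat = ez.build_catalog(eps, YEAST)
        n_expected = n_found = 0
        for g in truth.genes.values():
            w = g.usage_weights("wt")
            majors_true = g.endpoints[w >= 0.10 * w.max()]
            flagged = ez.select_major_isoforms(cat[g.gene_id], YEAST)
            found = set(flagged.major_offsets().tolist())
            n_expected += majors_true.size
            n_found += sum(int(o) in found for o in majors_true)
        assert n_found / n_expected >= 0.9


class TestEnetseq:
    def test_depth_zero_all_zero(self, small_synth):
        genome, genes, truth = small_synth
        cov = simulate_enetseq(truth, genes, genome, "wt", 0, seed=0)
        assert cov.total() == 0

    def test_bump_amplitudes_vs_baseline(self):
        genome, genes, truth = make_genome(3, cluster_spec=[[(60,)]] * 3,
                                           seed=14)
        cov = simulate_enetseq(truth, genes, genome, "wt", 1_000_000,
                               seed=15)
        gene = genes["g0000"]

        def mean_over(a, b):
            vals = [cov.query(gene.chrom,
                              gene.offset_to_genomic(60 + o), gene.strand)
                    for o in range(a, b + 1)]
            return np.mean(vals)

        baseline = mean_over(-100, -50)
        assert mean_over(10, 25) / baseline == pytest.approx(1.5, rel=0.05)
        assert mean_over(30, 100) / baseline == pytest.approx(2.5, rel=0.05)
        assert mean_over(-40, -1) / baseline == pytest.approx(0.6, rel=0.05)

    def test_second_bump_stronger_than_first(self):
        _, _, truth = make_genome(1, seed=0)
        occ = truth.occupancy
        assert occ.bump2 > occ.bump1
        assert occ.bump2_window[0] == 30 and occ.bump2_window[1] == 100


class TestIntronFixtures:
    def test_planted_hexamers_present(self):
        genome, introns, planted = make_intron_genome(seed=16)
        for chrom, start, strand in planted:
            assert genome.fetch(chrom, start, start + 6, strand) == "AATAAA"

    def test_flat_coverage_rate(self):
        genome, introns, _ = make_intron_genome(n_introns=1, seed=17)
        cov = simulate_flat_coverage(introns, 2.0, seed=18)
        n_bases = int(introns.iloc[0]["length"])
        assert cov.total() / n_bases == pytest.approx(2.0, rel=0.05)
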