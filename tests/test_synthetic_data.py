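import numpy as np
import pytest
from scipy import stats

import integscape as ig
from integscape.genomic_core import overlap_count
from integscape.sequence_profile import step_table, window_means
from integscape.site_filtering import site_has_re_motif
from integscape.synthetic_data import (
    BiasSpec,
    make_expression_table,
    make_gene_models,
    make_genome,
    simulate_sites,
)


class TestGenome:
    def test_gc_fraction_within_binomial_error(self):
        g = make_genome(100_000, gc_fraction=0.5, seed=1)
        seq = g.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 6 * np.sqrt(0.25 / 100_000)

    def test_determinism_and_divergence(self):
        assert make_genome(5000, 0.4, seed=2).sequences == \
            make_genome(5000, 0.4, seed=2).sequences
        assert make_genome(5000, 0.4, seed=2).sequences != \
            make_genome(5000, 0.4, seed=3).sequences

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            make_genome(1000, 0.0, seed=0)

    def test_multi_chromosome_split(self):
        g = make_genome(10_000, 0.4, seed=4, n_chroms=3)
        assert len(g.sequences) == 3
        assert g.total_length == 10_000


class TestGeneModels:
    def test_placement_and_consistency(self, small_genome):
        # shorter spans so 20 genes pack into 200 kb with the 2-kb gaps
        genes, tracks = make_gene_models(small_genome, n_genes=20,
                                         length_range=(2000, 6000), seed=5)
        assert len(genes) == 20
        spans = sorted((g.span.start, g.span.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # non-overlapping
        for g in genes:
            # exon + intron lengths tile the span exactly
            total = sum(len(e) for e in g.exons) + sum(
                len(i) for i in g.introns)
            assert total == len(g.span)
            five_prime = g.span.start if g.span.strand == "+" else g.span.end - 1
            assert g.tss == five_prime

    def test_derived_exon_intron_union_equals_span_track(self, small_genome):
        genes, tracks = make_gene_models(small_genome, n_genes=15,
                                         length_range=(2000, 6000), seed=6)
        union_bp = tracks["exons"].total_bp() + tracks["introns"].total_bp()
        assert union_bp == tracks["gene_spans"].total_bp()

    def test_intergenic_complements_gene_neighbourhoods(self, small_genome):
        genes, tracks = make_gene_models(small_genome, n_genes=10, seed=7)
        covered = tracks["intergenic"].total_bp()
        blocks = []
        for g in genes:
            blocks.append((max(0, g.span.start - 5000),
                           min(200_000, g.span.end + 5000)))
        blocks.sort()
        merged = []
        for lo, hi in blocks:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        assert covered == 200_000 - sum(hi - lo for lo, hi in merged)


class TestSimulateSites:
    def test_unbiased_placement_is_uniform(self, small_genome,
                                           small_annotation):
        genes, tracks = small_annotation
        sites = simulate_sites(small_genome, genes, tracks, 3000,
                               BiasSpec(seed=20))
        pos = np.array([s.insertion_point for s in sites])
        counts, _ = np.histogram(pos, bins=10, range=(0, 200_000))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_determinism_per_seed(self, small_genome, small_annotation):
        genes, tracks = small_annotation
        a = simulate_sites(small_genome, genes, tracks, 50, BiasSpec(seed=9))
        b = simulate_sites(small_genome, genes, tracks, 50, BiasSpec(seed=9))
        assert a == b

    def test_exon_fold_shifts_overlap(self, small_genome, small_annotation):
        genes, tracks = small_annotation
        flat = simulate_sites(small_genome, genes, tracks, 2000, BiasSpec(seed=10))
        boosted = simulate_sites(
            small_genome, genes, tracks, 2000,
            BiasSpec(feature_folds={"exons": 4.0}, seed=10))
        n_flat = overlap_count(flat, tracks["exons"])
        n_boost = overlap_count(boosted, tracks["exons"])
        assert n_boost > 2 * n_flat

    def test_tss_bias_concentrates_near_tss(self, small_genome,
                                            small_annotation):
        genes, tracks = small_annotation
        sites = simulate_sites(
            small_genome, genes, tracks, 1000,
            BiasSpec(tss_bias=(10.0, 500), seed=11))
        from integscape.gene_context import anchor_profile

        near = anchor_profile(sites, genes, "TSS", window_bp=500, bin_bp=100)
        farther = anchor_profile(sites, genes, "TSS", window_bp=2000, bin_bp=100)
        frac_near = near["count"].sum() / max(1, farther["count"].sum())
        assert frac_near > 0.5

    def test_flexibility_bias_raises_window_mean(self, small_genome,
                                                 small_annotation):
        genes, tracks = small_annotation
        t = step_table()

        def mean_twist(sites):
            wins = ig.extract_flank_windows(sites, small_genome,
                                            "transposon_tsd")
            return window_means(wins.windows, t, "Twist").mean()

        flat = simulate_sites(small_genome, genes, tracks, 800, BiasSpec(seed=12))
        tilted = simulate_sites(
            small_genome, genes, tracks, 800,
            BiasSpec(flexibility_bias=("Twist", 1.0), seed=12))
        assert mean_twist(tilted) > mean_twist(flat) + 0.02

    def test_noise_singletons_are_re_adjacent_count_one(self, small_genome,
                                                        small_annotation):
        genes, tracks = small_annotation
        sites = simulate_sites(
            small_genome, genes, tracks, 200,
            BiasSpec(noise_singleton_fraction=0.25, seed=13))
        singles = [s for s in sites if s.fragment_count == 1]
        assert len(singles) == 50
        assert all(site_has_re_motif(s, small_genome) for s in singles)

    def test_fragment_counts_positive_and_spread(self, small_genome,
                                                 small_annotation):
        genes, tracks = small_annotation
        sites = simulate_sites(small_genome, genes, tracks, 500, BiasSpec(seed=14))
        counts = np.array([s.fragment_count for s in sites])
        assert counts.min() >= 2
        assert counts.max() > 500  # heavy lognormal tail

    def test_tsd_flag_controls_interval_length(self, small_genome,
                                               small_annotation):
        genes, tracks = small_annotation
        tsd = simulate_sites(small_genome, genes, tracks, 20,
                             BiasSpec(tsd=True, seed=15))
        pt = simulate_sites(small_genome, genes, tracks, 20,
                            BiasSpec(tsd=False, seed=15))
        assert all(len(s.location) == 8 for s in tsd)
        assert all(len(s.location) == 1 for s in pt)


class TestExpressionTable:
    def test_classes_exactly_recoverable(self, small_annotation):
        genes, _ = small_annotation
        expr = make_expression_table(genes, seed=16)
        # the generator draws expressed values >= 1 and silent < 1, so the
        # classifier must recover the planted class of every gene
        classes = expr.classes
        fpkm = expr.fpkm
        for gid in fpkm.index:
            pre = (fpkm.loc[gid].iloc[:2] >= 1).any()
            post = (fpkm.loc[gid].iloc[2:] >= 1).any()
            expected = ("maternal_zygotic" if pre and post else
                        "maternal_only" if pre else
                        "zygotic_only" if post else "silent")
            assert classes[gid] == expected

    def test_overall_is_row_sum(self, small_annotation):
        genes, _ = small_annotation
        expr = make_expression_table(genes, seed=17)
        assert np.allclose(expr.overall, expr.fpkm.sum(axis=1))

    def test_bad_fractions_rejected(self, small_annotation):
        genes, _ = small_annotation
        with pytest.raises(ValueError):
            make_expression_table(genes, class_fractions={"silent": 0.5},
                                  seed=18)
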