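import numpy as np
import pytest

from integscape.genomic_core import Genome, GenomicInterval, reverse_complement
from integscape.sequence_profile import (
    PARAMETERS,
    STEPS,
    FlankWindowSet,
    extract_flank_windows,
    flexibility_profile,
    position_matrix,
    profile_divergence,
    region_divergence,
    step_table,
)
from conftest import make_site


class TestWindowGeometry:
    def test_tsd_layout_is_20_8_20(self, small_genome):
        site = make_site("chr1", 100, "+", length=8)
        ws = extract_flank_windows([site], small_genome, "transposon_tsd")
        (w,) = ws.windows
        assert len(w) == 48
        assert w == small_genome.sequences["chr1"][80:128]
        assert w[20:28] == small_genome.sequences["chr1"][100:108]

    def test_point_layout_position_21(self, small_genome):
        p = 500
        site = make_site("chr1", p, "+")
        (w,) = extract_flank_windows([site], small_genome,
                                     "point_integration").windows
        assert len(w) == 48
        assert w == small_genome.sequences["chr1"][p - 20:p + 28]
        assert w[20] == small_genome.sequences["chr1"][p]  # 1-based pos 21

    def test_minus_strand_point_window(self):
        seq = "ACGTTGCATTGGAACCTTGGACGTACGTAGCTAGCTAGGATCCAAGGTTCCAATTGGCC"
        g = Genome({"c1": seq})
        p = 30
        (w,) = extract_flank_windows([make_site("c1", p, "-")], g,
                                     "point_integration").windows
        # oriented window: 20 bases 5' of the site on the minus strand,
        # then the site base, then 27 more
        assert w == reverse_complement(seq[p - 27:p + 21])
        assert w[20] == reverse_complement(seq[p])

    def test_minus_strand_tsd_window(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        g = Genome({"c1": seq})
        site = make_site("c1", 100, "-", length=8)
        (w,) = extract_flank_windows([site], g, "transposon_tsd").windows
        assert w == reverse_complement(seq[80:128])
        assert w[20:28] == reverse_complement(seq[100:108])

    def test_out_of_bounds_and_n_windows_excluded(self):
        g = Genome({"c1": "A" * 30 + "N" + "A" * 100})
        sites = [make_site("c1", 5, length=8),     # runs off the left edge
                 make_site("c1", 25, length=8),    # covers the N
                 make_site("c1", 60, length=8)]
        ws = extract_flank_windows(sites, g, "transposon_tsd")
        assert len(ws.windows) == 1 and ws.n_excluded == 2

    def test_layout_mismatch_raises(self, small_genome):
        with pytest.raises(ValueError, match="8-bp"):
            extract_flank_windows([make_site("chr1", 100, length=1)],
                                  small_genome, "transposon_tsd")
        with pytest.raises(ValueError, match="1-bp"):
            extract_flank_windows([make_site("chr1", 100, length=8)],
                                  small_genome, "point_integration")


class TestPositionMatrix:
    def test_identical_windows_two_bits(self):
        ws = FlankWindowSet(["ACGT"] * 10, "point_integration")
        pm = position_matrix(ws)
        assert np.allclose(pm.bits, 2.0)
        assert pm.probs.loc[1, "A"] == 1.0

    def test_uniform_position_zero_bits(self):
        ws = FlankWindowSet(["A", "C", "G", "T"], "point_integration")
        pm = position_matrix(ws)
        assert pm.bits[0] == pytest.approx(0.0)

    def test_two_base_position_one_bit(self):
        ws = FlankWindowSet(["A", "A", "C", "C"], "point_integration")
        assert position_matrix(ws).bits[0] == pytest.approx(1.0)

    def test_probabilities_sum_to_one_and_bits_bounded(self, small_genome):
        rng = np.random.default_rng(1)
        sites = [make_site("chr1", int(p), length=8)
                 for p in rng.integers(100, 199_000, size=50)]
        ws = extract_flank_windows(sites, small_genome, "transposon_tsd")
        pm = position_matrix(ws)
        assert np.allclose(pm.probs.sum(axis=1), 1.0)
        assert np.all((pm.bits >= 0) & (pm.bits <= 2))


class TestStepTable:
    def test_published_anchor_values(self):
        t = step_table()
        assert t.value("Twist", "GC") == 36.1
        assert t.value("Slide", "GC") == 0.41
        assert t.value("Twist", "GG") == 32.9
        assert t.value("Slide", "GG") == -0.22

    def test_reverse_complement_symmetry_all_steps(self):
        t = step_table()
        for s in STEPS:
            rc = reverse_complement(s)
            for p in ("Twist", "Roll", "Rise", "Slide"):
                assert t.value(p, s) == pytest.approx(t.value(p, rc))
            for p in ("Tilt", "Shift"):
                assert t.value(p, s) == pytest.approx(-t.value(p, rc))

    def test_tilt_antisymmetry_example(self):
        t = step_table()
        assert t.value("Tilt", "AG") == -t.value("Tilt", "CT")


class TestFlexibilityProfile:
    def test_homopolymer_constant_profile(self):
        ws = FlankWindowSet(["A" * 48] * 5, "transposon_tsd")
        t = step_table()
        prof = flexibility_profile(ws, t, "Twist")
        assert prof.n_positions == 47
        assert np.allclose(prof.values, t.value("Twist", "AA"))

    def test_single_window_matches_hand_lookup(self):
        t = step_table()
        w = "ACGTACGTAC"
        prof = flexibility_profile(FlankWindowSet([w], "point_integration"),
                                   t, "Slide")
        expected = [t.value("Slide", w[i:i + 2]) for i in range(9)]
        assert np.allclose(prof.values, expected)

    def test_duplication_invariance(self, small_genome):
        rng = np.random.default_rng(2)
        sites = [make_site("chr1", int(p), length=8)
                 for p in rng.integers(100, 199_000, size=30)]
        ws = extract_flank_windows(sites, small_genome, "transposon_tsd")
        t = step_table()
        single = flexibility_profile(ws, t, "Roll").values
        doubled = flexibility_profile(
            FlankWindowSet(ws.windows * 2, ws.layout), t, "Roll").values
        assert np.allclose(single, doubled)

    def test_strand_pooling_symmetry(self, small_genome):
        """A window set pooled with its reverse complements is strand-blind:
        Twist/Roll/Rise/Slide profiles become midpoint-symmetric and
        Tilt/Shift antisymmetric, to machine precision."""
        rng = np.random.default_rng(3)
        sites = [make_site("chr1", int(p), length=8)
                 for p in rng.integers(100, 199_000, size=40)]
        ws = extract_flank_windows(sites, small_genome, "transposon_tsd")
        pooled = FlankWindowSet(
            ws.windows + [reverse_complement(w) for w in ws.windows],
            ws.layout)
        t = step_table()
        for p in ("Twist", "Roll", "Rise", "Slide"):
            v = flexibility_profile(pooled, t, p).values
            assert np.allclose(v, v[::-1])
        for p in ("Tilt", "Shift"):
            v = flexibility_profile(pooled, t, p).values
            assert np.allclose(v, -v[::-1])


class TestDivergence:
    @staticmethod
    def profile_with_controls(small_genome, n_exp=40, n_rep=40, seed=5):
        rng = np.random.default_rng(seed)
        t = step_table()
        def window_set():
            sites = [make_site("chr1", int(p), length=8)
                     for p in rng.integers(100, 199_000, size=n_exp)]
            return extract_flank_windows(sites, small_genome, "transposon_tsd")
        return flexibility_profile(window_set(), t, "Twist",
                                   [window_set() for _ in range(n_rep)])

    def test_zero_deviation_gives_zero_z(self):
        import pandas as pd
        from integscape.sequence_profile import FlexibilityProfile

        ctrl = np.tile(np.linspace(30, 38, 47), (40, 1))
        ctrl += np.random.default_rng(0).normal(0, 0.1, ctrl.shape)
        prof = FlexibilityProfile(
            parameter="Twist", values=ctrl.mean(axis=0),
            control_mean=ctrl.mean(axis=0), control_sd=ctrl.std(axis=0, ddof=1),
            control_profiles=ctrl)
        div = profile_divergence(prof)
        assert np.allclose(div["z"], 0.0)
        assert np.all(div["empirical_p"] == 1.0)

    def test_too_few_replicates_rejected(self, small_genome):
        prof = self.profile_with_controls(small_genome, n_rep=10)
        with pytest.raises(ValueError, match="30"):
            profile_divergence(prof)

    def test_null_z_behaves_like_standard_normal(self, small_genome):
        prof = self.profile_with_controls(small_genome, n_exp=60, n_rep=60)
        div = profile_divergence(prof)
        z = div["z"].to_numpy()
        assert np.abs(z).max() < 5
        assert abs(np.mean(z)) < 1.0
        rz, emp = region_divergence(prof)
        assert abs(rz) < 4
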