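"""The synthetic cohort generator: determinism, planted structure, round-trips."""

import numpy as np
import pytest
from scipy import stats

from nucperiod import genome_io as gio
from nucperiod import initiation as ini
from nucperiod import synthetic as syn
from nucperiod.genome_io import SCAN_WINDOW, TAG_WINDOW
from nucperiod.nucleosomes import read_fragments


class TestSequenceGeneration:
    def test_seed_reproducibility(self):
        cfg = syn.SimConfig(seed=3)
        s1, _ = syn.simulate_promoter_sequence(cfg, np.random.default_rng(9))
        s2, _ = syn.simulate_promoter_sequence(cfg, np.random.default_rng(9))
        assert s1 == s2

    def test_full_amplitude_forces_planted_slots(self):
        cfg = syn.SimConfig(amplitude=1.0, periodic_code="WW")
        seq, truth = syn.simulate_promoter_sequence(cfg, np.random.default_rng(1))
        for slot in truth["planted_slots"]:
            i = slot - SCAN_WINDOW.start
            assert seq[i] in "AT" and seq[i + 1] in "AT"

    def test_zero_amplitude_matches_background(self):
        """a=0 leaves the sequence statistically indistinguishable from the
        background composition (chi-square on base counts, fixed seed)."""
        cfg = syn.SimConfig(amplitude=0.0)
        seq, truth = syn.simulate_promoter_sequence(cfg, np.random.default_rng(12))
        assert truth["planted_slots"] == []
        counts = [seq.count(b) for b in "ACGT"]
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_consensus_pattern_planting(self):
        cfg = syn.SimConfig(amplitude=1.0, periodic_code="SSYYNWWNRR")
        seq, truth = syn.simulate_promoter_sequence(cfg, np.random.default_rng(4))
        from nucperiod.consensus_motifs import mismatches

        for slot in truth["planted_slots"]:
            i = slot - SCAN_WINDOW.start
            assert mismatches("SSYYNWWNRR", seq[i:i + 10]) == 0


class TestFragments:
    def test_zero_depth_empty(self):
        cfg = syn.SimConfig(fragments_per_promoter=0.0)
        p = gio.PromoterRecord("c", 5_000, "+", "p")
        assert syn.simulate_fragments(cfg, p, np.random.default_rng(0)) == []

    def test_all_fragments_147(self):
        cfg = syn.SimConfig()
        p = gio.PromoterRecord("c", 5_000, "-", "p")
        frags = syn.simulate_fragments(cfg, p, np.random.default_rng(0))
        assert frags and all(len(f) == 147 for f in frags)


class TestCage:
    def test_zero_depth_empty(self):
        cfg = syn.SimConfig(tag_depth=0.0)
        counts = syn.simulate_cage(cfg, np.random.default_rng(0))
        assert counts.sum() == 0

    def test_focused_mode_zero_di(self):
        cfg = syn.SimConfig(cage_mode="focused", tag_depth=500)
        counts = syn.simulate_cage(cfg, np.random.default_rng(0))
        r = ini.dispersion_index(ini.positions_from_counts(counts))
        assert r.defined and r.di == 0.0

    def test_periodic_mode_phases_with_cosine(self):
        """High-depth periodic initiation scores positive cosine covariance
        for at least 95% of promoters."""
        cfg = syn.SimConfig(cage_mode="periodic", tag_depth=10_000)
        root = np.random.SeedSequence(8).spawn(100)
        offsets = TAG_WINDOW.offsets()
        positive = 0
        for ss in root:
            counts = syn.simulate_cage(cfg, np.random.default_rng(ss))
            marks = ini.micro_peaks(counts, min_tags=100)
            if ini.cosine_covariance(marks, offsets) > 0:
                positive += 1
        assert positive >= 95

    def test_gaussian_mode_has_no_phase(self):
        # sigma well above the 10-bp period: for narrow piles the 5-bp
        # local-maximum rule itself spaces marks ~5 bp apart, an anti-phase
        # artifact of the extraction rather than planted structure
        cfg = syn.SimConfig(cage_mode="gaussian", sigma=15.0, tag_depth=10_000)
        root = np.random.SeedSequence(9).spawn(100)
        offsets = TAG_WINDOW.offsets()
        covs = []
        for ss in root:
            counts = syn.simulate_cage(cfg, np.random.default_rng(ss))
            marks = ini.micro_peaks(counts, min_tags=100)
            covs.append(ini.cosine_covariance(marks, offsets))
        assert abs(np.median(covs)) < 0.01


class TestVariants:
    def test_empty_spec(self):
        cfg = syn.SimConfig(variants_per_promoter=0)
        seq, _ = syn.simulate_promoter_sequence(cfg, np.random.default_rng(0))
        assert syn.simulate_variants(cfg, seq, np.random.default_rng(1)) == []

    def test_no_overlap(self):
        cfg = syn.SimConfig(variants_per_promoter=12, indel_fraction=0.5)
        seq, _ = syn.simulate_promoter_sequence(cfg, np.random.default_rng(0))
        vs = syn.simulate_variants(cfg, seq, np.random.default_rng(1))
        spans = sorted((v.pos, v.pos + len(v.ref)) for v in vs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_ref_alleles_match_sequence(self):
        cfg = syn.SimConfig(variants_per_promoter=8, indel_fraction=0.3)
        seq, _ = syn.simulate_promoter_sequence(cfg, np.random.default_rng(2))
        for v in syn.simulate_variants(cfg, seq, np.random.default_rng(3)):
            i = v.pos - SCAN_WINDOW.start
            assert seq[i:i + len(v.ref)] == v.ref


class TestCohort:
    def test_determinism(self):
        cfg = syn.SimConfig(seed=5, n_promoters=6, variant_fraction=0.5)
        a = syn.simulate_cohort(cfg)
        b = syn.simulate_cohort(cfg)
        for pid in a.promoters.ids():
            assert a.members[pid].oriented_seq == b.members[pid].oriented_seq
            assert a.members[pid].fragments == b.members[pid].fragments
            np.testing.assert_array_equal(a.members[pid].cage_ref[0],
                                          b.members[pid].cage_ref[0])
            assert a.members[pid].variants == b.members[pid].variants

    def test_oriented_sequence_recovered_from_genome(self):
        """extract_window on the written genome reproduces the oriented
        sequence for both strands."""
        cfg = syn.SimConfig(seed=6, n_promoters=4)
        cohort = syn.simulate_cohort(cfg)
        for p in cohort.promoters:
            extracted = gio.extract_window(cohort.genome, p, SCAN_WINDOW)
            assert extracted == cohort.members[p.id].oriented_seq

    def test_file_round_trips(self, tmp_path):
        """Emitted FASTA/BED/tag/VCF fixtures round-trip through the readers."""
        cfg = syn.SimConfig(seed=8, n_promoters=4, variant_fraction=1.0,
                            variants_per_promoter=3, indel_fraction=0.3,
                            tag_depth=200)
        cohort = syn.simulate_cohort(cfg)
        cohort.write_genome_fasta(tmp_path / "g.fa")
        cohort.write_promoters_bed(tmp_path / "p.bed")
        cohort.write_fragments_bed(tmp_path / "f.bed")
        cohort.write_cage_bed(tmp_path / "t.bed")
        cohort.write_vcf(tmp_path / "v.vcf")

        genome = gio.open_genome(tmp_path / "g.fa")
        promoters = gio.read_promoters(tmp_path / "p.bed")
        assert promoters.ids() == cohort.promoters.ids()
        for p in promoters:
            assert str(genome[p.chrom][:]) == cohort.genome[p.chrom]
            assert gio.extract_window(genome, p, SCAN_WINDOW) == \
                cohort.members[p.id].oriented_seq

        frags = read_fragments(tmp_path / "f.bed")
        assert sorted(frags) == sorted(cohort.fragments())

        tags = gio.TagCounts.read_bed(tmp_path / "t.bed")
        for p in promoters:
            np.testing.assert_array_equal(
                tags.promoter_profile(p, TAG_WINDOW),
                cohort.members[p.id].cage_ref[0])

        variants = gio.read_vcf(tmp_path / "v.vcf")
        n_expected = sum(len(m.variants) for m in cohort.members.values())
        assert len(variants) == n_expected
        # genomic ref alleles must match the written genome
        for v in variants:
            assert str(genome[v.chrom][v.pos:v.pos + len(v.ref)]) == v.ref

    def test_weak_fraction_lowers_amplitude(self):
        cfg = syn.SimConfig(seed=9, n_promoters=40, weak_fraction=0.5,
                            weak_amplitude=0.0, amplitude=0.9)
        cohort = syn.simulate_cohort(cfg)
        amps = [m.truth["amplitude"] for m in cohort.members.values()]
        assert 0.0 in amps and 0.9 in amps

    def test_di_power_table_plants_linear_relation(self):
        df = syn.simulate_di_power_table(n_promoters=100, c=5.0, k=0.2,
                                         noise_sd=0.0, seed=2)
        # power is exactly linear in the true DI; measured DI is close to it
        fit = stats.linregress(df["di"], df["power"])
        assert fit.slope < 0 and abs(fit.slope + 0.2) < 0.05
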