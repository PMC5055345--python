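"""Most-likely reference, sequence patching and per-window variant effects."""

import numpy as np
import pytest

from nucperiod import variant_effects as ve
from nucperiod.genome_io import RelativeWindow, SCAN_WINDOW, VariantRecord
from nucperiod.synthetic import SimConfig, simulate_cohort
from nucperiod.pipeline import run_fig4


def _v(pos, ref, alt, chrom="c", zyg="hom", af=None):
    return VariantRecord(chrom, pos, ref, alt, zyg, af)


class TestMostLikelyAlleles:
    def test_major_alt_wins(self):
        table = ve.most_likely_alleles([_v(10, "A", "G", af=0.7)])
        assert table.loc[0, "ml_allele"] == "G"

    def test_tie_keeps_reference(self):
        table = ve.most_likely_alleles([_v(10, "A", "G", af=0.5)])
        assert table.loc[0, "ml_allele"] == "A"

    def test_missing_frequency_flagged(self):
        table = ve.most_likely_alleles([_v(10, "A", "G")])
        assert not table.loc[0, "has_freq"] and table.loc[0, "ml_allele"] == "A"

    def test_sample_matching_ml_excluded(self):
        ml = ve.most_likely_alleles([_v(10, "A", "G", af=0.9)])
        # GM-style sample is hom G at a site where the ML genome carries G
        diffs = ve.select_sample_differences([_v(10, "A", "G")], ml)
        assert diffs == []

    def test_sample_differing_from_ml_kept(self):
        ml = ve.most_likely_alleles([_v(10, "A", "G", af=0.2)])
        diffs = ve.select_sample_differences([_v(10, "A", "G")], ml)
        assert len(diffs) == 1

    def test_het_never_selected(self):
        ml = ve.most_likely_alleles([_v(10, "A", "G", af=0.2)])
        assert ve.select_sample_differences([_v(10, "A", "G", zyg="het")],
                                            ml) == []


class TestPatch:
    def test_snp_substitutes_in_place(self):
        out = ve.patch("ACGT", [_v(2, "G", "T")])
        assert out.sequence == "ACTT"

    def test_insertion_shifts_map(self):
        out = ve.patch("ACGT", [_v(1, "C", "CAA")])
        assert out.sequence == "ACAAGT"
        assert out.map_position(3) == 5
        assert out.map_position(1) == 1

    def test_deletion_shifts_map(self):
        out = ve.patch("ACGTAC", [_v(1, "CGT", "C")])
        assert out.sequence == "ACAC"
        assert out.map_position(4) == 2

    def test_zero_variants_identity(self):
        out = ve.patch("ACGT", [])
        assert out.sequence == "ACGT"
        assert [out.map_position(i) for i in range(4)] == [0, 1, 2, 3]

    def test_reference_mismatch_names_position(self):
        with pytest.raises(ValueError, match="c:2"):
            ve.patch("ACGT", [_v(2, "A", "T")])

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ve.patch("ACGTACGT", [_v(1, "CGT", "C"), _v(2, "G", "A")])

    def test_heterozygous_rejected(self):
        with pytest.raises(ValueError, match="heterozygous"):
            ve.patch("ACGT", [_v(2, "G", "T", zyg="het")])

    def test_origin_offset(self):
        out = ve.patch("ACGT", [_v(-73, "C", "T")], origin=-74)
        assert out.sequence == "ATGT"

    def test_round_trip(self):
        """patch followed by the inverse variants restores the original."""
        rng = np.random.default_rng(15)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        variants = [
            _v(20, seq[20], "T" if seq[20] != "T" else "A"),
            _v(100, seq[100], seq[100] + "GATTACA"),
            _v(200, seq[200:205], seq[200]),
        ]
        fwd = ve.patch(seq, variants)
        back = ve.patch(fwd.sequence, fwd.inverse_variants())
        assert back.sequence == seq
        for pos in (0, 50, 150, 250, 299):
            assert back.map_position(fwd.map_position(pos)) == pos


class TestDeltaDiByWindow:
    def test_windows_covering_variant_report_mean(self):
        df = ve.delta_di_by_window({"p": 4.0}, {"p": [(120, "SNP")]},
                                   span=RelativeWindow(-200, 301))
        assert (df["mean_delta_di"] == 4.0).all()
        centers = df["center"].to_numpy()
        # variant at +120 is covered by windows centered within +-75 of it
        assert centers.min() >= 120 - 75 and centers.max() <= 120 + 75

    def test_no_variants_empty(self):
        df = ve.delta_di_by_window({"p": 4.0}, {"p": []})
        assert df.empty

    def test_kind_filter(self):
        offsets = {"p": [(120, "indel")]}
        assert ve.delta_di_by_window({"p": 1.0}, offsets, kind="SNP").empty
        assert not ve.delta_di_by_window({"p": 1.0}, offsets, kind="indel").empty

    def test_planted_n1_inflation_localizes(self):
        """Only variants inside [+50,+200) inflate DI: |Delta-DI| peaks there."""
        rng = np.random.default_rng(33)
        delta_di, offsets = {}, {}
        for i in range(300):
            pid = f"p{i}"
            pos = int(rng.integers(-800, 800))
            offsets[pid] = [(pos, "SNP")]
            inside = 50 <= pos < 200
            delta_di[pid] = (6.0 if inside else 0.0) + rng.normal(0, 0.5)
        df = ve.delta_di_by_window(delta_di, offsets)
        peak = df.loc[df["mean_delta_di"].abs().idxmax(), "center"]
        assert 50 <= peak < 200

    def test_position_independent_effects_are_flat(self):
        """ddi drawn independently of variant position gives a flat profile."""
        rng = np.random.default_rng(44)
        delta_di, offsets = {}, {}
        for i in range(400):
            pid = f"p{i}"
            offsets[pid] = [(int(rng.integers(-900, 900)), "SNP")]
            delta_di[pid] = rng.normal(0.0, 2.0)
        df = ve.delta_di_by_window(delta_di, offsets)
        grand = np.mean(list(delta_di.values()))
        se = df.apply(lambda r: 2.0 / np.sqrt(r["n"]), axis=1)
        assert ((df["mean_delta_di"] - grand).abs() <= 4 * se).all()


class TestDeltaPowerRegression:
    def test_degenerate_regressor_omitted(self):
        seq = "ACGT" * 100
        ref = {"p%d" % i: seq for i in range(5)}
        patched = {pid: ve.patch(s, []) for pid, s in ref.items()}
        ddi = {pid: 1.0 for pid in ref}
        offsets = {pid: [(50, "SNP")] for pid in ref}
        df = ve.delta_power_vs_delta_di(ref, patched, ddi, offsets,
                                        seq_start_offset=0,
                                        span=RelativeWindow(0, 400))
        assert df.empty  # all Delta-power identically zero

    def test_planted_coupling_recovered(self, tmp_path):
        """Delta-DI = -2*Delta-power + eps: slope at the planted window
        within 20% of -2."""
        cfg = SimConfig(seed=11, n_promoters=100, variant_fraction=1.0,
                        variants_per_promoter=8, tag_depth=5_000,
                        di_coupling=2.0, di_coupling_noise=0.25)
        out = run_fig4(simulate_cohort(cfg), tmp_path)
        row = out["slopes"].set_index("center").loc[125]
        assert -2.4 <= row["slope"] <= -1.6

    def test_disruptive_snp_sign(self):
        """A periodicity-destroying SNP has Delta-power < 0; with planted
        Delta-DI > 0 it contributes a negative point."""
        cfg = SimConfig(seed=5, amplitude=1.0)
        rng = np.random.default_rng(2)
        from nucperiod.synthetic import simulate_promoter_sequence

        seq, truth = simulate_promoter_sequence(cfg, rng)
        lo = 50 - SCAN_WINDOW.start
        # knock out several planted W slots across the N+1 window
        variants = []
        for slot in truth["planted_slots"][::2]:
            ref = seq[slot - SCAN_WINDOW.start]
            variants.append(_v(slot, ref, "C" if ref in "AT" else "A"))
        patched = ve.patch(seq, variants, origin=SCAN_WINDOW.start)
        p_ref = ve.window_power(seq[lo:lo + 150])
        p_alt = ve.window_power(patched.sequence[lo:lo + 150])
        assert p_alt < p_ref


class TestFig4SignRecovery:
    def test_negative_slope_sign_recovered_across_replicates(self, tmp_path):
        """The full variants -> Delta-power -> Delta-DI pipeline recovers the
        planted negative coupling sign in >=95% of seeded replicates."""
        n_rep = 20
        negative = 0
        for rep in range(n_rep):
            cfg = SimConfig(seed=1_000 + rep, n_promoters=40,
                            variant_fraction=1.0, variants_per_promoter=6,
                            tag_depth=1_000, di_coupling=2.0,
                            di_coupling_noise=0.5)
            out = run_fig4(simulate_cohort(cfg), tmp_path / "rep")
            slopes = out["slopes"].set_index("center")
            if 125 in slopes.index and slopes.loc[125, "slope"] < 0:
                negative += 1
        assert negative >= 0.95 * n_rep
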