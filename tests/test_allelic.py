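import numpy as np
import pandas as pd
import pytest

from gamhap import ConfigurationError, DataIntegrityError
from gamhap import allelic as al


class TestWdfTracks:
    def test_exact_ratio(self):
        seg = np.zeros((1, 200), bool)
        seg[0, :50] = True
        track = al.wdf_tracks(seg, seg, seg)
        assert track.unphased[0] == pytest.approx(0.25)

    def test_equal_phases_zero_differential(self, rng):
        seg = rng.random((10, 30)) < 0.3
        track = al.wdf_tracks(seg, seg, seg.copy())
        assert np.allclose(track.differential, 0.0)

    def test_zero_samples_rejected(self):
        empty = np.zeros((5, 0), bool)
        with pytest.raises(DataIntegrityError):
            al.wdf_tracks(empty, empty, empty)

    def test_planted_compaction_asymmetry_gives_positive_differential(self):
        import warnings

        from gamhap import (
            HaplotypePlan, SimConfig, SliceSpec, build_genome_model,
            build_segregation_tables, emit_dataset,
        )

        n = 100
        mult = np.ones(n)
        mult[40:60] = 2.0  # CAST decondensed in a block
        cfg = SimConfig(
            chrom_sizes={"chr1": n * 50_000},
            plans={"cast": HaplotypePlan(radius_multipliers=mult)},
            seed=21,
        )
        model = build_genome_model(cfg)
        table, _ = emit_dataset(model, SliceSpec(slices_per_sample=3), 400, seed=21, depth=100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = build_segregation_tables(table)
        track = al.wdf_tracks(res.unphased.matrix, res.cast.matrix, res.s129.matrix)
        assert track.differential[40:60].mean() > 0
        assert track.differential[40:60].mean() > track.differential[:40].mean()


class TestAseCall:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "cast", "s129", "tpm"])

    def test_monoallelic_closed_form_pvalue(self):
        out = al.ase_call(self.frame([("g", 20, 0, 5.0)]))
        assert out["pvalue"].iloc[0] == pytest.approx(2 * 0.5**20, rel=1e-9)
        assert out["class"].iloc[0] == al.CLASS_MONO_CAST
        assert np.isinf(out["log2fc"].iloc[0])

    def test_balanced_counts_biallelic(self):
        out = al.ase_call(self.frame([("g", 10, 10, 5.0)]))
        assert out["log2fc"].iloc[0] == 0.0
        assert out["class"].iloc[0] == al.CLASS_BIALLELIC

    def test_low_total_excluded(self):
        out = al.ase_call(self.frame([("g", 12, 7, 5.0)]))
        assert out["class"].iloc[0] == al.CLASS_EXCLUDED

    def test_no_snp_class(self):
        out = al.ase_call(self.frame([("g", 0, 0, 5.0)]))
        assert out["class"].iloc[0] == al.CLASS_NO_SNP

    def test_tpm_filter_blocks_ase(self):
        out = al.ase_call(self.frame([("g", 40, 0, 0.5)]))
        assert out["class"].iloc[0] == al.CLASS_BIALLELIC

    def test_negative_counts_rejected(self):
        with pytest.raises(DataIntegrityError):
            al.ase_call(self.frame([("g", -1, 5, 1.0)]))

    def test_label_swap_equivariance(self, rng):
        cast = rng.integers(0, 100, size=50)
        s129 = rng.integers(0, 100, size=50)
        base = pd.DataFrame({"gene": [f"g{i}" for i in range(50)], "cast": cast,
                             "s129": s129, "tpm": 5.0})
        swapped = base.rename(columns={"cast": "s129", "s129": "cast"})[
            ["gene", "cast", "s129", "tpm"]
        ]
        a = al.ase_call(base)["class"]
        b = al.ase_call(swapped)["class"]
        swap = {al.CLASS_CAST_ASE: al.CLASS_S129_ASE, al.CLASS_S129_ASE: al.CLASS_CAST_ASE,
                al.CLASS_MONO_CAST: al.CLASS_MONO_S129, al.CLASS_MONO_S129: al.CLASS_MONO_CAST}
        assert [swap.get(c, c) for c in a] == list(b)

    def test_power_at_strong_imbalance(self, rng):
        n_genes = 300
        totals = rng.integers(50, 200, size=n_genes)
        cast = rng.binomial(totals, 0.8)
        frame = pd.DataFrame({
            "gene": [f"g{i}" for i in range(n_genes)], "cast": cast,
            "s129": totals - cast, "tpm": 5.0,
        })
        out = al.ase_call(frame)
        ase = out["class"].isin([al.CLASS_CAST_ASE, al.CLASS_MONO_CAST])
        assert ase.mean() >= 0.8


class TestPhasePeaks:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["peak", "cast", "s129"])

    def test_clear_cast_peak(self):
        out = al.phase_peaks(self.frame([("p", 40, 5)]))
        assert out["log2fc"].iloc[0] == pytest.approx(3.0)
        assert out["class"].iloc[0] == al.PEAK_CAST

    def test_below_read_floor_unphased(self):
        out = al.phase_peaks(self.frame([("p", 8, 1)]))
        assert out["class"].iloc[0] == al.PEAK_UNPHASED

    def test_small_fold_change_common(self):
        out = al.phase_peaks(self.frame([("p", 20, 18)]))
        assert out["log2fc"].iloc[0] == pytest.approx(np.log2(20 / 18))
        assert abs(out["log2fc"].iloc[0]) < 0.16
        assert out["class"].iloc[0] == al.PEAK_COMMON

    def test_zero_denominator_is_allele_specific(self):
        out = al.phase_peaks(self.frame([("p", 15, 0)]))
        assert out["class"].iloc[0] == al.PEAK_CAST


class TestDScore:
    def test_hand_computed(self):
        assert al.d_score(np.array([30]), np.array([10]))[0] == pytest.approx(0.5)
        assert al.d_score(np.array([7]), np.array([7]))[0] == 0.0

    def test_exact_enumeration_oracle_small_n(self):
        # CAST=10, S129=0: only k in {0, 10} give |D| >= 1 -> p = 2/2^10
        p = al.d_score_permutation_pvalue(10, 0)
        assert p == pytest.approx(2 / 2**10)

    def test_exact_matches_brute_force_enumeration(self):
        from itertools import product

        for cast, s129 in [(6, 2), (5, 5), (9, 1), (3, 0)]:
            n = cast + s129
            obs = abs(cast - s129) / n
            hits = sum(
                1 for labels in product([0, 1], repeat=n)
                if abs(2 * sum(labels) - n) / n >= obs - 1e-12
            )
            assert al.d_score_permutation_pvalue(cast, s129) == pytest.approx(hits / 2**n)

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(3)
        p_mc = al.d_score_permutation_pvalue(60, 30, n_permutations=20_000, rng=rng,
                                             exact_max_reads=0)
        exact = al.d_score_permutation_pvalue(60, 30, exact_max_reads=100)
        assert abs(p_mc - exact) < 0.01


class TestAtacPeaks:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["peak", "cast_rep1", "s129_rep1",
                                           "cast_rep2", "s129_rep2"])

    def test_imbalanced_peak_called_with_sign(self):
        out = al.atac_allelic_peaks(self.frame([("p", 80, 10, 90, 12)]), seed=1)
        assert out["class"].iloc[0] == al.PEAK_CAST
        assert out["d_rep1"].iloc[0] > 0.3

    def test_balanced_peak_common(self):
        out = al.atac_allelic_peaks(self.frame([("p", 50, 50, 45, 55)]), seed=1)
        assert out["class"].iloc[0] == al.PEAK_COMMON

    def test_low_reads_not_called(self):
        out = al.atac_allelic_peaks(self.frame([("p", 5, 0, 4, 0)]), seed=1)
        assert out["class"].iloc[0] == al.PEAK_COMMON  # fails read floor, keeps default

    def test_zero_reads_unphased(self):
        out = al.atac_allelic_peaks(self.frame([("p", 0, 0, 0, 0)]), seed=1)
        assert out["class"].iloc[0] == al.PEAK_UNPHASED

    def test_literal_inside_range_flag_inverts_criterion(self):
        frame = self.frame([("p", 80, 10, 90, 12)])
        strict = al.atac_allelic_peaks(frame, seed=1, literal_inside_range=True)
        assert strict["class"].iloc[0] == al.PEAK_COMMON

    def test_d_sign_flips_under_label_swap(self):
        frame = self.frame([("p", 80, 10, 90, 12)])
        swapped = self.frame([("p", 10, 80, 12, 90)])
        a = al.atac_allelic_peaks(frame, seed=1)
        b = al.atac_allelic_peaks(swapped, seed=1)
        assert a["d_pooled"].iloc[0] == pytest.approx(-b["d_pooled"].iloc[0])
        assert b["class"].iloc[0] == al.PEAK_S129


class TestPromoterStates:
    def genes(self, rows):
        return pd.DataFrame(rows, columns=[
            "gene", "s5p_overlap", "s5p_reads", "s7p_overlap", "s7p_reads",
            "k27me3_overlap", "k27me3_reads",
        ])

    def base_frame(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return self.genes([
            (f"g{i}", True, rng.integers(50, 200), True, rng.integers(50, 200),
             False, 0) for i in range(n)
        ])

    def test_prca_state(self):
        frame = self.genes([
            ("g", True, 100, True, 100, True, 100),
            ("h", True, 100, True, 100, True, 100),
        ])
        out = al.promoter_state_classify(frame)
        assert (out["state"] == al.STATE_PRCA).all()

    def test_all_negative_is_inactive(self):
        frame = self.genes([("g", False, 0, False, 0, False, 0)])
        with pytest.warns(UserWarning):
            out = al.promoter_state_classify(frame)
        assert out["state"].iloc[0] == al.STATE_INACTIVE

    def test_prc_state_requires_k27_without_s7p(self):
        frame = self.genes([
            ("g", False, 0, False, 0, True, 100),
            ("h", False, 0, False, 0, True, 100),
        ])
        with pytest.warns(UserWarning):
            out = al.promoter_state_classify(frame)
        assert (out["state"] == al.STATE_PRC).all()

    def test_reads_below_fifth_percentile_negative(self):
        frame = self.base_frame()
        reads = np.sort(frame["s5p_reads"].to_numpy())
        low = frame.copy()
        low.loc[0, "s5p_reads"] = 0  # overlaps but far below the 5th percentile
        out = al.promoter_state_classify(low)
        assert not out["s5p_positive"].iloc[0]
        assert out["state"].iloc[0] == al.STATE_INACTIVE


class TestSelectIsoform:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "isoform", "s5p", "s7p", "length"])

    def test_highest_s5p_wins(self):
        out = al.select_isoform(self.frame([("g", "a", 100, 1, 10), ("g", "b", 50, 99, 99)]))
        assert out["isoform"].iloc[0] == "a"

    def test_s7p_breaks_tie(self):
        out = al.select_isoform(self.frame([("g", "a", 50, 30, 10), ("g", "b", 50, 10, 99)]))
        assert out["isoform"].iloc[0] == "a"

    def test_length_breaks_tie(self):
        out = al.select_isoform(self.frame([("g", "a", 50, 30, 10), ("g", "b", 50, 30, 99)]))
        assert out["isoform"].iloc[0] == "b"

    def test_full_tie_is_deterministic_under_seed(self):
        frame = self.frame([("g", "a", 1, 1, 1), ("g", "b", 1, 1, 1)])
        first = al.select_isoform(frame, seed=5)["isoform"].iloc[0]
        assert al.select_isoform(frame, seed=5)["isoform"].iloc[0] == first
        picks = {al.select_isoform(frame, seed=s)["isoform"].iloc[0] for s in range(20)}
        assert picks == {"a", "b"}


class TestCircularPermutation:
    def bed(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "stop"])

    def test_whole_genome_target_gives_p_one(self):
        features = self.bed([("chr1", 10, 20), ("chr1", 50, 60)])
        targets = self.bed([("chr1", 0, 100)])
        out = al.circular_permutation_test(features, targets, {"chr1": 100},
                                           n_permutations=200, seed=1)
        assert out["pvalue"] == 1.0
        assert out["null_sd"] == 0.0

    def test_exhaustive_rotation_matches_enumeration(self):
        # 1 feature of 1 bin on a 10-bin circle, 1-bin target:
        # exactly 1 of 10 rotations overlaps -> p = 0.1
        features = self.bed([("chr1", 0, 1)])
        targets = self.bed([("chr1", 5, 6)])
        out = al.circular_permutation_test(features, targets, {"chr1": 10},
                                           exhaustive_step=1)
        assert out["observed"] == 0
        assert out["pvalue"] == pytest.approx(1.0)  # depletion-free enrichment p
        out2 = al.circular_permutation_test(self.bed([("chr1", 5, 6)]), targets,
                                            {"chr1": 10}, exhaustive_step=1)
        assert out2["observed"] == 1
        assert out2["pvalue"] == pytest.approx(0.1)

    def test_fixed_seed_reproducible(self):
        features = self.bed([("chr1", 10, 20), ("chr2", 5, 15)])
        targets = self.bed([("chr1", 15, 40), ("chr2", 50, 80)])
        sizes = {"chr1": 100, "chr2": 100}
        a = al.circular_permutation_test(features, targets, sizes, n_permutations=500, seed=9)
        b = al.circular_permutation_test(features, targets, sizes, n_permutations=500, seed=9)
        assert a == b

    def test_empty_features_rejected(self):
        with pytest.raises(DataIntegrityError):
            al.circular_permutation_test(self.bed([]), self.bed([("chr1", 0, 1)]), {"chr1": 10})

    def test_enrichment_detected(self, rng):
        # features planted inside targets -> small p
        targets = self.bed([("chr1", k * 1000, k * 1000 + 100) for k in range(0, 100, 10)])
        features = self.bed([("chr1", k * 1000 + 10, k * 1000 + 30) for k in range(0, 100, 10)])
        out = al.circular_permutation_test(features, targets, {"chr1": 100_000},
                                           n_permutations=500, seed=2)
        assert out["pvalue"] < 0.05


def bed_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "stop"])


class TestRegulatoryContacts:
    def setup_ep(self):
        windows = pd.DataFrame({
            "chrom": ["chr1"] * 100,
            "start": np.arange(100) * 50_000,
            "stop": (np.arange(100) + 1) * 50_000,
        })
        contacts = pd.DataFrame({
            "window_i": [10, 10],
            "window_j": [30, 70],
            "distance": [20 * 50_000, 60 * 50_000],
            "class": ["strong-CAST", "strong-CAST"],
        })
        genes = pd.DataFrame({
            "gene": ["g"], "chrom": ["chr1"], "tss": [10 * 50_000 + 100],
            "class": [al.CLASS_CAST_ASE],
        })
        peaks = {
            "s5p": bed_frame([("chr1", 0, 100 * 50_000)]),
            "atac": bed_frame([("chr1", 0, 100 * 50_000)]),
            "h3k27ac": bed_frame([("chr1", 0, 100 * 50_000)]),
        }
        return contacts, windows, genes, peaks

    def test_distance_filter_rejects_far_pair(self):
        contacts, windows, genes, peaks = self.setup_ep()
        out = al.annotate_regulatory_contacts(contacts, windows, "EP", genes=genes,
                                              peak_sets=peaks)
        assert len(out) == 1  # the 3-Mb pair is rejected
        assert out["window_j"].iloc[0] == 30

    def test_ep_kept_and_labelled_by_haplotype(self):
        contacts, windows, genes, peaks = self.setup_ep()
        out = al.annotate_regulatory_contacts(contacts, windows, "EP", genes=genes,
                                              peak_sets=peaks)
        assert out["allele_configuration"].iloc[0] == "most-expressed"

    def test_missing_peak_set_rejected(self):
        contacts, windows, genes, peaks = self.setup_ep()
        del peaks["h3k27ac"]
        with pytest.raises(ConfigurationError):
            al.annotate_regulatory_contacts(contacts, windows, "EP", genes=genes,
                                            peak_sets=peaks)

    def test_ctcf_convergence_rule(self):
        windows = pd.DataFrame({
            "chrom": ["chr1"] * 50,
            "start": np.arange(50) * 50_000,
            "stop": (np.arange(50) + 1) * 50_000,
        })
        contacts = pd.DataFrame({
            "window_i": [5, 20], "window_j": [15, 30],
            "distance": [10 * 50_000, 10 * 50_000],
            "class": ["strong-CAST", "strong-CAST"],
        })
        ctcf = pd.DataFrame({
            "chrom": ["chr1"] * 4,
            "start": [5 * 50_000, 15 * 50_000, 20 * 50_000, 30 * 50_000],
            "stop": [5 * 50_000 + 10, 15 * 50_000 + 10, 20 * 50_000 + 10, 30 * 50_000 + 10],
            "strand": ["+", "-", "+", "+"],  # convergent for first pair, tandem second
        })
        rad21 = bed_frame([("chr1", 0, 50 * 50_000)])
        out = al.annotate_regulatory_contacts(
            contacts, windows, "CTCF-loop", peak_sets={"ctcf": ctcf, "rad21": rad21}
        )
        assert out["window_i"].tolist() == [5]


class TestDifferentialMethylation:
    def test_equal_ratios_not_called(self):
        cpgs = pd.DataFrame({
            "chrom": ["chr1"] * 8,
            "pos": [100, 200, 300, 400] * 2,
            "cast_pct": [80, 80, 20, 20] * 2,
            "s129_pct": [80, 80, 20, 20] * 2,
        }).drop_duplicates("pos")
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "tss": [250], "length": [3000]})
        out = al.differential_methylation(cpgs, genes)
        assert out["differential"].iloc[0] == 0.0
        assert not out["called"].iloc[0]

    def test_short_gene_excluded(self):
        cpgs = pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                             "cast_pct": [90], "s129_pct": [10]})
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "tss": [100], "length": [1500]})
        out = al.differential_methylation(cpgs, genes)
        assert out["exclude_reason"].iloc[0] == "short-gene"

    def test_no_covered_cpgs_excluded(self):
        cpgs = pd.DataFrame({"chrom": ["chr1"], "pos": [10**7],
                             "cast_pct": [90], "s129_pct": [10]})
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "tss": [100], "length": [3000]})
        out = al.differential_methylation(cpgs, genes)
        assert out["exclude_reason"].iloc[0] == "no-covered-cpgs"

    def test_single_extreme_promoter_called(self, rng):
        genes = pd.DataFrame({
            "gene": [f"g{i}" for i in range(100)],
            "chrom": "chr1",
            "tss": np.arange(100) * 10_000 + 5_000,
            "length": 3_000,
        })
        rows = []
        for i in range(100):
            base = 5 if i != 7 else 95  # promoter 7: S129 heavily methylated
            for k in range(10):
                rows.append(("chr1", i * 10_000 + 4_500 + k * 100, 5, base))
        cpgs = pd.DataFrame(rows, columns=["chrom", "pos", "cast_pct", "s129_pct"])
        out = al.differential_methylation(cpgs, genes)
        called = out[out["called"]]
        assert called["gene"].tolist() == ["g7"]
        assert called["direction"].iloc[0] == "S129-higher"


class TestCryoFish:
    def test_hand_fraction(self):
        counts = np.array([2] * 6 + [1] * 40)
        assert al.cryofish_allele_fraction(counts) == pytest.approx(6 / 46)

    def test_all_both(self):
        assert al.cryofish_allele_fraction([2, 2, 2]) == 1.0

    def test_none_both(self):
        assert al.cryofish_allele_fraction([1, 1]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(DataIntegrityError):
            al.cryofish_allele_fraction([])

    def test_invalid_counts_rejected(self):
        with pytest.raises(DataIntegrityError):
            al.cryofish_allele_fraction([0, 1, 2])


class TestCooccurrence:
    def test_identical_sets_correlate_perfectly(self):
        peaks = bed_frame([("chr1", 10_000, 11_000), ("chr1", 450_000, 451_000)])
        out = al.feature_cooccurrence({"a": peaks, "b": peaks.copy()}, {"chr1": 600_000})
        assert out.loc["a", "b"] == pytest.approx(1.0)

    def test_disjoint_two_bin_toy_anticorrelates(self):
        a = bed_frame([("chr1", 10_000, 11_000)])
        b = bed_frame([("chr1", 210_000, 211_000)])
        out = al.feature_cooccurrence({"a": a, "b": b}, {"chr1": 400_000})
        assert out.loc["a", "b"] == pytest.approx(-1.0)

    def test_empty_set_gives_nan_with_warning(self):
        a = bed_frame([("chr1", 10_000, 11_000)])
        b = bed_frame([])
        with pytest.warns(UserWarning):
            out = al.feature_cooccurrence({"a": a, "b": b}, {"chr1": 400_000})
        assert np.isnan(out.loc["a", "b"])

    def test_constant_counts_undefined(self):
        a = bed_frame([("chr1", 10_000, 11_000), ("chr1", 210_000, 211_000)])
        out = al.feature_cooccurrence({"a": a, "b": a.copy()}, {"chr1": 400_000})
        assert np.isnan(out.loc["a", "b"])  # one peak per bin -> zero variance
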