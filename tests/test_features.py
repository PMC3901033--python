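"""uORF scanning, contingency/bin analyses, concordance, correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom

from translatome import (SyntheticConfig, bin_association_analysis,
                         generate_dataset, length_bin_analysis,
                         pearson_r2, scan_uorfs, sign_concordance_test)
from translatome.core import build_translation_state_table
from translatome.features import (bin_ttest_table, classify_transcripts,
                                  fisher_or_yates, significance_tier)


class TestScanUorfs:
    def test_manual_codon_walk_contained(self):
        # leader AA ATG TTT TAA CC, main ORF at 13
        seq = "AAATGTTTTAACC" + "ATGGCTGCTTGA"
        found = scan_uorfs(seq, 13)
        assert len(found) == 1
        rec = found[0]
        assert rec.start == 2
        assert rec.length_codons == 2
        assert rec.overlap_class == "contained_in_leader"

    def test_no_atg_leader_empty(self):
        assert scan_uorfs("CCTTCCTT" + "ATGTTTTGA", 8) == []

    def test_unterminated_leader_atg_overlaps_main_orf(self):
        # uORF ATG at 0 has no stop in the leader; its frame hits a
        # stop inside the main region
        seq = "ATGAAA" + "ATGGCTTAAGCTTGA"
        found = scan_uorfs(seq, 6)
        assert len(found) == 1
        assert found[0].overlap_class == "overlaps_main_orf"

    def test_candidate_without_any_stop_discarded(self):
        seq = "ATGAAA" + "ATGGCTGCT"  # no stop anywhere in frame 0
        assert scan_uorfs(seq, 6) == []

    def test_cds_start_out_of_range(self):
        with pytest.raises(ValueError):
            scan_uorfs("ATGTTT", 10)

    def test_round_trip_with_generator(self, small_dataset):
        from translatome import generate_transcript_sequences
        ann = small_dataset["annotation"]
        discordant = 0
        for rec in generate_transcript_sequences(ann, seed=0):
            n = len(scan_uorfs(str(rec.seq),
                               int(ann.loc[rec.id, "utr5_length"])))
            discordant += (n != int(ann.loc[rec.id, "n_uorfs"]))
        assert discordant == 0


class TestFisherOrYates:
    def test_exact_enumeration_oracle(self):
        """Fisher p equals the exhaustive sum over tables with fixed
        margins of hypergeometric probabilities <= that of the
        observed table."""
        rng = np.random.default_rng(1)
        checked = 0
        for N in range(2, 41):
            for _ in range(20):
                r1 = int(rng.integers(0, N + 1))
                c1 = int(rng.integers(0, N + 1))
                lo, hi = max(0, r1 + c1 - N), min(r1, c1)
                if lo > hi:
                    continue
                x = int(rng.integers(lo, hi + 1))
                table = [[x, r1 - x], [c1 - x, N - r1 - c1 + x]]
                ks = np.arange(lo, hi + 1)
                pmf = hypergeom.pmf(ks, N, c1, r1)
                oracle = min(pmf[pmf <= hypergeom.pmf(x, N, c1, r1)
                                 * (1 + 1e-7)].sum(), 1.0)
                p = stats.fisher_exact(table)[1]
                assert abs(p - oracle) < 1e-12
                checked += 1
        assert checked > 500

    def test_imbalanced_table_matches_enumeration(self):
        # [[1,9],[9,1]]: support is k in [0,10] with margins (10,10;20)
        ks = np.arange(0, 11)
        pmf = hypergeom.pmf(ks, 20, 10, 10)
        oracle = pmf[pmf <= hypergeom.pmf(1, 20, 10, 10)
                     * (1 + 1e-7)].sum()
        assert stats.fisher_exact([[1, 9], [9, 1]])[1] == pytest.approx(
            oracle, abs=1e-12)

    def test_sparse_table_routed_to_fisher(self):
        p, test = fisher_or_yates([[0, 5], [4, 1]])
        assert test == "fisher"
        assert p == stats.fisher_exact([[0, 5], [4, 1]])[1]

    def test_switches_to_yates_for_large_tables(self):
        p, test = fisher_or_yates([[30, 70], [50, 50]])
        assert test == "chi2_yates"
        expected = stats.chi2_contingency(
            [[30, 70], [50, 50]], correction=True)[1]
        assert p == expected

    def test_tiers(self):
        assert significance_tier(1e-5) == "**"
        assert significance_tier(0.01) == "*"
        assert significance_tier(0.2) == ""
        assert significance_tier(np.nan) == ""


class TestBinAssociation:
    def _annotation(self, n_uorfs, cds):
        return pd.DataFrame(
            {"n_uorfs": n_uorfs, "cds_length": cds},
            index=[f"g{i}" for i in range(len(n_uorfs))])

    def test_reference_bin_has_p_one(self):
        rng = np.random.default_rng(0)
        n = 300
        ann = self._annotation(rng.integers(0, 2, n),
                               rng.integers(300, 3000, n))
        delta = pd.Series(rng.uniform(-1.3, 1.3, n), index=ann.index)
        out = bin_association_analysis(delta, ann)
        ref = out[out["is_reference"]]
        assert (ref["p"] == 1.0).all()

    def test_percentages_sum_to_100_per_bin(self):
        rng = np.random.default_rng(3)
        n = 500
        ann = self._annotation(rng.integers(0, 3, n),
                               rng.integers(100, 4000, n))
        delta = pd.Series(rng.normal(0, 0.6, n), index=ann.index)
        out = bin_association_analysis(delta, ann)
        sums = out[out["n_bin"] > 0].groupby("bin")["percent"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_uorf_repression_detected_in_under_bins(self):
        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(
                n_genes=3000, genotypes=("WT", "mut"), regulon_size=0,
                uorf_gene_fraction=0.2, uorf_delta_tl=-1.0,
                noise_sd=0.2, length_effect_slope=0.0,
                dropout_quantile=0.0, seed=seed)
            signals, _, ann, _ = generate_dataset(cfg)
            ts = build_translation_state_table(signals.log2_transform())
            out = bin_association_analysis(ts["delta_tl.mut"], ann)
            under = out[(out["bin_high"] <= -0.6)
                        & (out["feature_class"] == "uorf")
                        & (out["n_bin"] > 0)]
            if (under["p"] < 0.05).any():
                hits += 1
        assert hits >= 9

    def test_classify_transcripts_threshold(self):
        ann = self._annotation([0, 0, 1], [2000, 500, 500])
        cls = classify_transcripts(ann)
        assert cls.tolist() == ["no_uorf_long", "no_uorf_short", "uorf"]


class TestBinTTests:
    def test_identical_bins_give_p_one(self):
        vals = pd.Series(np.tile([1.0, 2.0, 3.0, 4.0], 2),
                         index=[f"g{i}" for i in range(8)])
        bin_by = pd.Series([0.1] * 4 + [0.9] * 4, index=vals.index)
        out = bin_ttest_table(bin_by, vals, [0, 0.5, 1], reference_bin=0)
        assert out.loc[1, "p"] == pytest.approx(1.0)

    def test_shifted_bin_matches_closed_form_t(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        vals = pd.Series(np.concatenate([a, b]),
                         index=[f"g{i}" for i in range(100)])
        bin_by = pd.Series([0.25] * 50 + [0.75] * 50, index=vals.index)
        out = bin_ttest_table(bin_by, vals, [0, 0.5, 1],
                              reference_bin=0)
        t, p = stats.ttest_ind(b, a, equal_var=True)
        assert out.loc[1, "t"] == pytest.approx(t)
        assert out.loc[1, "p"] == pytest.approx(p)
        assert out.loc[1, "p"] < 1e-3
        assert out.loc[1, "sem"] == pytest.approx(
            b.std(ddof=1) / np.sqrt(50))

    def test_length_effect_shows_in_short_cds_bins(self):
        cfg = SyntheticConfig(
            n_genes=4000, genotypes=("WT", "pabx"), regulon_size=0,
            uorf_gene_fraction=0.0, length_effect_slope=0.3,
            length_effect_genotype="pabx", noise_sd=0.2,
            dropout_quantile=0.0, seed=8)
        signals, _, ann, _ = generate_dataset(cfg)
        ts = build_translation_state_table(signals.log2_transform())
        out = length_bin_analysis(ts["delta_tl.pabx"],
                                  ann["cds_length"].astype(float))
        shortest = out.iloc[0]
        assert shortest["mean"] < 0
        assert shortest["p"] < 1e-4


class TestSignConcordance:
    def test_single_positive_delta(self):
        res = sign_concordance_test([0.7], alternative="greater")
        assert res["sign_p"] == pytest.approx(0.5)

    def test_all_positive_matches_binomial(self):
        res = sign_concordance_test(np.linspace(0.1, 1.0, 10),
                                    alternative="greater")
        assert res["sign_p"] == pytest.approx(0.5 ** 10)
        assert res["wilcoxon_p"] == pytest.approx(
            stats.wilcoxon(np.linspace(0.1, 1.0, 10),
                           alternative="greater",
                           method="exact").pvalue)

    def test_symmetric_deltas_are_null(self):
        d = np.concatenate([np.linspace(0.1, 1, 20),
                            -np.linspace(0.1, 1, 20)])
        res = sign_concordance_test(d, alternative="greater")
        assert res["sign_p"] == pytest.approx(0.5, abs=0.15)
        assert res["wilcoxon_p"] == pytest.approx(0.5, abs=0.15)

    def test_all_zero_deltas(self):
        res = sign_concordance_test([0.0, 0.0])
        assert res["wilcoxon_p"] == 1.0 and res["n"] == 0


class TestPearsonR2:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        assert pearson_r2(x, 2 * x + 1)["r2"] == pytest.approx(1.0)
        assert pearson_r2(x, -x)["sign"] == -1

    def test_hand_computed_example(self):
        res = pearson_r2([1, 2, 3, 4], [1, 3, 2, 4])
        assert res["r2"] == pytest.approx(0.64)
        assert res["sign"] == 1

    def test_independence_limit(self, rng):
        x = rng.normal(0, 1, 20000)
        y = rng.normal(0, 1, 20000)
        assert pearson_r2(x, y)["r2"] < 0.01

    def test_degenerate_inputs_flagged(self):
        assert not pearson_r2([1, 1, 1], [1, 2, 3])["defined"]
        assert not pearson_r2([1, 2], [3, 4])["defined"]
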