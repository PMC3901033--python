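"""Prefilter sets, moderated t, BH adjustment, and the two DTG routes."""

import itertools
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from translatome import (SyntheticConfig, adhoc_filter, bh_fdr,
                         build_prefilter_sets, generate_dataset,
                         identify_dtg, moderated_t)
from translatome.core import build_translation_state_table
from translatome.dtg import (ModeratedTTest, per_replicate_fold_changes,
                             squeeze_variance)


def _calls(rows, genes=None):
    genes = genes or [f"g{i}" for i in range(len(rows))]
    cols = [f"WT.PL.{i + 1}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, index=genes, columns=cols)


class TestPrefilterSets:
    def test_all_present_uniform_sd(self):
        calls = _calls([["P"] * 4] * 10)
        sd = pd.Series(np.linspace(0.1, 1.0, 10), index=calls.index)
        sets = build_prefilter_sets(calls, sd, sd_quantile=0.8)
        assert list(sets.pm) == list(sets.all_genes)
        assert len(sets.stable) == 8  # ceil(0.8 * 10)
        assert set(sets.stable_and_pm) == set(sets.stable)

    def test_below_half_pm_excluded(self):
        calls = _calls([["P", "A", "A", "A"], ["P", "P", "A", "A"]])
        sd = pd.Series([0.1, 0.1], index=calls.index)
        sets = build_prefilter_sets(calls, sd)
        assert "g0" not in sets.pm        # 25% < 50%
        assert "g1" in sets.pm            # exactly 50%

    def test_single_absent_call_blocks_stable_and_pm(self):
        calls = _calls([["P", "P", "P", "A"], ["P"] * 4, ["P"] * 4,
                        ["P"] * 4, ["P"] * 4])
        sd = pd.Series([0.1, 0.2, 0.3, 0.4, 0.9], index=calls.index)
        sets = build_prefilter_sets(calls, sd, sd_quantile=0.8)
        assert "g0" in sets.stable and "g0" in sets.pm
        assert "g0" not in sets.stable_and_pm

    def test_subset_invariants(self, small_dataset):
        ts = build_translation_state_table(
            small_dataset["signals"].log2_transform())
        sd = ts[[c for c in ts.columns
                 if c.startswith("tl.WT.")]].std(axis=1, ddof=1)
        sets = build_prefilter_sets(small_dataset["calls"].calls, sd)
        assert set(sets.stable_and_pm) <= set(sets.stable)
        assert set(sets.stable_and_pm) <= set(sets.pm)
        assert set(sets.pm) <= set(sets.all_genes)


class TestModeratedT:
    def test_no_moderation_equals_ordinary_t(self, rng):
        x1 = pd.DataFrame(rng.normal(0, 1, (100, 3)))
        x2 = pd.DataFrame(rng.normal(0, 1, (100, 4)))
        res = moderated_t(x1, x2, prior_df=0)
        t, p = stats.ttest_ind(x1, x2, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], t, atol=1e-12)
        np.testing.assert_allclose(res["p"], p, atol=1e-12)

    def test_full_shrinkage_ranks_by_delta(self, rng):
        x1 = pd.DataFrame(rng.normal(0, 1, (50, 3)))
        x2 = pd.DataFrame(rng.normal(0, 1, (50, 3)))
        res = moderated_t(x1, x2, prior_df=np.inf)
        assert (res["s2_post"].nunique() == 1)
        order_t = res["t"].abs().rank()
        order_d = res["delta"].abs().rank()
        pd.testing.assert_series_equal(order_t, order_d,
                                       check_names=False)

    def test_posterior_between_prior_and_sample(self, rng):
        s2g = 0.05 * 8 / rng.chisquare(8, 400)
        x1 = pd.DataFrame(rng.normal(0, 1, (400, 3))
                          * np.sqrt(s2g)[:, None])
        x2 = pd.DataFrame(rng.normal(0, 1, (400, 3))
                          * np.sqrt(s2g)[:, None])
        res = moderated_t(x1, x2)
        s0 = res.attrs["s2_prior"]
        lo = np.minimum(res["s2"], s0)
        hi = np.maximum(res["s2"], s0)
        assert ((res["s2_post"] >= lo - 1e-12)
                & (res["s2_post"] <= hi + 1e-12)).all()

    def test_null_calibration(self, rng):
        x1 = pd.DataFrame(rng.normal(0, 0.4, (4000, 3)))
        x2 = pd.DataFrame(rng.normal(0, 0.4, (4000, 3)))
        res = moderated_t(x1, x2)
        assert 0.04 <= (res["p"] < 0.05).mean() <= 0.06
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_constant_variances_fall_back_to_infinite_prior(self, caplog):
        x1 = pd.DataFrame([[0.0, 1.0]] * 20)
        x2 = pd.DataFrame([[0.5, 1.5]] * 20)
        res = moderated_t(x1, x2)
        assert np.isinf(res.attrs["df_prior"])

    def test_matches_limma_ebayes(self, rng):
        """Independent oracle: R limma's eBayes on the same matrix."""
        s2g = 0.04 * 6 / rng.chisquare(6, 200)
        x1 = rng.normal(0, 1, (200, 3)) * np.sqrt(s2g)[:, None]
        x2 = rng.normal(0.3, 1, (200, 3)) * np.sqrt(s2g)[:, None]
        with tempfile.TemporaryDirectory() as td:
            np.savetxt(f"{td}/x.tsv", np.hstack([x1, x2]),
                       delimiter="\t")
            script = (
                'suppressMessages(library(limma));'
                f'x <- as.matrix(read.table("{td}/x.tsv"));'
                'design <- model.matrix(~factor(c(0,0,0,1,1,1)));'
                'fit <- eBayes(lmFit(x, design));'
                'write.table(cbind(fit$df.prior, fit$s2.prior,'
                ' fit$t[,2], fit$p.value[,2]),'
                f' "{td}/out.tsv", row.names=FALSE, col.names=FALSE)')
            proc = subprocess.run(["Rscript", "-e", script],
                                  capture_output=True, text=True)
            if proc.returncode != 0:
                pytest.skip(f"Rscript/limma unavailable: {proc.stderr}")
            out = np.loadtxt(f"{td}/out.tsv")
        res = moderated_t(pd.DataFrame(x2), pd.DataFrame(x1))
        assert res.attrs["df_prior"] == pytest.approx(out[0, 0], rel=1e-6)
        assert res.attrs["s2_prior"] == pytest.approx(out[0, 1], rel=1e-6)
        np.testing.assert_allclose(res["t"], out[:, 2], atol=1e-8)
        np.testing.assert_allclose(res["p"], out[:, 3], atol=1e-10)

    def test_estimator_validates_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            ModeratedTTest().fit(np.zeros((4, 5)),
                                 ["a", "a", "b", "c"])
        with pytest.raises(ValueError, match="replicates"):
            ModeratedTTest().fit(np.zeros((2, 5)), ["a", "b"])


def _bh_bruteforce(p):
    """Step-up from the definition: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_capped(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m counts only the non-missing entries
        np.testing.assert_allclose(q[[0, 2]],
                                   _bh_bruteforce([0.01, 0.04]))

    def test_matches_bruteforce_on_grid(self):
        grid = [0.001, 0.01, 0.2, 0.5, 0.8, 1.0]
        rng = np.random.default_rng(0)
        for length in range(1, 9):
            for combo in itertools.combinations_with_replacement(
                    grid, length):
                p = np.array(combo)
                rng.shuffle(p)
                np.testing.assert_allclose(bh_fdr(p), _bh_bruteforce(p),
                                           atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_order_preserving_and_bounded(self, p):
        q = bh_fdr(p)
        assert ((q >= np.asarray(p) - 1e-12) & (q <= 1.0)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestAdhocFilter:
    def test_all_criteria_pass(self):
        fc = pd.DataFrame([[1.2, 1.1, 1.3]], index=["g"])
        res = adhoc_filter(fc)
        row = res.loc["g"]
        assert row[["adhoc_i", "adhoc_ii", "adhoc_iii",
                    "dtg_adhoc"]].all()

    def test_consistent_but_small_change_fails_fold_minimum(self):
        fc = pd.DataFrame([[0.4, 0.5, 0.45]], index=["g"])
        row = adhoc_filter(fc).loc["g"]
        assert not row["adhoc_i"]
        assert row["adhoc_ii"] and row["adhoc_iii"]
        assert not row["dtg_adhoc"]  # mean 0.45 < 0.59

    def test_null_gene_never_called(self):
        row = adhoc_filter(pd.DataFrame([[0.0, 0.0, 0.0]],
                                        index=["g"])).loc["g"]
        assert row["adhoc_iii"] and not row["adhoc_ii"]
        assert not row["dtg_adhoc"]

    def test_sign_consistency_required_for_criterion_i(self):
        row = adhoc_filter(pd.DataFrame([[1.5, -1.5, 1.5]],
                                        index=["g"])).loc["g"]
        assert not row["adhoc_i"]

    def test_pairing_rules(self):
        mut = pd.DataFrame([[2.0, 3.0]], index=["g"])
        wt = pd.DataFrame([[1.0, 1.0]], index=["g"])
        fc = per_replicate_fold_changes(mut, wt)
        np.testing.assert_allclose(fc.loc["g"], [1.0, 2.0])
        wt3 = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        fc = per_replicate_fold_changes(mut, wt3)
        np.testing.assert_allclose(fc.loc["g"], [0.0, 1.0])


@pytest.fixture(scope="module")
def noiseless():
    cfg = SyntheticConfig(
        n_genes=500, genotypes=("WT", "mut"), regulon_size=50,
        regulon_delta_tl=1.2, uorf_gene_fraction=0.0, noise_sd=0.0,
        length_effect_slope=0.0, dropout_quantile=0.0, seed=21)
    signals, calls, _, truth = generate_dataset(cfg)
    ts = build_translation_state_table(signals.log2_transform())
    sd = ts[[c for c in ts.columns
             if c.startswith("tl.WT.")]].std(axis=1, ddof=1)
    sets = build_prefilter_sets(calls.calls, sd)
    return ts, sets, truth


class TestIdentifyDTG:

    def test_noiseless_regulon_fully_recovered(self, noiseless):
        ts, sets, truth = noiseless
        table = identify_dtg(ts, sets, mutant="mut")
        called = set(table.index[table["dtg_union"]])
        planted = set(truth.index[truth["regulon_member"]])
        assert called == planted
        assert (table.loc[sorted(called), "direction"] == "over").all()

    def test_union_is_or_of_set_flags(self, noiseless):
        ts, sets, _ = noiseless
        table = identify_dtg(ts, sets, mutant="mut")
        set_cols = [c for c in table.columns if c.startswith("dtg_")
                    and c not in ("dtg_union", "dtg_adhoc")]
        pd.testing.assert_series_equal(table["dtg_union"],
                                       table[set_cols].any(axis=1),
                                       check_names=False)

    def test_alpha_nesting(self, small_dataset):
        ts = build_translation_state_table(
            small_dataset["signals"].log2_transform())
        sd = ts[[c for c in ts.columns
                 if c.startswith("tl.WT.")]].std(axis=1, ddof=1)
        sets = build_prefilter_sets(small_dataset["calls"].calls, sd)
        strict = identify_dtg(ts, sets, mutant="mut", alpha=0.01)
        loose = identify_dtg(ts, sets, mutant="mut", alpha=0.05)
        strict_set = set(strict.index[strict["dtg_union"]])
        loose_set = set(loose.index[loose["dtg_union"]])
        assert strict_set <= loose_set
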