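"""Differential-expression module: filtering, normalisation, NB Wald GLM,
BH adjustment, VST and the Wilcoxon helper."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucoseq.containers import CountMatrix, DesignSpec
from mucoseq.de import (
    benjamini_hochberg,
    estimate_dispersions,
    estimate_size_factors,
    filter_low_counts,
    filter_unannotated,
    fit_nb_wald,
    fold_to_log2fc,
    log2fc_to_fold,
    vst,
    wilcoxon_two_sample,
)


def _cm(counts: np.ndarray, groups, genders=None) -> CountMatrix:
    counts = np.asarray(counts)
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(counts.shape[0])],
        columns=[f"s{j}" for j in range(counts.shape[1])],
    )
    samples = pd.DataFrame({"group": list(groups)}, index=df.columns)
    if genders is not None:
        samples["gender"] = list(genders)
    return CountMatrix(df, samples)


class TestFilter:
    def test_threshold_boundary(self):
        cm = _cm([[13] + [0] * 5, [14] + [0] * 5], "AAABBB")
        kept = filter_low_counts(cm, 14)
        assert list(kept.gene_ids) == ["g1"]

    def test_zero_threshold_is_identity(self, toy_counts):
        assert list(filter_low_counts(toy_counts, 0).gene_ids) == list(
            toy_counts.gene_ids
        )

    def test_row_sums_one_to_ten(self):
        rows = [[i + 1] + [0] * 5 for i in range(10)]
        kept = filter_low_counts(_cm(rows, "AAABBB"), 6)
        assert len(kept.gene_ids) == 5

    def test_auto_uses_smallest_group(self):
        counts = np.ones((3, 17 + 14 + 27), dtype=int)
        groups = ["UC.I"] * 17 + ["UC.nI"] * 14 + ["Cntrl"] * 27
        cm = _cm(counts, groups)
        # every row sums to 58 >= 14, so all survive; threshold inferred = 14
        assert len(filter_low_counts(cm, "auto").gene_ids) == 3
        cm2 = _cm(np.full((1, 58), 0), groups)
        cm2.counts.iloc[0, :13] = 1  # row sum 13 < 14
        with pytest.raises(ValueError, match="14"):
            filter_low_counts(cm2, "auto")

    def test_empty_result_raises(self, toy_counts):
        with pytest.raises(ValueError):
            filter_low_counts(toy_counts, 10**9)

    def test_annotation_completeness(self):
        cm = _cm(np.ones((3, 4), dtype=int), "AABB")
        cm.annotation = pd.DataFrame(
            {
                "chromosome": ["1", None, "2"],
                "full_name": ["x", "y", ""],
                "entrez": [1, 2, 3],
            },
            index=cm.gene_ids,
        )
        assert list(filter_unannotated(cm).gene_ids) == ["g0"]


class TestSizeFactors:
    def test_doubled_column(self):
        counts = pd.DataFrame({"a": [10, 30, 7], "b": [20, 60, 14]})
        s = estimate_size_factors(counts)
        assert s["b"] / s["a"] == pytest.approx(2.0)

    def test_identical_columns_equal_factors(self):
        counts = pd.DataFrame({"a": [3, 9], "b": [3, 9], "c": [3, 9]})
        assert estimate_size_factors(counts).nunique() == 1

    def test_hand_computed_two_by_two(self):
        # genes x samples: (10, 20), (20, 40); geometric means sqrt(200), sqrt(800)
        counts = pd.DataFrame([[10, 20], [20, 40]], columns=["a", "b"])
        s = estimate_size_factors(counts)
        assert s["a"] == pytest.approx(10 / np.sqrt(200))
        assert s["b"] == pytest.approx(40 / np.sqrt(800))
        assert s.to_numpy() == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_no_reference_gene_raises_without_fallback(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo"):
            estimate_size_factors(counts)
        s = estimate_size_factors(counts, allow_pseudo_reference=True)
        assert (s > 0).all()


class TestDispersions:
    def test_poisson_gene_hits_floor(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(40):
            counts = pd.DataFrame(rng.poisson(50, size=(1, 60)))
            sf = pd.Series(1.0, index=counts.columns)
            disp, _ = estimate_dispersions(counts, sf, shrink=False)
            hits += disp.iloc[0] <= 0.01
        assert hits >= 38  # sub-Poisson moments give (near-)floor estimates

    def test_moment_recovery_alpha_half(self):
        rng = np.random.default_rng(2)
        alpha = 0.5
        meds = []
        for _ in range(200):
            mu = 100.0
            r = 1 / alpha
            counts = pd.DataFrame(rng.negative_binomial(r, r / (r + mu), size=(1, 80)))
            sf = pd.Series(1.0, index=counts.columns)
            disp, _ = estimate_dispersions(counts, sf, shrink=False)
            meds.append(disp.iloc[0])
        assert 0.35 <= np.median(meds) <= 0.65

    def test_shrinkage_moves_toward_trend(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 5 / (5 + 100), size=(50, 30))
        )
        sf = pd.Series(1.0, index=counts.columns)
        raw, trend = estimate_dispersions(counts, sf, shrink=False)
        shrunk, _ = estimate_dispersions(counts, sf, shrink=True)
        a0, a1 = trend
        mu = (counts / sf).mean(axis=1)
        tr = a0 + a1 / mu
        lo = np.minimum(raw, tr)
        hi = np.maximum(raw, tr)
        between = ((shrunk >= lo - 1e-12) & (shrunk <= hi + 1e-12))
        assert between[raw > 1e-7].all()


class TestNBWald:
    def test_identical_groups_zero_beta(self):
        block = np.array([[10, 20, 30], [5, 50, 9]])
        cm = _cm(np.hstack([block, block]), "AAABBB")
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = pd.Series(0.1, index=cm.gene_ids)
        res = fit_nb_wald(cm, DesignSpec("group", ("B", "A")), sf, disp)
        assert res.table["log2FC"].abs().max() < 1e-6

    def test_matches_independent_glm_fit(self):
        """Same likelihood optimum as statsmodels' NB GLM on easy data."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        groups = "A" * 10 + "B" * 10
        counts = rng.negative_binomial(10, 10 / 110, size=(12, 20))
        cm = _cm(counts, groups)
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = pd.Series(0.1, index=cm.gene_ids)
        res = fit_nb_wald(cm, DesignSpec("group", ("B", "A")), sf, disp)
        X = sm.add_constant(np.array([0.0] * 10 + [1.0] * 10))
        for g in ["g0", "g7"]:
            fit = sm.GLM(
                cm.counts.loc[g].to_numpy(),
                X,
                family=sm.families.NegativeBinomial(alpha=0.1),
            ).fit()
            assert res.table.loc[g, "log2FC"] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-4
            )
            assert res.table.loc[g, "SE"] == pytest.approx(
                fit.bse[1] / np.log(2), rel=1e-3
            )

    def test_contrast_antisymmetry(self, toy_counts):
        sf = pd.Series(1.0, index=toy_counts.sample_ids)
        disp = pd.Series(0.1, index=toy_counts.gene_ids)
        ab = fit_nb_wald(toy_counts, DesignSpec("group", ("A", "B")), sf, disp)
        ba = fit_nb_wald(toy_counts, DesignSpec("group", ("B", "A")), sf, disp)
        assert np.allclose(ab.table["log2FC"], -ba.table["log2FC"], atol=1e-8)
        assert np.allclose(ab.table["p"], ba.table["p"], atol=1e-8)

    def test_scaling_equivariance(self, toy_counts):
        s1 = estimate_size_factors(toy_counts.counts)
        disp = pd.Series(0.1, index=toy_counts.gene_ids)
        r1 = fit_nb_wald(toy_counts, DesignSpec("group", ("B", "A")), s1, disp)
        scaled = toy_counts.counts.copy()
        scaled["s0"] = scaled["s0"] * 4
        cm2 = CountMatrix(scaled, toy_counts.samples)
        s2 = estimate_size_factors(cm2.counts)
        # the geometric-mean reference rescales too, so the invariant is on
        # size-factor ratios: s0 gains a factor c relative to every other sample
        assert (s2["s0"] / s2["s1"]) / (s1["s0"] / s1["s1"]) == pytest.approx(4.0)
        # normalised counts k/s are restored, but the scaled sample carries
        # more likelihood weight, so the NB MLE moves only slightly
        r2 = fit_nb_wald(cm2, DesignSpec("group", ("B", "A")), s2, disp)
        assert np.allclose(r1.table["log2FC"], r2.table["log2FC"], atol=0.02)

    def test_global_scaling_exact_invariance(self, toy_counts):
        disp = pd.Series(0.1, index=toy_counts.gene_ids)
        s1 = estimate_size_factors(toy_counts.counts)
        r1 = fit_nb_wald(toy_counts, DesignSpec("group", ("B", "A")), s1, disp)
        r2 = fit_nb_wald(
            toy_counts, DesignSpec("group", ("B", "A")), s1 * 8.0, disp
        )
        assert np.allclose(r1.table["log2FC"], r2.table["log2FC"], atol=1e-6)

    def test_planted_effect_recovery(self):
        rng = np.random.default_rng(7)
        beta, alpha = 1.5, 0.1
        n = 20
        mu_a, mu_b = 100.0, 100.0 * 2**beta
        r = 1 / alpha
        est = []
        for _ in range(100):
            ka = rng.negative_binomial(r, r / (r + mu_a), n)
            kb = rng.negative_binomial(r, r / (r + mu_b), n)
            cm = _cm(np.concatenate([ka, kb])[None, :], "A" * n + "B" * n)
            sf = pd.Series(1.0, index=cm.sample_ids)
            disp = pd.Series(alpha, index=cm.gene_ids)
            res = fit_nb_wald(cm, DesignSpec("group", ("B", "A")), sf, disp)
            est.append(res.table["log2FC"].iloc[0])
        assert abs(np.mean(est) - beta) < 0.1


class TestBenjaminiHochberg:
    def test_hand_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_nan_propagates(self):
        q = benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_invalid_raises(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.0, 0.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([1.5])

    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_properties(self, ps, rnd):
        q = benjamini_hochberg(ps)
        assert (q >= np.asarray(ps) - 1e-15).all()
        assert (q <= 1.0).all()
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q_perm = benjamini_hochberg([ps[i] for i in perm])
        assert np.allclose([q[i] for i in perm], q_perm)

    def test_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 200)
        assert np.allclose(benjamini_hochberg(p), mt.multipletests(p, method="fdr_bh")[1])


class TestVST:
    TREND = (0.05, 2.0)

    def test_zero_count_finite(self):
        counts = pd.DataFrame([[0, 5]], columns=["a", "b"])
        sf = pd.Series(1.0, index=counts.columns)
        v = vst(counts, sf, self.TREND)
        assert np.isfinite(v.to_numpy()).all()

    def test_asymptotic_two_fold_difference(self):
        counts = pd.DataFrame([[10**6, 2 * 10**6]], columns=["a", "b"])
        sf = pd.Series(1.0, index=counts.columns)
        v = vst(counts, sf, (0.05, 1e-9))
        assert v.iloc[0, 1] - v.iloc[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_counts(self):
        counts = pd.DataFrame([np.arange(0, 500, 7)])
        sf = pd.Series(1.0, index=counts.columns)
        v = vst(counts, sf, self.TREND).to_numpy()[0]
        assert (np.diff(v) > 0).all()

    def test_variance_flattening_across_mean_tiers(self):
        rng = np.random.default_rng(5)
        a0, a1 = self.TREND
        raw_var, vst_var = [], []
        sf = pd.Series(1.0, index=range(300))
        for mu in (10, 100, 1000, 10000):
            alpha = a0 + a1 / mu
            r = 1 / alpha
            k = rng.negative_binomial(r, r / (r + mu), size=(1, 300))
            counts = pd.DataFrame(k)
            raw_var.append(np.var(k))
            vst_var.append(np.var(vst(counts, sf, self.TREND).to_numpy()))
        assert max(raw_var) / min(raw_var) > 30
        assert max(vst_var) / min(vst_var) < 3


class TestWilcoxon:
    def test_exact_extreme_arrangement(self):
        W, p = wilcoxon_two_sample([1, 2, 3], [4, 5, 6])
        assert W == 6.0
        assert p == pytest.approx(0.1)

    def test_exact_matches_enumeration(self):
        x = [1.0, 5.0, 2.5]
        y = [4.0, 0.5, 7.0, 3.0]
        _, p = wilcoxon_two_sample(x, y)
        pooled = sorted(x + y)
        from scipy.stats import rankdata

        ranks = rankdata(x + y)
        w_obs = ranks[:3].sum()
        ws = [
            sum(rankdata(pooled)[list(c)])
            for c in itertools.combinations(range(7), 3)
        ]
        mean_w = np.mean(ws)
        p_enum = np.mean([abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12 for w in ws])
        assert p == pytest.approx(p_enum)

    def test_identical_samples(self):
        _, p = wilcoxon_two_sample([2, 2, 2], [2, 2, 2])
        assert p == 1.0
        _, p2 = wilcoxon_two_sample([1, 2, 3, 4], [2, 3, 1, 4])
        assert p2 == pytest.approx(1.0, abs=0.05)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=9), rng.normal(1, 1, size=11)
        w1, p1 = wilcoxon_two_sample(x, y)
        w2, p2 = wilcoxon_two_sample(np.exp(x), np.exp(y))
        assert w1 == w2 and p1 == pytest.approx(p2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_two_sample([], [1.0])


def test_fold_change_conversions_round_trip():
    assert log2fc_to_fold(fold_to_log2fc(10.0)) == pytest.approx(10.0)
    assert fold_to_log2fc(2.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fold_to_log2fc(-1.0)
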