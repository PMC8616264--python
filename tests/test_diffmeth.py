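"""Size factors, dispersion, NB Wald test, BH adjustment, DMCGI calls."""

import numpy as np
import pandas as pd
import pytest

from mbdpipe.counting import FeatureCountMatrix
from mbdpipe.diffmeth import (
    bh_adjust,
    call_dmcgi,
    estimate_dispersions,
    nb_wald_test,
    run_diffmeth,
    size_factors,
    top_features,
)
from mbdpipe.simulate import CountSimConfig, simulate_annotation, simulate_counts


def _matrix(counts: np.ndarray, groups: list[str]) -> FeatureCountMatrix:
    ids = [f"chr1:{i*200+1}-{i*200+100}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return FeatureCountMatrix(
        pd.DataFrame(counts, index=ids, columns=samples),
        pd.Series(["island"] * len(ids), index=ids),
        pd.Series(groups, index=samples),
    )


class TestSizeFactors:
    def test_doubled_sample_forced_values(self):
        counts = np.array([[10, 20], [30, 60], [7, 14], [100, 200]])
        m = _matrix(counts, ["control", "case"])
        s = size_factors(m)
        assert s.tolist() == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_identical_samples_unit_factors(self):
        counts = np.tile(np.array([[10], [20], [30]]), (1, 4))
        m = _matrix(counts, ["control", "control", "case", "case"])
        assert size_factors(m).tolist() == pytest.approx([1.0] * 4)

    def test_geometric_mean_one(self, toy_dataset):
        m, _ = toy_dataset
        s = size_factors(m)
        assert np.exp(np.mean(np.log(s))) == pytest.approx(1.0)

    def test_recovers_simulated_libsizes(self):
        feats, _ = simulate_annotation(400, seed=5)
        isl = [f for f in feats if f.feature_class == "island"]
        cfg = CountSimConfig(seed=5, planted_fraction=0.0, baseline_mean=100)
        m, truth = simulate_counts(cfg, feats)
        s = size_factors(m)
        lib = pd.Series(truth.libsize_factors)
        lib = lib / np.exp(np.mean(np.log(lib)))
        assert np.max(np.abs(s / lib - 1.0)) < 0.05

    def test_no_common_nonzero_feature_errors(self):
        counts = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(_matrix(counts, ["control", "case"]))


class TestDispersions:
    def test_constant_counts_hit_floor(self):
        counts = np.tile(np.array([[50], [80]]), (1, 6))
        m = _matrix(counts, ["control"] * 3 + ["case"] * 3)
        # raw moment estimate is 0 for constant rows -> floored;
        # shrinkage can only move it within [floor, trend]
        alpha = estimate_dispersions(m, size_factors(m), trend_weight=0.0)
        assert (alpha <= 1e-8 + 1e-12).all()

    def test_poisson_data_near_floor(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(100, size=(300, 28))
        m = _matrix(counts, ["control"] * 16 + ["case"] * 12)
        alpha = estimate_dispersions(m, size_factors(m), trend_weight=0.0)
        assert np.median(alpha) < 0.01

    def test_nb_dispersion_recovered(self):
        feats, _ = simulate_annotation(600, seed=8)
        isl = [f for f in feats if f.feature_class == "island"]
        cfg = CountSimConfig(seed=8, planted_fraction=0.0, dispersion=0.1)
        m, _ = simulate_counts(cfg, isl)
        alpha = estimate_dispersions(m, size_factors(m))
        assert 0.05 < np.median(alpha) < 0.2

    def test_single_sample_group_errors(self):
        counts = np.array([[5, 6, 7]])
        m = _matrix(counts, ["control", "control", "case"])
        with pytest.raises(ValueError, match="at least 2"):
            estimate_dispersions(m, size_factors(m))


class TestWald:
    def test_zero_case_counts_negative_fc(self):
        counts = np.column_stack(
            [np.full((20, 4), 50), np.zeros((20, 4), dtype=int)]
        )
        m = _matrix(counts, ["control"] * 4 + ["case"] * 4)
        s = pd.Series(1.0, index=m.counts.columns)
        alpha = pd.Series(0.05, index=m.counts.index)
        res = nb_wald_test(m, s, alpha, control="control", case="case")
        assert (res["log2fc"] < 0).all()
        assert (res["direction"] == "hypo").all()

    def test_planted_fold_change_recovered(self):
        feats, _ = simulate_annotation(800, seed=3)
        isl = [f for f in feats if f.feature_class == "island"]
        cfg = CountSimConfig(seed=3, planted_fraction=0.1, planted_fc=4.0)
        m, truth = simulate_counts(cfg, isl)
        res = run_diffmeth(m, control="control", case="case")
        est = res.loc[truth.planted_hyper, "log2fc"]
        assert abs(est.median() - 2.0) < 0.3

    def test_null_p_uniform(self):
        feats, _ = simulate_annotation(1000, seed=4)
        isl = [f for f in feats if f.feature_class == "island"]
        cfg = CountSimConfig(seed=4, planted_fraction=0.0)
        m, _ = simulate_counts(cfg, isl)
        res = run_diffmeth(m, control="control", case="case")
        from scipy import stats

        ks = stats.kstest(res["wald_p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_matches_deseq2_style_reference_on_strong_effects(self):
        """Independent cross-check: log2fc of strongly planted islands agrees
        with the reference NB Wald implementation (pydeseq2) on a small fixture."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        feats, _ = simulate_annotation(60, seed=12)
        isl = [f for f in feats if f.feature_class == "island"]
        cfg = CountSimConfig(seed=12, planted_fraction=0.25, planted_fc=4.0)
        m, truth = simulate_counts(cfg, isl)
        res = run_diffmeth(m, control="control", case="case")

        meta = pd.DataFrame({"condition": m.groups})
        dds = DeseqDataSet(
            counts=m.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["condition", "case", "control"], quiet=True)
        stat.summary()
        ref = stat.results_df

        ours = res.loc[truth.planted_hyper, "log2fc"]
        theirs = ref.loc[truth.planted_hyper, "log2FoldChange"]
        assert np.max(np.abs(ours - theirs)) < 0.3
        # same calls on the clearly-planted set
        assert (ref.loc[truth.planted_hyper, "padj"] < 0.1).all()
        assert (res.loc[truth.planted_hyper, "q"] < 0.1).all()


class TestBH:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert q.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_degenerate_vectors(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_nan_excluded_from_family(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # family size is 2, not 3
        assert q[0] == pytest.approx(0.02)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_stepup(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 50))
        q = bh_adjust(p)
        # brute-force step-up oracle
        m = len(p)
        order = np.argsort(p)
        expect = np.empty(m)
        for rank_pos, i in enumerate(order, start=1):
            expect[i] = min(
                min(p[j] * m / (list(order).index(j) + 1)
                    for j in order[rank_pos - 1:]),
                1.0,
            )
        assert np.allclose(q, expect)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        assert np.allclose(
            bh_adjust(p), statsmodels.multipletests(p, method="fdr_bh")[1]
        )


class TestCalls:
    def _results(self, log2fc, q):
        ids = [f"chr1:{i*10+1}-{i*10+5}" for i in range(len(log2fc))]
        return pd.DataFrame({"log2fc": log2fc, "q": q}, index=ids)

    def test_strict_thresholds(self):
        res = self._results([2.0, 1.0, 3.0, -2.0], [0.05, 0.05, 0.1, 0.01])
        hyper, hypo = call_dmcgi(res)
        assert hyper == ["chr1:1-5"]       # log2fc 2 > 1, q < 0.1
        assert hypo == ["chr1:31-35"]      # log2fc -2, q 0.01
        # q exactly 0.1 and |log2fc| exactly 1 are excluded

    def test_hyper_hypo_partition_fc_passing_dmrs(self, toy_dataset):
        m, _ = toy_dataset
        from mbdpipe.counting import filter_matrix, subset_islands

        res = run_diffmeth(subset_islands(filter_matrix(m)),
                           control="control", case="case")
        hyper, hypo = call_dmcgi(res)
        assert not set(hyper) & set(hypo)
        both = res["is_dmr"].fillna(False) & res["is_fc_pass"].fillna(False)
        assert len(hyper) + len(hypo) == int(both.sum())

    def test_top_features_ranking_and_ties(self):
        res = self._results([3.0, 2.5, 2.5, 4.0], [0.01, 0.001, 0.01, 0.05])
        assert top_features(res, 1) == ["chr1:31-35"]
        # fc tie between rows 1 and 2 -> smaller q first
        assert top_features(res, 4)[1:3] == ["chr1:1-5", "chr1:11-15"]
        with pytest.raises(ValueError):
            top_features(res, 5)

    def test_top_features_stable_under_row_permutation(self):
        rng = np.random.default_rng(2)
        res = self._results(
            rng.uniform(1.5, 5, size=30), rng.uniform(0, 0.09, size=30)
        )
        top = top_features(res, 10)
        shuffled = res.sample(frac=1.0, random_state=1)
        assert top_features(shuffled, 10) == top
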