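import itertools
import math

import numpy as np
import pandas as pd
import pytest

from refstab import (
    CqMatrix,
    bestkeeper_stability,
    comprehensive_rank,
    cq_to_linear,
    delta_ct_stability,
    genorm_pairwise_variation,
    genorm_stability,
    normfinder_stability,
    stability_report,
)


def _cq(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


def _random_cq(rng, genes=5, samples=8, noise=0.5):
    base = rng.uniform(18, 28, size=(genes, 1))
    shift = rng.normal(0, 1, size=(1, samples))
    return _cq(base + shift + rng.normal(0, noise, size=(genes, samples)))


class TestCqToLinear:
    def test_constant_gene_all_ones(self):
        q = cq_to_linear(_cq([[24, 24, 24]]))
        np.testing.assert_allclose(q.to_numpy(), 1.0)

    def test_one_cycle_above_minimum_halves_quantity(self):
        q = cq_to_linear(_cq([[20, 21, 22]]))
        np.testing.assert_allclose(q.to_numpy()[0], [1.0, 0.5, 0.25])

    def test_elementwise_oracle_with_custom_efficiency(self):
        rng = np.random.default_rng(12)
        arr = rng.uniform(18, 30, size=(4, 6))
        effs = {f"g{i}": e for i, e in enumerate([2.0, 1.9, 2.1, 1.85])}
        q = cq_to_linear(CqMatrix(_cq(arr), efficiencies=effs))
        for i in range(4):
            e = effs[f"g{i}"]
            for j in range(6):
                assert q.iat[i, j] == pytest.approx(
                    e ** (arr[i].min() - arr[i, j]), rel=1e-12
                )

    def test_per_gene_maximum_is_one(self):
        q = cq_to_linear(_random_cq(np.random.default_rng(13)))
        np.testing.assert_allclose(q.max(axis=1), 1.0)


class TestDeltaCt:
    def test_parallel_genes_score_zero(self):
        q = delta_ct_stability(_cq([[20, 22, 21], [23, 25, 24]]))
        np.testing.assert_allclose(q.to_numpy(), 0.0, atol=1e-12)

    def test_matches_pairwise_stdev_oracle(self):
        rng = np.random.default_rng(14)
        arr = rng.uniform(18, 28, size=(3, 4))
        vals = delta_ct_stability(_cq(arr))
        for i in range(3):
            sds = [np.std(arr[i] - arr[h], ddof=1) for h in range(3) if h != i]
            assert vals.iloc[i] == pytest.approx(np.mean(sds), rel=1e-12)

    def test_per_sample_shift_invariance(self):
        rng = np.random.default_rng(15)
        arr = rng.uniform(18, 28, size=(4, 6))
        shift = rng.normal(0, 2, size=6)
        a = delta_ct_stability(_cq(arr))
        b = delta_ct_stability(_cq(arr + shift[None, :]))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_single_gene_is_error(self):
        with pytest.raises(ValueError):
            delta_ct_stability(_cq([[20, 21, 22]]))


class TestBestKeeper:
    def test_constant_gene_zero(self):
        v = bestkeeper_stability(_cq([[24, 24, 24], [20, 21, 22]]))
        assert v.iloc[0] == 0.0

    def test_two_sample_dispersions(self):
        v_mad = bestkeeper_stability(_cq([[19, 21]]), mode="mad")
        v_sd = bestkeeper_stability(_cq([[19, 21]]), mode="sd")
        assert v_mad.iloc[0] == pytest.approx(1.0)
        assert v_sd.iloc[0] == pytest.approx(math.sqrt(2))

    def test_gene_shift_invariance_but_not_sample_shift(self):
        rng = np.random.default_rng(16)
        arr = rng.uniform(18, 28, size=(3, 6))
        base = bestkeeper_stability(_cq(arr))
        shifted = arr.copy()
        shifted[1] += 5.0  # per-gene constant shift
        np.testing.assert_allclose(
            bestkeeper_stability(_cq(shifted)).to_numpy(), base.to_numpy(), atol=1e-12
        )
        sample_shift = arr + rng.normal(0, 2, size=(1, 6))
        assert not np.allclose(
            bestkeeper_stability(_cq(sample_shift)).to_numpy(), base.to_numpy()
        )


class TestNormFinder:
    def test_perfect_additive_data_scores_zero(self):
        gene_eff = np.array([[0.0], [1.0], [2.0], [3.0]])
        sample_eff = np.array([[0.0, 0.5, 1.0, 1.5, 2.0]])
        arr = 20 + gene_eff + sample_eff
        vals = normfinder_stability(_cq(arr))
        np.testing.assert_allclose(vals.to_numpy(), 0.0, atol=1e-9)

    def test_matches_two_way_residual_oracle(self):
        rng = np.random.default_rng(17)
        arr = rng.uniform(18, 28, size=(4, 6))
        cm = CqMatrix(_cq(arr))
        vals = normfinder_stability(cm)
        y = np.log2(cq_to_linear(cm).to_numpy())
        g = 4
        resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
        for i in range(g):
            expect = np.std(resid[i], ddof=1) * math.sqrt(g / (g - 1))
            assert vals.iloc[i] == pytest.approx(expect, abs=1e-12)

    def test_sample_shift_invariance(self):
        rng = np.random.default_rng(18)
        arr = rng.uniform(18, 28, size=(4, 6))
        shift = rng.normal(0, 2, size=6)
        a = normfinder_stability(_cq(arr))
        b = normfinder_stability(_cq(arr + shift[None, :]))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_grouped_mode_penalizes_group_difference(self):
        rng = np.random.default_rng(19)
        arr = 24 + rng.normal(0, 0.05, size=(8, 8))
        biased = arr.copy()
        biased[0, 4:] += 2.0  # gene 0 runs 2 cycles higher in group B
        groups = {f"s{j}": ("A" if j < 4 else "B") for j in range(8)}
        vals = normfinder_stability(CqMatrix(_cq(biased), groups=groups))
        assert vals.iloc[0] > 3 * vals.iloc[1:].max()

    def test_singleton_group_is_error(self):
        groups = {"s0": "A", "s1": "B", "s2": "B", "s3": "B"}
        with pytest.raises(ValueError, match="fewer than 2"):
            normfinder_stability(
                CqMatrix(_cq(np.full((3, 4), 24.0)), groups=groups), grouped=True
            )


def _genorm_oracle(quantities):
    """Brute-force geNorm: recompute every round from scratch."""
    logq = {g: np.log2(quantities.loc[g].to_numpy()) for g in quantities.index}
    included = list(quantities.index)
    m_hist, order = {}, []
    while len(included) > 2:
        m = {}
        for g in included:
            vs = [
                np.std(logq[g] - logq[h], ddof=1) for h in included if h != g
            ]
            m[g] = float(np.mean(vs))
        m_hist.update(m)
        worst_val = max(m.values())
        worst = max(g for g, v in m.items() if v == worst_val)
        order.append(worst)
        included.remove(worst)
    v = float(np.std(logq[included[0]] - logq[included[1]], ddof=1))
    for g in included:
        m_hist[g] = v
    return m_hist, order, included


class TestGeNorm:
    def test_proportional_genes_have_zero_pairwise_variation(self):
        q = _cq([[1, 2, 4], [0.5, 1, 2], [1, 1, 1]])
        m, ranks = genorm_stability(q)
        # genes 0 and 1 are proportional: their mutual V is 0, so they
        # survive elimination and share the top rank
        assert ranks.iloc[0] == ranks.iloc[1] == 1.5
        assert m.iloc[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_genes", [4, 5, 6])
    def test_matches_full_recomputation_oracle(self, n_genes):
        rng = np.random.default_rng(20 + n_genes)
        q = pd.DataFrame(
            rng.lognormal(0, 0.5, size=(n_genes, 7)),
            index=[f"g{i}" for i in range(n_genes)],
        )
        m, ranks = genorm_stability(q)
        m_oracle, order, survivors = _genorm_oracle(q)
        for g in q.index:
            assert m[g] == pytest.approx(m_oracle[g], rel=1e-12)
        for pos, g in enumerate(reversed(order), start=3):
            assert ranks[g] == pos
        assert all(ranks[s] == 1.5 for s in survivors)

    def test_first_round_m_equals_delta_ct_at_e2(self):
        rng = np.random.default_rng(21)
        cq = _random_cq(rng, genes=5, samples=8)
        deltact = delta_ct_stability(cq)
        logq = np.log2(cq_to_linear(cq).to_numpy())
        first_m = []
        for i in range(5):
            vs = [np.std(logq[i] - logq[h], ddof=1) for h in range(5) if h != i]
            first_m.append(np.mean(vs))
        np.testing.assert_allclose(first_m, deltact.to_numpy(), atol=1e-10)

    def test_final_pair_m_equals_mutual_v(self):
        rng = np.random.default_rng(22)
        q = pd.DataFrame(rng.lognormal(0, 0.5, size=(5, 6)))
        q.index = [f"g{i}" for i in range(5)]
        m, ranks = genorm_stability(q)
        survivors = list(ranks[ranks == 1.5].index)
        assert len(survivors) == 2
        v = np.std(
            np.log2(q.loc[survivors[0]] / q.loc[survivors[1]]), ddof=1
        )
        assert m[survivors[0]] == pytest.approx(v) == m[survivors[1]]

    def test_split_tie_mode_gives_ranks_1_and_2(self):
        rng = np.random.default_rng(23)
        q = pd.DataFrame(rng.lognormal(0, 0.5, size=(5, 6)))
        q.index = [f"g{i}" for i in range(5)]
        _, ranks = genorm_stability(q, tie_mode="split")
        assert sorted(ranks)[:2] == [1.0, 2.0]

    def test_positive_quantities_required(self):
        q = _cq([[1, 0, 1], [1, 1, 1], [2, 2, 2]])
        with pytest.raises(ValueError, match="positive"):
            genorm_stability(q)


class TestPairwiseVariation:
    def test_identical_genes_give_zero_for_all_k(self):
        q = _cq([[1, 2, 3]] * 5)
        for k in range(2, 5):
            assert genorm_pairwise_variation(q, k) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(24)
        q = pd.DataFrame(
            rng.lognormal(0, 0.4, size=(5, 7)), index=[f"g{i}" for i in range(5)]
        )
        _, ranks = genorm_stability(q)
        order = list(ranks.sort_values(kind="mergesort").index)
        for k in (2, 3, 4):
            nf_k = np.log2(q.loc[order[:k]]).mean(axis=0)
            nf_k1 = np.log2(q.loc[order[: k + 1]]).mean(axis=0)
            expect = np.std(nf_k - nf_k1, ddof=1)
            assert genorm_pairwise_variation(q, k) == pytest.approx(expect, rel=1e-12)

    def test_sample_relabeling_invariance(self):
        rng = np.random.default_rng(25)
        q = pd.DataFrame(
            rng.lognormal(0, 0.4, size=(4, 6)), index=[f"g{i}" for i in range(4)]
        )
        perm = rng.permutation(6)
        assert genorm_pairwise_variation(q, 2) == pytest.approx(
            genorm_pairwise_variation(q.iloc[:, perm], 2)
        )

    def test_k_out_of_range(self):
        q = _cq([[1, 2, 3]] * 4)
        with pytest.raises(ValueError):
            genorm_pairwise_variation(q, 1)
        with pytest.raises(ValueError):
            genorm_pairwise_variation(q, 4)


class TestComprehensiveRank:
    def test_unanimous_winner(self):
        ranks = pd.DataFrame(
            {"a": [1, 2, 3], "b": [1, 3, 2], "c": [1, 2, 3], "d": [1, 3, 2]},
            index=["top", "mid", "low"],
        )
        out = comprehensive_rank(ranks)
        assert out.loc["top", "comprehensive_geomean"] == pytest.approx(1.0)
        assert out.loc["top", "comprehensive_rank"] == 1

    def test_geometric_mean_arithmetic(self):
        ranks = pd.DataFrame({"a": [2.0], "b": [8.0], "c": [4.0], "d": [1.0]},
                             index=["g"])
        out = comprehensive_rank(ranks)
        assert out.loc["g", "comprehensive_geomean"] == pytest.approx(64 ** 0.25)

    def test_method_column_order_irrelevant(self):
        rng = np.random.default_rng(26)
        ranks = pd.DataFrame(
            rng.permuted(np.tile(np.arange(1.0, 7.0), (4, 1)), axis=1).T,
            index=[f"g{i}" for i in range(6)],
            columns=list("abcd"),
        )
        a = comprehensive_rank(ranks)
        b = comprehensive_rank(ranks[["d", "b", "a", "c"]])
        pd.testing.assert_frame_equal(a, b)

    def test_missing_rank_is_error(self):
        ranks = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, 1.0]}, index=["x", "y"])
        with pytest.raises(ValueError, match="x"):
            comprehensive_rank(ranks)


class TestReportAndInvariances:
    def test_gene_wise_shift_leaves_all_methods_unchanged(self):
        rng = np.random.default_rng(27)
        arr = _random_cq(rng, genes=5, samples=8).to_numpy()
        shifted = arr.copy()
        shifted[2] += 4.0
        base, after = _cq(arr), _cq(shifted)
        for fn in (
            delta_ct_stability,
            bestkeeper_stability,
            normfinder_stability,
            lambda m: genorm_stability(cq_to_linear(m))[0],
        ):
            np.testing.assert_allclose(
                fn(base).to_numpy(), fn(after).to_numpy(), atol=1e-9
            )

    def test_report_has_all_columns_and_consistent_ranks(self):
        rng = np.random.default_rng(28)
        cq = _random_cq(rng, genes=6, samples=9)
        report = stability_report(cq)
        for method in ("deltact", "bestkeeper", "normfinder"):
            vals = report[f"{method}_value"]
            ranks = report[f"{method}_rank"]
            assert (vals >= 0).all()
            pd.testing.assert_series_equal(
                ranks, vals.rank(method="average"), check_names=False
            )
        geo = report[
            ["deltact_rank", "bestkeeper_rank", "normfinder_rank", "genorm_rank"]
        ].prod(axis=1) ** 0.25
        np.testing.assert_allclose(report["comprehensive_geomean"], geo, rtol=1e-12)

    def test_report_requires_minimum_size(self):
        with pytest.raises(ValueError):
            stability_report(_cq(np.full((2, 5), 24.0)))
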