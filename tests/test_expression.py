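import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from plaquemap.expression import (
    find_degs,
    mean_profiles,
    normalize,
    rank_sum_one_vs_rest,
)
from plaquemap.io_formats import ClusterAssignment, CountMatrix, ValidationError


def _cm(dense, genes=None, barcodes=None):
    dense = np.asarray(dense)
    genes = genes or [f"G{i}" for i in range(dense.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(dense.shape[1])]
    return CountMatrix(genes, barcodes, sp.csr_matrix(dense))


class TestNormalize:
    def test_closed_form_single_gene(self):
        cm = _cm([[10, 1], [0, 1]])
        norm = normalize(cm, scale=1e4)
        assert norm.dense()[0, 0] == pytest.approx(np.log1p(1e4))

    def test_zero_total_cell_fatal(self):
        cm = _cm([[1, 0], [1, 0]])
        with pytest.raises(ValidationError, match="zero total"):
            normalize(cm)

    def test_zero_counts_stay_zero(self):
        cm = _cm([[3, 0], [0, 2]])
        dense = normalize(cm).dense()
        assert dense[0, 1] == 0 and dense[1, 0] == 0

    def test_per_cell_conservation(self):
        rng = np.random.default_rng(2)
        cm = _cm(rng.poisson(2.0, size=(100, 50)) + 1)
        norm = normalize(cm, scale=1e4)
        sums = np.expm1(norm.dense()).sum(axis=0)
        np.testing.assert_allclose(sums, 1e4, rtol=1e-9)


class TestMeanProfiles:
    def test_identical_cells_column(self):
        col = np.array([[3], [0], [7]])
        cm = _cm(np.hstack([col, col, col, 2 * col]))
        clusters = ClusterAssignment(
            {"c0": "same", "c1": "same", "c2": "same", "c3": "other"}
        )
        prof = mean_profiles(normalize(cm), clusters)
        single = normalize(cm).dense()[:, 0]
        np.testing.assert_allclose(prof.table["same"].to_numpy(), single)

    def test_matches_two_loop_oracle(self):
        rng = np.random.default_rng(5)
        cm = _cm(rng.poisson(1.5, size=(30, 24)) + 1)
        labels = [f"k{i % 3}" for i in range(24)]
        clusters = ClusterAssignment(dict(zip(cm.barcodes, labels)))
        norm = normalize(cm)
        prof = mean_profiles(norm, clusters)
        dense = norm.dense()
        for lab in ("k0", "k1", "k2"):
            cols = [j for j, l in enumerate(labels) if l == lab]
            for gi in range(30):
                expected = sum(dense[gi, j] for j in cols) / len(cols)
                assert prof.table.loc[cm.genes[gi], lab] == pytest.approx(expected)

    def test_weighted_columns_recover_global_mean(self):
        rng = np.random.default_rng(8)
        cm = _cm(rng.poisson(1.0, size=(20, 12)) + 1)
        labels = ["a"] * 5 + ["b"] * 7
        clusters = ClusterAssignment(dict(zip(cm.barcodes, labels)))
        norm = normalize(cm)
        prof = mean_profiles(norm, clusters)
        combined = (5 * prof.table["a"] + 7 * prof.table["b"]) / 12
        np.testing.assert_allclose(combined.to_numpy(), norm.dense().mean(axis=1))


def exact_rank_sum_p(x_in, x_out):
    """Exhaustive two-sided rank-sum p over all C(n1+n2, n1) splits."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x_in, x_out])
    n1 = len(x_in)
    ranks = rankdata(pooled)
    mu = n1 * (len(pooled) - n1) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        hits += abs(u - mu) >= dev - 1e-12
        total += 1
    return hits / total


class TestRankSum:
    def test_six_vs_six_against_enumeration(self):
        x_in = np.array([8.0, 7, 6, 5, 4, 3])
        x_out = np.array([2.5, 2, 1.5, 1, 0.5, 0])
        exact = exact_rank_sum_p(x_in, x_out)
        assert exact == pytest.approx(2 / 924)
        x = np.concatenate([x_in, x_out])[None, :]
        mask = np.zeros(12, dtype=bool)
        mask[:6] = True
        approx = rank_sum_one_vs_rest(x, mask)[0]
        assert abs(approx - exact) < 0.02

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(40, 60))
        x[:, :25] = np.round(x[:, :25], 1)  # induce ties
        mask = np.zeros(60, dtype=bool)
        mask[:25] = True
        ours = rank_sum_one_vs_rest(x, mask)
        for gi in range(40):
            ref = mannwhitneyu(
                x[gi, mask], x[gi, ~mask], alternative="two-sided", method="asymptotic"
            ).pvalue
            assert ours[gi] == pytest.approx(ref, rel=1e-9)

    def test_all_tied_gives_p_one(self):
        x = np.ones((3, 20))
        mask = np.zeros(20, dtype=bool)
        mask[:8] = True
        np.testing.assert_array_equal(rank_sum_one_vs_rest(x, mask), 1.0)


class TestFindDegs:
    def _separated(self):
        rng = np.random.default_rng(3)
        dense = rng.poisson(1.0, size=(20, 60)) + 1
        dense[0, :] = 0
        dense[0, :20] = rng.integers(5, 15, 20)  # nonzero only in cluster A
        cm = _cm(dense)
        labels = ["A"] * 20 + ["B"] * 40
        return cm, ClusterAssignment(dict(zip(cm.barcodes, labels)))

    def test_perfect_separation_significant(self):
        cm, clusters = self._separated()
        degs = find_degs(normalize(cm), clusters)
        row = degs.table[(degs.table["gene"] == "G0") & (degs.table["cluster"] == "A")]
        assert row["is_significant"].item()
        assert row["log2_fold_change"].item() > 0

    def test_constant_gene_not_significant(self):
        # equal cell totals so the constant gene stays constant after
        # normalisation: G0 separates the clusters, G2 balances totals
        dense = np.zeros((3, 60), dtype=int)
        dense[0, :20] = 10
        dense[1, :] = 5
        dense[2, 20:] = 10
        cm = _cm(dense)
        labels = ["A"] * 20 + ["B"] * 40
        clusters = ClusterAssignment(dict(zip(cm.barcodes, labels)))
        degs = find_degs(normalize(cm), clusters)
        g1 = degs.table[degs.table["gene"] == "G1"]
        assert (g1["pval"] == 1.0).all()
        assert not g1["is_significant"].any()
        g0 = degs.table[(degs.table["gene"] == "G0") & (degs.table["cluster"] == "A")]
        assert g0["is_significant"].item()

    def test_low_expression_genes_excluded_from_universe(self):
        cm, clusters = self._separated()
        cmat = cm.dense()
        cmat[2, :] = 0
        cmat[2, 0] = 1  # expressed in 1 cell < min_cells_expressing
        degs = find_degs(normalize(_cm(cmat)), clusters)
        assert "G2" not in degs.universe

    def test_column_permutation_invariance(self):
        cm, clusters = self._separated()
        degs_a = find_degs(normalize(cm), clusters)
        rng = np.random.default_rng(0)
        perm = rng.permutation(60)
        cm_p = CountMatrix(
            cm.genes, [cm.barcodes[j] for j in perm], sp.csr_matrix(cm.dense()[:, perm])
        )
        degs_b = find_degs(normalize(cm_p), clusters)
        a = degs_a.table.sort_values(["gene", "cluster"]).reset_index(drop=True)
        b = degs_b.table.sort_values(["gene", "cluster"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_alpha_monotonicity(self, small_simulation):
        cm, clusters, _ = small_simulation
        norm = normalize(cm)
        loose = set(find_degs(norm, clusters, alpha=0.05).deg_genes)
        strict = set(find_degs(norm, clusters, alpha=0.01).deg_genes)
        assert strict <= loose

    def test_small_cluster_skipped(self):
        cm, _ = self._separated()
        labels = ["A"] * 2 + ["B"] * 29 + ["C"] * 29
        clusters = ClusterAssignment(dict(zip(cm.barcodes, labels)))
        degs = find_degs(normalize(cm), clusters)
        assert set(degs.table["cluster"]) == {"B", "C"}
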