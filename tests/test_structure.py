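"""Batch scaling, ward.D clustering, correlation PCA, fold-change tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.base import clone

from ntmemory import (CorrelationPCA, DoubleZScore, WardClustering,
                      double_zscore, heatmap_matrix, hierarchical_cluster,
                      ma_table, pca_samples)
from ntmemory.structure import cut_clusters
from conftest import lance_williams_ward


def _matrix(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values, index=[f"t{i}" for i in range(values.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(values.shape[1])])


def _batches(cols, assignment):
    return pd.Series(assignment, index=cols)


class TestDoubleZScore:
    def test_single_batch_equals_row_zscore(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(20, 6)))
        b = _batches(m.columns, ["b1"] * 6)
        out = double_zscore(m, b)
        expected = m.sub(m.mean(axis=1), axis=0).div(m.std(axis=1, ddof=1), axis=0)
        assert np.allclose(out, expected)

    def test_additive_batch_offset_removed(self):
        base = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        shifted = base.copy()
        shifted[0, 3:] += 7.5  # pure per-batch location shift
        b = _batches([f"s{j}" for j in range(6)], ["b1"] * 3 + ["b2"] * 3)
        out_plain = double_zscore(_matrix(base), b)
        out_shift = double_zscore(_matrix(shifted), b)
        assert np.allclose(out_plain, out_shift)

    def test_batch_scale_also_removed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 8))
        scaled = base.copy()
        scaled[:, 4:] = scaled[:, 4:] * 3.0 + 2.0
        b = _batches([f"s{j}" for j in range(8)], ["b1"] * 4 + ["b2"] * 4)
        assert np.allclose(double_zscore(_matrix(base), b),
                           double_zscore(_matrix(scaled), b))

    def test_output_rows_standardized(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(30, 9)))
        b = _batches(m.columns, ["b1"] * 3 + ["b2"] * 3 + ["b3"] * 3)
        out = double_zscore(m, b)
        assert np.allclose(out.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(out.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_single_sample_batch_rejected(self):
        m = _matrix(np.ones((3, 3)))
        b = _batches(m.columns, ["b1", "b1", "b2"])
        with pytest.raises(ValueError, match="single sample"):
            double_zscore(m, b)

    def test_constant_rows_zeroed_with_warning(self):
        m = _matrix(np.vstack([np.ones(4), [1, 2, 3, 4]]))
        b = _batches(m.columns, ["b1"] * 4)
        with pytest.warns(UserWarning, match="constant"):
            out = double_zscore(m, b)
        assert np.allclose(out.iloc[0], 0)


class TestWardClustering:
    def test_identical_pair_merges_first_at_zero(self):
        m = _matrix(np.array([[0.0, 0.0, 5.0], [1.0, 1.0, 9.0]]))
        dendro = hierarchical_cluster(m, axis="samples")
        first = dendro["linkage"][0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(size=(12, 8)))
        heights = hierarchical_cluster(m)["heights"]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_matches_lance_williams_oracle_on_six_samples(self):
        """Full ward.D merge history against the naive recurrence oracle."""
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(size=(15, 6)))
        dendro = hierarchical_cluster(m, axis="samples")
        dist = squareform(pdist(m.to_numpy().T))
        oracle = lance_williams_ward(dist)
        # replay the package linkage into leaf-member merge history
        members = {i: {i} for i in range(6)}
        for step, (a, b, h, _) in enumerate(dendro["linkage"]):
            got = (members[int(a)], members[int(b)])
            exp_i, exp_j, exp_h = oracle[step]
            assert {frozenset(got[0]), frozenset(got[1])} == \
                {frozenset(exp_i), frozenset(exp_j)}
            assert h == pytest.approx(exp_h)
            members[6 + step] = members.pop(int(a)) | members.pop(int(b))

    def test_nan_rejected(self):
        m = _matrix(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValueError, match="NaN"):
            hierarchical_cluster(m)

    def test_estimator_flat_cut(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (4, 10)), rng.normal(5, 0.1, (4, 10))])
        est = clone(WardClustering(n_clusters=2)).fit(X)
        assert len(set(est.labels_[:4])) == 1
        assert len(set(est.labels_[4:])) == 1
        assert est.labels_[0] != est.labels_[4]


class TestCorrelationPCA:
    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        res = pca_samples(_matrix(rng.normal(size=(40, 7))))
        assert res["variance_fractions"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_perfectly_correlated_pair_eigenvalues(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        m = _matrix(np.vstack([x, 3 * x + 1]))
        res = pca_samples(m)
        assert res["eigenvalues"][0] == pytest.approx(2.0)
        assert res["eigenvalues"][1] == pytest.approx(0.0, abs=1e-12)

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.normal(size=(20, 6)))
        res = pca_samples(m)
        X = m.to_numpy().T
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        corr = Xs.T @ Xs / (X.shape[0] - 1)
        w, v = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        scores = Xs @ v
        for k in range(5):
            got = res["scores"].to_numpy()[:, k]
            assert np.allclose(np.abs(got), np.abs(scores[:, k]), atol=1e-8)
        assert np.allclose(res["eigenvalues"][:5], w[:5])

    def test_zero_variance_variable_dropped(self):
        m = _matrix(np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2]))
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_samples(m)
        assert len(res["loadings"]) == 2

    def test_estimator_round_trip(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 5))
        est = clone(CorrelationPCA(n_components=3))
        scores = est.fit_transform(X)
        assert scores.shape == (10, 3)
        assert np.allclose(est.transform(X), scores, atol=1e-8)


class TestFoldChangeTables:
    def _samples(self):
        return pd.DataFrame({"sample_id": ["d0", "i0", "i1"],
                             "group": ["donor", "IVF_ectoderm", "IVF_ectoderm"]})

    def test_reference_mean_maps_to_zero(self):
        m = pd.DataFrame({"d0": [4.0], "i0": [4.0], "i1": [4.0]}, index=["t0"])
        out = heatmap_matrix(m, self._samples(), reference_group="IVF_ectoderm")
        assert np.allclose(out, 0.0)

    def test_doubling_adds_one_without_pseudocount(self):
        m = pd.DataFrame({"d0": [8.0], "i0": [2.0], "i1": [6.0]}, index=["t0"])
        base = heatmap_matrix(m, self._samples(), pseudocount=0.0)
        m2 = m.copy()
        m2["d0"] *= 2
        doubled = heatmap_matrix(m2, self._samples(), pseudocount=0.0)
        assert doubled.loc["t0", "d0"] - base.loc["t0", "d0"] == pytest.approx(1.0)

    def test_matches_cell_by_cell_recomputation(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.uniform(0, 50, size=(6, 3)),
                         index=[f"t{i}" for i in range(6)],
                         columns=["d0", "i0", "i1"])
        out = heatmap_matrix(m, self._samples(), reference_group="pooled",
                             pseudocount=1.0)
        for t in m.index:
            ref = m.loc[t].mean()
            for c in m.columns:
                assert out.loc[t, c] == pytest.approx(
                    np.log2((m.loc[t, c] + 1) / (ref + 1)))

    def test_empty_reference_rejected(self):
        m = pd.DataFrame({"d0": [1.0]}, index=["t0"])
        with pytest.raises(ValueError, match="empty"):
            heatmap_matrix(m, self._samples(), reference_group="NT_ectoderm")

    def test_ma_table_axis_values(self):
        de = pd.DataFrame({"logFC": [0.5, -1.0]}, index=["t0", "t1"])
        rpkm = pd.DataFrame({"d0": [0.0, 1.0], "d1": [0.0, 1.0]},
                            index=["t0", "t1"])
        out = ma_table(de, rpkm)
        assert out.loc["t0", "mean_log2_rpkm_donor"] == pytest.approx(0.0)
        assert out.loc["t1", "mean_log2_rpkm_donor"] == pytest.approx(1.0)
        # brute force per transcript
        rng = np.random.default_rng(10)
        rpkm = pd.DataFrame(rng.uniform(0, 20, (5, 3)),
                            index=[f"g{i}" for i in range(5)])
        de = pd.DataFrame({"logFC": rng.normal(size=5)}, index=rpkm.index)
        out = ma_table(de, rpkm)
        for g in rpkm.index:
            assert out.loc[g, "mean_log2_rpkm_donor"] == pytest.approx(
                np.mean([np.log2(1 + v) for v in rpkm.loc[g]]))


def test_double_zscore_estimator_matches_function():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(6, 12))  # samples × transcripts
    batches = ["b1"] * 3 + ["b2"] * 3
    est = clone(DoubleZScore(batches=batches))
    out = est.fit_transform(X)
    m = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(6)])
    expected = double_zscore(m, pd.Series(batches, index=m.columns))
    assert np.allclose(out, expected.to_numpy().T)


def test_cut_clusters_labels():
    m = _matrix(np.array([[0, 0, 9, 9.1], [0, 0.1, 9, 9]]))
    cl = cut_clusters(hierarchical_cluster(m), 2)
    assert cl["s0"] == cl["s1"] and cl["s2"] == cl["s3"]
    assert cl["s0"] != cl["s2"]
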