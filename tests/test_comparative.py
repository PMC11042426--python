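"""Sample matrix assembly, Pearson correlation, Ward clustering."""

import numpy as np
import pytest

from snoglyc.comparative import (
    build_matrix,
    cluster,
    mutual_nearest_merges,
    pearson,
)
from snoglyc.precursor_aggregation import bin_features
from snoglyc.spectra_io import PrecursorFeature, RunConfig


def _hist(cfg, sample, masses_intensities):
    feats = [PrecursorFeature(mass=m, rt=0.0, intensity=i, sample=sample)
             for m, i in masses_intensities]
    return bin_features(feats, cfg, sample)


class TestBuildMatrix:
    def test_rows_sum_to_one(self, cfg):
        h1 = _hist(cfg, "a", [(2000.0, 3e6), (3000.0, 7e6)])
        h2 = _hist(cfg, "b", [(2000.0, 5e6), (3000.0, 5e6)])
        m = build_matrix([h1, h2])
        np.testing.assert_allclose(m.data.sum(axis=1), [1.0, 1.0])

    def test_absent_bin_is_zero(self, cfg):
        h1 = _hist(cfg, "a", [(2000.0, 1e7), (2500.0, 1e7)])
        h2 = _hist(cfg, "b", [(2000.0, 1e7)])
        m = build_matrix([h1, h2])
        assert m.data.loc["b", 2500.0] == 0.0

    def test_single_histogram_rejected(self, cfg):
        with pytest.raises(ValueError):
            build_matrix([_hist(cfg, "a", [(2000.0, 1e7)])])

    def test_duplicate_labels_rejected(self, cfg):
        h1 = _hist(cfg, "a", [(2000.0, 1e7)])
        h2 = _hist(cfg, "a", [(2500.0, 1e7)])
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix([h1, h2])


class TestPearson:
    def test_identical_rows(self, cfg):
        h1 = _hist(cfg, "a", [(2000.0, 3e6), (3000.0, 7e6)])
        h2 = _hist(cfg, "b", [(2000.0, 3e6), (3000.0, 7e6)])
        corr = pearson(build_matrix([h1, h2]))
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_scale_invariance_before_tic_normalization(self, cfg):
        h1 = _hist(cfg, "a", [(2000.0, 3e6), (3000.0, 7e6)])
        h2 = _hist(cfg, "b", [(2000.0, 9e6), (3000.0, 21e6)])  # 3x scaled
        corr = pearson(build_matrix([h1, h2]))
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_two_point_anticorrelation(self, cfg):
        h1 = _hist(cfg, "a", [(2000.0, 1e7)])
        h2 = _hist(cfg, "b", [(3000.0, 1e7)])
        corr = pearson(build_matrix([h1, h2]))
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal(self, cfg):
        rng = np.random.default_rng(0)
        hists = [
            _hist(cfg, f"s{i}",
                  [(2000.0 + 10 * j, float(rng.uniform(1e6, 1e7)))
                   for j in range(5)])
            for i in range(4)
        ]
        corr = pearson(build_matrix(hists)).to_numpy()
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert np.all(corr <= 1.0 + 1e-12) and np.all(corr >= -1.0 - 1e-12)


def _ward_oracle(points, labels):
    """Brute-force Lance-Williams Ward agglomeration (<= 6 items)."""
    clusters = {i: [i] for i in range(len(points))}
    sizes = {i: 1 for i in range(len(points))}
    d = {}
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d[(i, j)] = float(np.linalg.norm(points[i] - points[j]))
    merges = []
    next_id = len(points)
    while len(clusters) > 1:
        (a, b), dist = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((a, b, dist, sizes[a] + sizes[b]))
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (a, b):
                continue
            dak = d[tuple(sorted((a, k)))]
            dbk = d[tuple(sorted((b, k)))]
            dab = d[tuple(sorted((a, b)))]
            na, nb, nk = sizes[a], sizes[b], sizes[k]
            n = na + nb + nk
            # Lance-Williams update for Ward linkage on Euclidean distances
            dnew = np.sqrt(
                (na + nk) / n * dak ** 2 + (nb + nk) / n * dbk ** 2
                - nk / n * dab ** 2
            )
            d[tuple(sorted((new, k)))] = float(dnew)
        clusters[new] = clusters.pop(a) + clusters.pop(b)
        sizes[new] = sizes.pop(a) + sizes.pop(b)
        d = {k: v for k, v in d.items()
             if a not in k and b not in k}
    return merges


class TestCluster:
    def test_coincident_pair_merges_first_at_zero(self, cfg):
        h1 = _hist(cfg, "a", [(2000.0, 1e7)])
        h2 = _hist(cfg, "b", [(2000.0, 1e7)])
        h3 = _hist(cfg, "c", [(3000.0, 1e7)])
        dendro = cluster(build_matrix([h1, h2, h3]))
        first = dendro.linkage[0]
        assert {dendro.labels[int(first[0])], dendro.labels[int(first[1])]} == \
            {"a", "b"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_two_items_single_merge(self, cfg):
        h1 = _hist(cfg, "a", [(2000.0, 1e7)])
        h2 = _hist(cfg, "b", [(3000.0, 1e7)])
        dendro = cluster(build_matrix([h1, h2]))
        assert dendro.linkage.shape == (1, 4)

    def test_merge_heights_monotone(self, cfg):
        rng = np.random.default_rng(1)
        hists = [
            _hist(cfg, f"s{i}",
                  [(2000.0 + 10 * j, float(rng.uniform(1e6, 1e7)))
                   for j in range(6)])
            for i in range(6)
        ]
        dendro = cluster(build_matrix(hists))
        heights = dendro.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_matches_bruteforce_ward_oracle(self, cfg):
        rng = np.random.default_rng(2)
        hists = [
            _hist(cfg, f"s{i}",
                  [(2000.0 + 10 * j, float(rng.uniform(1e6, 1e7)))
                   for j in range(4)])
            for i in range(5)
        ]
        matrix = build_matrix(hists)
        dendro = cluster(matrix)
        points = matrix.data.sort_index().to_numpy()
        oracle = _ward_oracle(points, sorted(matrix.samples))
        np.testing.assert_allclose(dendro.linkage[:, 2],
                                   [m[2] for m in oracle], rtol=1e-9)
        np.testing.assert_allclose(dendro.linkage[:, 3],
                                   [m[3] for m in oracle])

    def test_leaf_order_deterministic_under_input_order(self, cfg):
        h = {
            name: _hist(cfg, name, [(2000.0 + 10 * i, 1e7)])
            for i, name in enumerate(["a", "b", "c"])
        }
        d1 = cluster(build_matrix([h["a"], h["b"], h["c"]]))
        d2 = cluster(build_matrix([h["c"], h["a"], h["b"]]))
        assert d1.leaf_order() == d2.leaf_order()

    def test_newick_parses_with_dendropy(self, cfg):
        import dendropy

        h1 = _hist(cfg, "a", [(2000.0, 1e7)])
        h2 = _hist(cfg, "b", [(2000.0, 9e6), (2500.0, 1e6)])
        h3 = _hist(cfg, "c", [(3000.0, 1e7)])
        dendro = cluster(build_matrix([h1, h2, h3]))
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == \
            {"a", "b", "c"}

    def test_mutual_nearest_merges(self, cfg):
        h = [
            _hist(cfg, "t1_a", [(2000.0, 1e7), (2500.0, 2e6)]),
            _hist(cfg, "t1_b", [(2000.0, 1.05e7), (2500.0, 2.1e6)]),
            _hist(cfg, "t2_a", [(3000.0, 1e7)]),
            _hist(cfg, "t2_b", [(3000.0, 1.02e7), (2000.0, 1e5)]),
        ]
        dendro = cluster(build_matrix(h))
        result = mutual_nearest_merges(
            dendro, [("t1_a", "t1_b"), ("t2_a", "t2_b")])
        assert all(result.values())
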