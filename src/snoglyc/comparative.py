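"""Cross-sample comparison: sample x mass-bin matrix, Pearson correlation,
Ward hierarchical clustering.

Clustering by default runs on the TIC-normalized bin-intensity vectors
(Euclidean distance, Ward linkage).  A t-SNE embedding of the matrix
prior to clustering is available behind a flag for exploratory use; it
is stochastic and therefore not the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class SampleMatrix:
    """TIC-normalized intensities: rows = samples, columns = bin centers."""

    data: pd.DataFrame  # index: sample labels, columns: bin centers

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def centers(self) -> list[float]:
        return list(self.data.columns)


def build_matrix(histograms: list) -> SampleMatrix:
    """Union-of-bins matrix with per-sample TIC normalization.

    Bins absent in a sample contribute 0; rows of samples with nonzero
    TIC sum to 1.
    """
    if len(histograms) < 2:
        raise ValueError("need at least two histograms to compare")
    labels = [h.sample for h in histograms]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate sample labels: {dupes}")
    centers = sorted({round(b.center, 6) for h in histograms for b in h.bins})
    rows = []
    for h in histograms:
        vec = dict.fromkeys(centers, 0.0)
        for b in h.bins:
            vec[round(b.center, 6)] += b.intensity
        total = sum(vec.values())
        if total > 0:
            vec = {k: v / total for k, v in vec.items()}
        rows.append([vec[c] for c in centers])
    df = pd.DataFrame(rows, index=labels, columns=centers)
    return SampleMatrix(df)


def pearson(matrix: SampleMatrix) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation matrix.

    Symmetric with unit diagonal; rows with zero variance give NaN
    entries (flagged undefined).
    """
    values = matrix.data.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.samples, columns=matrix.samples)


@dataclass
class Dendrogram:
    linkage: np.ndarray
    labels: list[str]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        body = walk(tree, tree.dist)
        # root branch length is meaningless; strip it
        return body.rsplit(":", 1)[0] + ";"


def cluster(matrix: SampleMatrix, method: str = "ward",
            use_tsne: bool = False, perplexity: float = 5.0,
            random_state: int = 0) -> Dendrogram:
    """Agglomerative clustering of samples (Euclidean distance).

    Samples are sorted by label first so leaf order is deterministic
    under input reordering.  With ``use_tsne`` the Euclidean distances
    are taken between t-SNE coordinates of the samples instead of the
    raw bin vectors (seeded; perplexity configurable).
    """
    df = matrix.data.sort_index()
    labels = list(df.index)
    values = df.to_numpy(dtype=float)
    if use_tsne:
        from sklearn.manifold import TSNE

        perplexity = min(perplexity, max(1.0, (len(labels) - 1) / 3))
        values = TSNE(n_components=2, perplexity=perplexity,
                      random_state=random_state, init="pca").fit_transform(values)
    dists = pdist(values, metric="euclidean")
    if not np.all(np.isfinite(dists)):
        raise ValueError("non-finite distances between samples")
    Z = hierarchy.linkage(dists, method=method)
    return Dendrogram(linkage=Z, labels=labels)


def mutual_nearest_merges(dendro: Dendrogram,
                          pairs: list[tuple[str, str]]) -> dict[tuple[str, str], bool]:
    """For each (a, b) pair: do a and b merge with each other first?

    True when the first merge involving either leaf is the merge of the
    two leaves together (the replicate-reproducibility check).
    """
    idx = {lab: i for i, lab in enumerate(dendro.labels)}
    n = len(dendro.labels)
    out = {}
    for a, b in pairs:
        ia, ib = idx[a], idx[b]
        result = False
        for row in dendro.linkage:
            left, right = int(row[0]), int(row[1])
            members = {left, right}
            if members == {ia, ib}:
                result = True
                break
            if (ia in members or ib in members) and (left < n and right < n):
                break
            if ia in members or ib in members:
                break
        out[(a, b)] = result
    return out
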