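"""Unsupervised sample analysis: Spearman similarity + Ward clustering.

Inter-sample similarity is Spearman's rank-order correlation of expression
profiles (ties mid-ranked). Hierarchical clustering is then run *on the
similarity matrix* with Euclidean distance and Ward's minimum-variance
linkage — read literally: Euclidean distances between the rows of the
similarity matrix. The alternative reading, ``sqrt(2 * (1 - rho))`` as a
correlation-derived distance, is available via ``distance="one-minus-cor"``.

The adjusted Rand index against the binary response labels quantifies
whether unsupervised structure recovers the responder split (in highly
correlated tumor cohorts it typically does not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from .formats import ExpressionMatrix, ResponseTable


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric sample × sample correlation matrix with unit diagonal."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.sample_ids)
        if values.shape != (n, n):
            raise ValueError("similarity matrix must be square over sample_ids")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")
        if np.nanmax(np.abs(values)) > 1 + 1e-12:
            raise ValueError("similarity values must lie in [-1, 1]")


def spearman_similarity(expr: ExpressionMatrix) -> SimilarityMatrix:
    """Pairwise Spearman correlation between sample expression profiles.

    A sample constant across all genes has no defined rank correlation and
    raises an error naming the sample.
    """
    if expr.n_samples < 2 or expr.n_genes < 2:
        raise ValueError("need >=2 samples and >=2 genes")
    for j, sid in enumerate(expr.sample_ids):
        if np.ptp(expr.values[:, j]) == 0:
            raise ValueError(
                f"sample {sid!r} is constant across genes: Spearman undefined"
            )
    ranks = rankdata(expr.values, axis=0)  # mid-ranks within each sample
    corr = np.corrcoef(ranks.T)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    return SimilarityMatrix(expr.sample_ids, corr)


def _linkage_to_newick(link: np.ndarray, leaf_names: list[str] | tuple[str, ...]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch
    lengths taken from merge-height differences."""
    tree = hierarchy.to_tree(link)

    def build(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = build(node.get_left(), node.dist)
        right = build(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"


def ward_cluster(
    sim: SimilarityMatrix, k: int, distance: str = "euclidean-rows"
) -> tuple[dict[str, int], str]:
    """Ward hierarchical clustering of samples from their similarity matrix.

    ``distance="euclidean-rows"`` (default): Euclidean distance between rows
    of the similarity matrix. ``distance="one-minus-cor"``: the
    correlation-as-distance alternative ``sqrt(2 * (1 - rho))``. Returns a
    sample -> cluster assignment (clusters numbered 1..k) and a Newick
    dendrogram; deterministic.
    """
    n = len(sim.sample_ids)
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, {n - 1}], got {k}")
    if distance == "euclidean-rows":
        dists = pdist(sim.values, metric="euclidean")
    elif distance == "one-minus-cor":
        iu = np.triu_indices(n, k=1)
        dists = np.sqrt(np.clip(2.0 * (1.0 - sim.values[iu]), 0.0, None))
    else:
        raise ValueError(f"unknown distance {distance!r}")
    link = hierarchy.linkage(dists, method="ward")
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    assignment = {s: int(c) for s, c in zip(sim.sample_ids, flat)}
    return assignment, _linkage_to_newick(link, list(sim.sample_ids))


def cluster_label_concordance(
    assignment: dict[str, int], labels: ResponseTable
) -> float:
    """Adjusted Rand index between a clustering and the binary response."""
    missing = set(labels.sample_ids) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing samples: {sorted(missing)}")
    pred = [assignment[s] for s in labels.sample_ids]
    return float(adjusted_rand_score(labels.response, pred))
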