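"""Biomarker scoring: concordance index, permutation significance, ranking.

The concordance index (C-index) of a score vector against a binary response
is the probability that a randomly chosen responder scores higher than a
randomly chosen non-responder, with tied scores counting one half — the
AUC-equivalent for binary outcomes. Significance is a label-permutation
fraction: how often a random relabelling yields a C-index strictly greater
than the observed one (one-sided toward high C-index; a symmetric variant
uses max(c, 1 - c)).

The permutation fraction is reported per feature exactly as computed, and a
separate Benjamini–Hochberg-adjusted column is attached when ranking many
features, so no multiplicity claim is hidden behind a single number.
Exhaustive enumeration of distinct labelings replaces Monte-Carlo sampling
automatically when there are at most 10,000 of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from .classifier import DeltaTscProfile
from .formats import ExpressionMatrix, ResponseTable
from .tsc import UNDEFINED

logger = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class BiomarkerResult:
    """One feature's predictive value within one (arm, ER) group."""

    feature_name: str
    cindex: float
    perm_significance: float
    n_samples: int
    group: tuple[str, str] | None = None
    bh_adjusted: float = UNDEFINED


def concordance_index(scores: Sequence[float], labels: Sequence[int]) -> float:
    """C-index of scores against binary labels (ties count 0.5 per pair).

    Computed from midranks (Mann–Whitney U), which equals the mean over all
    (positive, negative) pairs of [score_pos > score_neg] + 0.5·[equal].
    Returns the undefined marker when either class is empty.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return UNDEFINED
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _cindex_from_ranks(ranks: np.ndarray, pos_mask: np.ndarray) -> float:
    n_pos = int(pos_mask.sum())
    n_neg = pos_mask.size - n_pos
    u = ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _iter_labelings(n: int, n_pos: int):
    base = np.zeros(n, dtype=bool)
    for pos in combinations(range(n), n_pos):
        lab = base.copy()
        lab[list(pos)] = True
        yield lab


def permutation_significance(
    scores: Sequence[float],
    labels: Sequence[int],
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "auto",
) -> float:
    """Fraction of label permutations whose C-index strictly exceeds the
    observed one.

    ``mode``: "auto" (exhaustive when the number of distinct labelings is at
    most 10,000, Monte-Carlo otherwise), "exhaustive", or "montecarlo".
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("auto", "exhaustive", "montecarlo"):
        raise ValueError(f"unknown mode {mode!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n = labels.size
    if n_pos == 0 or n_pos == n:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(scores)
    observed = _cindex_from_ranks(ranks, labels == 1)

    exhaustive = mode == "exhaustive" or (
        mode == "auto" and comb(n, n_pos) <= EXHAUSTIVE_LIMIT
    )
    if exhaustive:
        total = exceed = 0
        for lab in _iter_labelings(n, n_pos):
            total += 1
            if _cindex_from_ranks(ranks, lab) > observed:
                exceed += 1
        return exceed / total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _cindex_from_ranks(ranks, (labels == 1)[perm]) > observed:
            exceed += 1
    return exceed / n_perm


def _permutation_fractions_matrix(
    rank_matrix: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """One-sided permutation fractions for many features sharing one label
    vector, vectorized over features.

    For binary labels the C-index of feature ``f`` under a relabelling ``b``
    is affine in ``rank_matrix[f] @ b``, so every permutation is one
    matrix-vector product.
    """
    n = labels.size
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    offset = n_pos * (n_pos + 1) / 2
    scale = n_pos * n_neg
    observed = (rank_matrix @ (labels == 1) - offset) / scale

    if comb(n, n_pos) <= EXHAUSTIVE_LIMIT:
        labelings = np.stack(list(_iter_labelings(n, n_pos)))  # (L, n)
        perm_c = (rank_matrix @ labelings.T - offset) / scale  # (F, L)
        return (perm_c > observed[:, None] + 1e-12).mean(axis=1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(rank_matrix.shape[0])
    pos = (labels == 1).astype(float)
    for _ in range(n_perm):
        b = pos[rng.permutation(n)]
        perm_c = (rank_matrix @ b - offset) / scale
        exceed += perm_c > observed + 1e-12
    return exceed / n_perm


def _rank_and_sort(
    names: list[str],
    cindices: np.ndarray,
    perm_fracs: np.ndarray,
    n_samples: int,
    group: tuple[str, str] | None,
) -> list[BiomarkerResult]:
    bh = multipletests(perm_fracs, method="fdr_bh")[1]
    results = [
        BiomarkerResult(name, float(c), float(p), n_samples, group, float(q))
        for name, c, p, q in zip(names, cindices, perm_fracs, bh)
    ]
    results.sort(key=lambda r: (-r.cindex, r.feature_name))
    return results


def univariate_gene_biomarkers(
    expr: ExpressionMatrix,
    labels: ResponseTable,
    group: tuple[str, str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[BiomarkerResult]:
    """Per-gene C-index against response within one (arm, ER) group, with
    permutation significance and a BH-adjusted column; sorted by C-index
    descending (gene name breaks ties deterministically).

    A group with an empty class is skipped with a warning (empty list).
    """
    sub_labels = labels.group(*group) if group is not None else labels
    if len(sub_labels) == 0 or len(set(sub_labels.response)) < 2:
        logger.warning("group %s has an empty response class: skipped", group)
        return []
    sub_expr = expr.subset_samples(list(sub_labels.sample_ids))
    y = sub_labels.response
    rank_matrix = rankdata(sub_expr.values, axis=1)
    offset = y.sum() * (y.sum() + 1) / 2
    scale = y.sum() * (len(y) - y.sum())
    cindices = (rank_matrix @ (y == 1) - offset) / scale
    perm = _permutation_fractions_matrix(rank_matrix, y, n_perm, seed)
    return _rank_and_sort(list(sub_expr.gene_ids), cindices, perm, len(y), group)


def pathway_biomarkers(
    profile: DeltaTscProfile,
    labels: ResponseTable,
    group: tuple[str, str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[BiomarkerResult]:
    """Per-pathway C-index of the delta-TSC column against response.

    Undefined delta entries are dropped pairwise with their labels; a column
    that is entirely undefined is excluded with a warning. The profile must
    have been computed on the same samples as ``labels`` (after any
    grouping).
    """
    sub_labels = labels.group(*group) if group is not None else labels
    sub_labels = sub_labels.subset(
        [s for s in profile.sample_ids if s in set(sub_labels.sample_ids)]
    )
    row = {s: i for i, s in enumerate(profile.sample_ids)}
    rows = np.array([row[s] for s in sub_labels.sample_ids], dtype=int)
    y_all = sub_labels.response

    names: list[str] = []
    cindices: list[float] = []
    fracs: list[float] = []
    for p, name in enumerate(profile.pathway_names):
        col = profile.delta[rows, p]
        defined = ~np.isnan(col)
        if not defined.any():
            logger.warning("pathway %r: delta-TSC entirely undefined, excluded", name)
            continue
        scores, y = col[defined], y_all[defined]
        if len(set(y)) < 2:
            logger.warning("pathway %r: one class fully undefined, excluded", name)
            continue
        c = concordance_index(scores, y)
        frac = permutation_significance(scores, y, n_perm=n_perm, seed=seed + p)
        names.append(name)
        cindices.append(c)
        fracs.append(frac)
    if not names:
        return []
    return _rank_and_sort(
        names, np.asarray(cindices), np.asarray(fracs), len(sub_labels), group
    )


def compare_biomarker_profiles(
    cindex_vec_a: Mapping[str, float],
    cindex_vec_b: Mapping[str, float],
) -> float:
    """Spearman rank correlation of two pathway C-index profiles over their
    shared pathways; undefined (nan) with fewer than 3 shared pathways."""
    shared = sorted(set(cindex_vec_a) & set(cindex_vec_b))
    if len(shared) < 3:
        return UNDEFINED
    a = np.array([cindex_vec_a[k] for k in shared])
    b = np.array([cindex_vec_b[k] for k in shared])
    rho = spearmanr(a, b).statistic
    return float(rho)


def biomarker_profile_matrix(
    profiles: Mapping[str, Mapping[str, float]],
) -> tuple[list[str], np.ndarray]:
    """Pairwise Spearman matrix over >=2 named C-index profiles (e.g. the
    six arm × ER groups); entries with <3 shared pathways are nan."""
    names = list(profiles)
    if len(names) < 2:
        raise ValueError("need >=2 profiles to compare")
    n = len(names)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rho = compare_biomarker_profiles(profiles[names[i]], profiles[names[j]])
            mat[i, j] = mat[j, i] = rho
    return names, mat


def cluster_biomarker_profiles(
    profiles: Mapping[str, Mapping[str, float]],
) -> tuple[list[str], np.ndarray, str]:
    """Ward clustering of >=3 groups by their pathway C-index profiles.

    Returns (group names, pairwise Spearman matrix, Newick dendrogram). The
    clustering runs on the rows of the Spearman matrix with Euclidean
    distance, mirroring the sample-level unsupervised analysis.
    """
    from .clustering import _linkage_to_newick  # local import avoids a cycle
    from scipy.cluster.hierarchy import linkage

    names, mat = biomarker_profile_matrix(profiles)
    if len(names) < 3:
        raise ValueError("need >=3 profiles to cluster")
    if np.isnan(mat).any():
        raise ValueError("profile matrix has undefined entries (too few shared pathways)")
    link = linkage(mat, method="ward", metric="euclidean")
    return names, mat, _linkage_to_newick(link, names)
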