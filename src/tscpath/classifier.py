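"""Responder prediction from pathway-level transcriptional similarity.

Two procedures live here:

* :func:`delta_tsc_profile` — for every (sample, pathway), the difference
  between the sample's TSC to the responder population and to the
  non-responder population, each computed leave-one-out (the scored sample is
  excluded from both reference populations). The resulting samples × pathways
  "delta TSC" matrix is the pathway biomarker feature.

* :func:`loocv_predict` — the subsampled leave-one-out majority-vote
  classifier: each held-out sample is compared, per pathway, against small
  random draws (default 5 samples) from responders and from non-responders;
  the two per-pathway TSC vectors are reduced to their medians and the sample
  votes responder when the responder-side median is strictly higher. The vote
  is repeated (default 100 draws) and the majority decides.

Tie votes and median ties count as non-responder: conservative toward the
clinically default "no pCR" class, and deterministic. Draws are without
replacement within a class; when a class is smaller than the draw size the
sampler falls back to drawing with replacement and logs loudly. One global
seed spawns per-sample substreams indexed by sample rank, so adding a sample
does not perturb the draws of the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats import ExpressionMatrix, GeneSetCollection, ResponseTable
from .tsc import UNDEFINED, _tsc_from_grams, is_defined

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeltaTscProfile:
    """Samples × pathways matrix of TSC(sample vs responders) - TSC(sample vs
    non-responders); entries may carry the undefined marker (nan)."""

    sample_ids: tuple[str, ...]
    pathway_names: tuple[str, ...]
    delta: np.ndarray

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta, dtype=float)
        object.__setattr__(self, "delta", delta)
        if delta.shape != (len(self.sample_ids), len(self.pathway_names)):
            raise ValueError("delta shape must be (samples, pathways)")
        defined = delta[~np.isnan(delta)]
        if defined.size and (np.abs(defined) > 2 + 1e-9).any():
            raise ValueError("defined delta-TSC entries must lie in [-2, 2]")

    def column(self, pathway: str) -> np.ndarray:
        return self.delta[:, self.pathway_names.index(pathway)]


@dataclass(frozen=True)
class VotePrediction:
    """Majority-vote outcome for one held-out sample."""

    sample_id: str
    votes_responder: int
    votes_total: int
    predicted: int
    vote_fraction: float

    def __post_init__(self) -> None:
        if self.votes_responder > self.votes_total:
            raise ValueError("votes_responder cannot exceed votes_total")


def classify_rule(tsc_resp: float, tsc_nonresp: float) -> float:
    """Binary vote from the two reference similarities.

    1 when similarity to responders is strictly higher, 0 when strictly
    lower; a tie counts as non-responder. When exactly one side is undefined
    the vote follows the defined side (similarity to the other class could
    not be established); both sides undefined propagates the marker.
    """
    r_def, n_def = is_defined(tsc_resp), is_defined(tsc_nonresp)
    if not r_def and not n_def:
        return UNDEFINED
    if not n_def:
        return 1.0
    if not r_def:
        return 0.0
    return 1.0 if tsc_resp > tsc_nonresp else 0.0


class _PathwayWorkspace:
    """Precomputed per-pathway gene submatrices and per-sample outer Grams.

    The off-diagonal Gram of a multi-sample population is the sum of the
    per-sample outer products with the diagonal zeroed, so leave-one-out
    population Grams are obtained by subtracting one sample's outer product
    from the class total.
    """

    def __init__(self, expr: ExpressionMatrix, pathways: GeneSetCollection):
        self.pathway_names: list[str] = []
        self.submatrices: list[np.ndarray | None] = []
        universe = set(expr.gene_ids)
        for name in pathways.names:
            shared = sorted(set(pathways[name]) & universe)
            self.pathway_names.append(name)
            if len(shared) < 2:
                self.submatrices.append(None)  # TSC undefined for this pathway
            else:
                self.submatrices.append(expr.values[expr.gene_index(shared)])

    def sample_gram(self, p: int, col: int) -> np.ndarray | None:
        sub = self.submatrices[p]
        if sub is None:
            return None
        x = sub[:, col]
        gram = np.outer(x, x)
        np.fill_diagonal(gram, 0.0)
        return gram

    def population_gram(self, p: int, cols: np.ndarray) -> np.ndarray | None:
        sub = self.submatrices[p]
        if sub is None:
            return None
        block = sub[:, cols]
        gram = block @ block.T
        np.fill_diagonal(gram, 0.0)
        return gram


def delta_tsc_profile(
    expr: ExpressionMatrix,
    labels: ResponseTable,
    pathways: GeneSetCollection,
) -> DeltaTscProfile:
    """Leave-one-out delta-TSC matrix over all samples and pathways.

    For sample ``s`` and pathway ``P``: ``TSC(s, responders \\ {s}) -
    TSC(s, non-responders \\ {s})``. An undefined TSC on either side makes
    the entry undefined. A class emptied by the holdout is a hard error.
    """
    order = {s: i for i, s in enumerate(expr.sample_ids)}
    resp_cols = np.array([order[s] for s in labels.samples_with(1)], dtype=int)
    non_cols = np.array([order[s] for s in labels.samples_with(0)], dtype=int)
    ws = _PathwayWorkspace(expr, pathways)
    n_s, n_p = len(labels), len(ws.pathway_names)
    delta = np.full((n_s, n_p), np.nan)

    for si, sample in enumerate(labels.sample_ids):
        col = order[sample]
        r_cols = resp_cols[resp_cols != col]
        n_cols = non_cols[non_cols != col]
        if r_cols.size == 0:
            raise ValueError(
                f"holding out {sample!r} empties the responder class"
            )
        if n_cols.size == 0:
            raise ValueError(
                f"holding out {sample!r} empties the non-responder class"
            )
        for p in range(n_p):
            g_s = ws.sample_gram(p, col)
            if g_s is None:
                continue
            t_r = _tsc_from_grams(g_s, ws.population_gram(p, r_cols))
            t_n = _tsc_from_grams(g_s, ws.population_gram(p, n_cols))
            if is_defined(t_r) and is_defined(t_n):
                delta[si, p] = t_r - t_n
    return DeltaTscProfile(
        tuple(labels.sample_ids), tuple(ws.pathway_names), delta
    )


def sample_substream(seed: int, rank: int) -> np.random.Generator:
    """Per-sample random stream, indexed by the sample's rank in the label
    table: adding or re-seeding one sample never perturbs the draws of the
    others."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(rank,))
    )


def _draw(rng: np.random.Generator, pool: np.ndarray, size: int, tag: str) -> np.ndarray:
    if pool.size >= size:
        return rng.choice(pool, size=size, replace=False)
    logger.warning(
        "class %s has only %d samples (< draw size %d): sampling WITH replacement",
        tag,
        pool.size,
        size,
    )
    return rng.choice(pool, size=size, replace=True)


def loocv_predict(
    expr: ExpressionMatrix,
    labels: ResponseTable,
    pathways: GeneSetCollection,
    n_draws: int = 100,
    draw_size: int = 5,
    seed: int = 0,
) -> list[VotePrediction]:
    """Subsampled leave-one-out majority-vote prediction for every sample.

    For each held-out sample, ``n_draws`` times: draw ``draw_size``
    responders and ``draw_size`` non-responders (both excluding the sample),
    compute the per-pathway TSC of the sample against each draw, reduce each
    side to its median over pathways (undefined entries dropped), and vote
    via :func:`classify_rule`. A draw in which more than half of the pathways
    are undefined on either side abstains and is not counted. The majority of
    counted votes is the prediction (vote tie -> non-responder). Fully
    reproducible from ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if draw_size < 1:
        raise ValueError("draw_size must be >= 1")
    order = {s: i for i, s in enumerate(expr.sample_ids)}
    resp_cols = np.array([order[s] for s in labels.samples_with(1)], dtype=int)
    non_cols = np.array([order[s] for s in labels.samples_with(0)], dtype=int)
    if resp_cols.size == 0 or non_cols.size == 0:
        raise ValueError("both response classes must be non-empty")
    ws = _PathwayWorkspace(expr, pathways)
    n_p = len(ws.pathway_names)
    if n_p == 0:
        raise ValueError("no pathways supplied")

    predictions: list[VotePrediction] = []
    for rank, sample in enumerate(labels.sample_ids):
        col = order[sample]
        rng = sample_substream(seed, rank)
        r_pool = resp_cols[resp_cols != col]
        n_pool = non_cols[non_cols != col]
        sample_grams = [ws.sample_gram(p, col) for p in range(n_p)]
        votes_resp = 0
        votes_total = 0
        for _ in range(n_draws):
            r_cols = _draw(rng, r_pool, draw_size, "responder")
            n_cols = _draw(rng, n_pool, draw_size, "non-responder")
            t_resp = np.full(n_p, np.nan)
            t_non = np.full(n_p, np.nan)
            for p in range(n_p):
                g_s = sample_grams[p]
                if g_s is None:
                    continue
                t_resp[p] = _tsc_from_grams(g_s, ws.population_gram(p, r_cols))
                t_non[p] = _tsc_from_grams(g_s, ws.population_gram(p, n_cols))
            def_r = ~np.isnan(t_resp)
            def_n = ~np.isnan(t_non)
            # abstain when either side has no defined pathway or loses >50%
            if def_r.sum() == 0 or def_n.sum() == 0:
                continue
            if (~def_r).sum() > n_p / 2 or (~def_n).sum() > n_p / 2:
                continue
            vote = classify_rule(
                float(np.median(t_resp[def_r])), float(np.median(t_non[def_n]))
            )
            if not is_defined(vote):
                continue
            votes_total += 1
            votes_resp += int(vote)
        predicted = 1 if votes_resp > votes_total / 2 else 0
        fraction = votes_resp / votes_total if votes_total else 0.0
        predictions.append(
            VotePrediction(sample, votes_resp, votes_total, predicted, fraction)
        )
    return predictions
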