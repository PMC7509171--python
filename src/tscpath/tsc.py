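"""Transcriptional similarity coefficient (TSC) between sample populations.

The TSC compares the gene–gene co-expression pattern of one pathway between
two sets of samples ("populations"). Let ``P`` be the genes × samples matrix
of a pathway's expression in one population. Its *off-diagonal Gram matrix*

    P0 = P @ P.T - Diagonal(P @ P.T)

captures pairwise gene–gene inner products with the self-products removed;
zeroing the diagonal makes the comparison insensitive to how many samples
each population contains. The TSC of two populations ``P1``, ``P2`` sharing
the same ordered gene list is the cosine similarity of their off-diagonal
Grams:

    TSC(P1, P2) = trace(P10 @ P20) / sqrt(||P10||_F^2 * ||P20||_F^2)

which lies in [-1, 1] by Cauchy–Schwarz, equals 1 for a population compared
with itself, and is exactly invariant to duplicating samples or rescaling a
population by any nonzero scalar.

A TSC is *undefined* when either off-diagonal Gram is all-zero (zero
denominator); the package represents this by ``nan`` — an explicit marker,
never silently 0, because 0 is a meaningful similarity value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import ExpressionMatrix

#: Marker for an undefined TSC (zero-denominator comparison).
UNDEFINED = float("nan")


def is_defined(value: float) -> bool:
    """True when a TSC (or other score) value is defined (not the marker)."""
    return not np.isnan(value)


@dataclass(frozen=True)
class PopulationMatrix:
    """Pathway-restricted genes × samples submatrix for one population.

    Needs at least 2 genes (with a single gene the off-diagonal Gram is
    empty) and at least 1 sample. Two populations entering a TSC must share
    the same gene list in the same order.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    population_label: str = ""

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(self.gene_ids) < 2:
            raise ValueError("TSC needs >=2 genes; off-diagonal Gram empty otherwise")
        if values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"values have {values.shape[0]} rows for {len(self.gene_ids)} genes"
            )
        if values.shape[1] < 1:
            raise ValueError("population needs >=1 sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[1])


def offdiag_gram(pop: PopulationMatrix | np.ndarray) -> np.ndarray:
    """Off-diagonal Gram matrix ``P @ P.T`` with the diagonal zeroed.

    Symmetric by construction; requires >=2 genes.
    """
    values = pop.values if isinstance(pop, PopulationMatrix) else np.asarray(pop, float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("off-diagonal Gram needs a 2-D matrix with >=2 gene rows")
    gram = values @ values.T
    np.fill_diagonal(gram, 0.0)
    return gram


def _tsc_from_grams(g1: np.ndarray, g2: np.ndarray) -> float:
    # trace(g1 @ g2) == Frobenius inner product for symmetric matrices
    denom = np.sqrt(np.sum(g1 * g1) * np.sum(g2 * g2))
    if denom == 0.0:
        return UNDEFINED
    # Cauchy-Schwarz bounds the quotient by 1; clip float rounding overshoot
    return float(np.clip(np.sum(g1 * g2) / denom, -1.0, 1.0))


def tsc(pop1: PopulationMatrix, pop2: PopulationMatrix) -> float:
    """TSC between two populations on an identical ordered gene list.

    Returns a value in [-1, 1], or ``nan`` when either off-diagonal Gram is
    all-zero (the caller decides how to treat an uninformative pathway).
    """
    if pop1.gene_ids != pop2.gene_ids:
        raise ValueError("populations must share the same gene list in the same order")
    return _tsc_from_grams(offdiag_gram(pop1), offdiag_gram(pop2))


def tsc_sample_vs_population(
    expr: ExpressionMatrix,
    sample_id: str,
    population_ids: list[str] | tuple[str, ...],
    gene_set: tuple[str, ...] | list[str],
) -> float:
    """TSC of one sample against a multi-sample population on one pathway.

    The gene set is intersected with the measured genes and canonicalized to
    lexicographic order before Gram construction, so the result does not
    depend on GMT or file ordering (the trace and norms are permutation-
    covariant; canonicalization makes outputs byte-stable). Fewer than 2
    shared genes yields the undefined marker; an empty population is an
    error.
    """
    if len(population_ids) == 0:
        raise ValueError("population is empty")
    if sample_id in population_ids:
        raise ValueError(f"sample {sample_id!r} may not appear in its own reference")
    shared = sorted(set(gene_set) & set(expr.gene_ids))
    if len(shared) < 2:
        return UNDEFINED
    rows = expr.gene_index(shared)
    col = expr.sample_index([sample_id])
    cols = expr.sample_index(population_ids)
    sub = expr.values[rows]
    p1 = PopulationMatrix(tuple(shared), sub[:, col], population_label=sample_id)
    p2 = PopulationMatrix(tuple(shared), sub[:, cols], population_label="population")
    return tsc(p1, p2)
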