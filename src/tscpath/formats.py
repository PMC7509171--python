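"""Domain containers and on-disk formats.

Every downstream stage consumes the three containers defined here:

* :class:`ExpressionMatrix` — a genes × samples abundance table,
* :class:`GeneSetCollection` — named gene sets (GMT-backed, e.g. MSigDB GO C5),
* :class:`ResponseTable` — per-sample binary response (pCR) plus treatment arm
  and estrogen-receptor (ER) stratum.

Expression and clinical tables travel as TSV/CSV with a header row; gene sets
travel as standard GMT (``name<TAB>description<TAB>gene...``). Result tables
written elsewhere in the package are TSV with a YAML sidecar recording the
parameters and seed of the run.

Expression values are consumed exactly as given. The pipeline never rescales
silently; an explicit ``log2(x + 1)`` transform is available via
:func:`log2p1` for callers whose matrices are on a linear abundance scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARMS = ("lapatinib", "trastuzumab", "combination")
ER_STATUSES = ("ER+", "ER-")


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples numeric abundance table on a log-like scale.

    Invariants: identifiers unique, no missing values, at least one gene and
    one sample. ``values[i, j]`` is the abundance of ``gene_ids[i]`` in
    ``sample_ids[j]``.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValueError(f"expression values must be 2-D, got {values.ndim}-D")
        if len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise ValueError("expression matrix needs at least 1 gene and 1 sample")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicated {label} identifiers: {dups}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def sample_index(self, samples: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in samples], dtype=int)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index(samples)
        return ExpressionMatrix(self.gene_ids, tuple(samples), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            tuple(map(str, frame.index)),
            tuple(map(str, frame.columns)),
            frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with ordered, duplicate-free membership lists."""

    sets: Mapping[str, tuple[str, ...]]
    source_description: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for name, genes in self.sets.items():
            genes = tuple(str(g) for g in genes)
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            dups = _find_duplicates(genes)
            if dups:
                raise ValueError(f"gene set {name!r} has duplicate genes: {dups}")
            clean[str(name)] = genes
        object.__setattr__(self, "sets", clean)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.sets)


@dataclass(frozen=True)
class ResponseTable:
    """Per-sample clinical labels: binary pCR response, arm, ER status.

    ``response`` is 1 for a responder (recorded pathological complete
    response) and 0 otherwise — any patient without a recorded pCR counts as
    a non-responder.
    """

    sample_ids: tuple[str, ...]
    response: np.ndarray
    arm: tuple[str, ...]
    er_status: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        resp = np.asarray(self.response, dtype=int)
        object.__setattr__(self, "response", resp)
        object.__setattr__(self, "arm", tuple(str(a) for a in self.arm))
        object.__setattr__(self, "er_status", tuple(str(e) for e in self.er_status))
        n = len(self.sample_ids)
        if not (len(resp) == len(self.arm) == len(self.er_status) == n):
            raise ValueError("response/arm/er_status lengths must match sample_ids")
        dups = _find_duplicates(self.sample_ids)
        if dups:
            raise ValueError(f"duplicated sample identifiers: {dups}")
        if not np.isin(resp, (0, 1)).all():
            raise ValueError("response labels must be binary (0/1)")
        bad_arm = sorted(set(self.arm) - set(ARMS))
        if bad_arm:
            raise ValueError(f"unknown treatment arm(s): {bad_arm}")
        bad_er = sorted(set(self.er_status) - set(ER_STATUSES))
        if bad_er:
            raise ValueError(f"unknown ER status value(s): {bad_er}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def label_of(self, sample_id: str) -> int:
        return int(self.response[self.sample_ids.index(sample_id)])

    def samples_with(self, response: int) -> list[str]:
        return [s for s, r in zip(self.sample_ids, self.response) if r == response]

    def subset(self, sample_ids: Sequence[str]) -> "ResponseTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return ResponseTable(
            tuple(sample_ids),
            self.response[rows],
            tuple(self.arm[i] for i in rows),
            tuple(self.er_status[i] for i in rows),
        )

    def group(self, arm: str, er_status: str) -> "ResponseTable":
        """Restrict to one (treatment arm, ER stratum) group."""
        keep = [
            s
            for s, a, e in zip(self.sample_ids, self.arm, self.er_status)
            if a == arm and e == er_status
        ]
        return self.subset(keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "response": self.response,
                "arm": list(self.arm),
                "er_status": list(self.er_status),
            }
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_DIALECT_SEP = {"tsv": "\t", "csv": ","}


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes × samples table: first column gene ids, header sample ids.

    Raises ``ValueError`` naming the offending identifiers/cells on duplicate
    ids, non-numeric entries, or an empty file.
    """
    sep = _DIALECT_SEP[dialect]
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty expression file: {path}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"expression file {path} has no genes or no samples")
    for label, ids in (("gene", list(frame.index)), ("sample", list(frame.columns))):
        dups = _find_duplicates([str(x) for x in ids])
        if dups:
            raise ValueError(f"duplicated {label} identifiers in {path}: {dups}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        col = numeric.columns[numeric.isna().any(axis=0)][0]
        raise ValueError(
            f"non-numeric cell in {path} at gene {gene!r}, sample {col!r}"
        )
    return ExpressionMatrix.from_frame(numeric)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    expr.to_frame().to_csv(path, sep=_DIALECT_SEP[dialect], index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (``name<TAB>description<TAB>gene...``).

    Duplicate genes within a line are dropped (first occurrence kept) with a
    logged warning; a duplicate set name or a line with fewer than three
    fields is a hard error.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: list[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "gene set %r: dropped %d duplicate gene(s)",
                    name,
                    len(genes) - len(deduped),
                )
            sets[name] = tuple(deduped)
            descriptions.append(description)
    return GeneSetCollection(sets, source_description=str(path))


def write_gmt(
    collection: GeneSetCollection, path: str | Path, description: str = "na"
) -> None:
    with open(path, "w") as handle:
        for name, genes in collection.sets.items():
            handle.write("\t".join([name, description, *genes]) + "\n")


def read_response_table(path: str | Path, dialect: str = "tsv") -> ResponseTable:
    """Read a clinical table with columns sample_id, response, arm, er_status."""
    frame = pd.read_csv(path, sep=_DIALECT_SEP[dialect], dtype=str)
    required = {"sample_id", "response", "arm", "er_status"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"clinical table {path} missing columns: {sorted(missing)}")
    return ResponseTable(
        tuple(frame["sample_id"]),
        frame["response"].astype(int).to_numpy(),
        tuple(frame["arm"]),
        tuple(frame["er_status"]),
    )


def write_response_table(
    labels: ResponseTable, path: str | Path, dialect: str = "tsv"
) -> None:
    labels.to_frame().to_csv(path, sep=_DIALECT_SEP[dialect], index=False)


def filter_sets_by_size(
    collection: GeneSetCollection,
    min_size: int,
    max_size: int,
    expr: ExpressionMatrix,
) -> GeneSetCollection:
    """Keep sets whose intersection with the measured genes has size in
    ``[min_size, max_size]`` (inclusive), replacing memberships by that
    intersection.

    Sizes are counted *after* intersecting with the expression matrix's gene
    universe: the similarity coefficient can only use measured genes. Genes
    absent from the matrix are dropped silently per set, with one summary log
    line. An empty result is a soft error: an empty collection plus a warning.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2 (similarity needs >=2 genes)")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    universe = set(expr.gene_ids)
    kept: dict[str, tuple[str, ...]] = {}
    n_dropped_genes = 0
    for name, genes in collection.sets.items():
        present = tuple(g for g in genes if g in universe)
        n_dropped_genes += len(genes) - len(present)
        if min_size <= len(present) <= max_size:
            kept[name] = present
    if n_dropped_genes:
        logger.info(
            "size filter: %d gene memberships absent from the expression matrix "
            "were dropped across %d sets",
            n_dropped_genes,
            len(collection),
        )
    if not kept:
        logger.warning(
            "size filter [%d, %d] removed every gene set (of %d)",
            min_size,
            max_size,
            len(collection),
        )
    return GeneSetCollection(kept, source_description=collection.source_description)


def log2p1(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Explicit ``log2(x + 1)`` transform for linear-scale abundances."""
    if (expr.values < -1).any():
        raise ValueError("log2(x+1) undefined for values < -1")
    return ExpressionMatrix(
        expr.gene_ids, expr.sample_ids, np.log2(expr.values + 1.0)
    )
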