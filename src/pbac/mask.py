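"""Gene–pathway mask layer.

The mask matrix ``M`` (pathways × genes) encodes gene-set membership: entry
``M[p, g]`` is 1 iff gene ``g`` belongs to pathway ``p``.  Applying the mask
aggregates gene-level expression into pathway-level features ``Xm = X · Mᵀ``
(per-sample sum over each pathway's member genes), so that genes outside all
pathways have exactly zero influence on everything downstream.

By default genes are z-scored before aggregation so that high-variance genes
and large pathways do not dominate the downstream softmax attention; the
statistics are computed on the training split and frozen for test data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix, PathwayCollection

logger = logging.getLogger("pbac")

__all__ = ["MaskMatrix", "PathwayFeatures", "GeneStandardizer", "build_mask", "apply_mask"]


@dataclass
class MaskMatrix:
    """Binary pathway × gene incidence matrix."""

    pathway_names: list[str]
    gene_ids: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (len(self.pathway_names), len(self.gene_ids)):
            raise ValueError("mask shape does not match pathway/gene lists")
        if not np.isin(self.M, [0.0, 1.0]).all():
            raise ValueError("mask entries must be 0 or 1")
        if (self.M.sum(axis=1) == 0).any():
            empty = [self.pathway_names[i] for i in np.flatnonzero(self.M.sum(axis=1) == 0)]
            raise ValueError(f"pathways with no measured genes: {empty[:5]}")

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_names)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class PathwayFeatures:
    """Pathway-level features: samples × pathways."""

    sample_ids: list[str]
    pathway_names: list[str]
    Xm: np.ndarray

    def __post_init__(self) -> None:
        self.Xm = np.asarray(self.Xm, dtype=float)
        if self.Xm.shape != (len(self.sample_ids), len(self.pathway_names)):
            raise ValueError("feature shape does not match sample/pathway lists")


@dataclass
class GeneStandardizer:
    """Per-gene z-scoring with frozen (training-set) mean/sd.

    Zero-variance genes are mapped to 0 with a warning instead of dividing by
    zero; they carry no information either way.
    """

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "GeneStandardizer":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)  # population sd
        n_const = int((sd == 0).sum())
        if n_const:
            warnings.warn(
                f"{n_const} zero-variance gene(s) set to 0 under standardization",
                stacklevel=2,
            )
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        safe_sd = np.where(self.sd == 0, 1.0, self.sd)
        Z = (X - self.mean) / safe_sd
        Z[:, self.sd == 0] = 0.0
        return Z


def build_mask(collection: PathwayCollection, genes: Sequence[str]) -> MaskMatrix:
    """Build the binary incidence matrix over a measured gene list.

    Row order follows collection order; pathways with no measured gene are
    dropped with a logged warning.  An empty result (no pathway overlaps any
    gene) is an error.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    gene_index = {g: i for i, g in enumerate(genes)}

    rows: list[np.ndarray] = []
    kept: list[str] = []
    dropped: list[str] = []
    for p in collection:
        row = np.zeros(len(genes))
        hit = False
        for g in p.genes:
            j = gene_index.get(g)
            if j is not None:
                row[j] = 1.0
                hit = True
        if hit:
            rows.append(row)
            kept.append(p.name)
        else:
            dropped.append(p.name)
    if dropped:
        logger.warning(
            "dropped %d pathway(s) with no measured genes: %s%s",
            len(dropped),
            dropped[:5],
            "..." if len(dropped) > 5 else "",
        )
    if not kept:
        raise ValueError("no pathway overlaps any measured gene; check gene identifiers")
    return MaskMatrix(kept, genes, np.vstack(rows))


def apply_mask(
    X: ExpressionMatrix,
    mask: MaskMatrix,
    standardize: bool = True,
    standardizer: GeneStandardizer | None = None,
    aggregate: str = "sum",
) -> PathwayFeatures:
    """Aggregate expression into pathway features ``Xm = X · Mᵀ``.

    With ``standardize`` on (default) gene columns are z-scored first; pass a
    pre-fitted ``standardizer`` to reuse training-set statistics on test data.
    ``aggregate`` is ``"sum"`` (plain ``X · Mᵀ``) or ``"mean"`` (divide each
    pathway by its measured-gene count; this is what the network uses so that
    feature scale does not grow with pathway size).
    """
    if X.gene_ids != mask.gene_ids:
        raise ValueError("expression gene order does not match mask column order")
    if aggregate not in ("sum", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    values = X.values
    if standardize:
        if standardizer is None:
            standardizer = GeneStandardizer.fit(values)
        values = standardizer.transform(values)
    Xm = values @ mask.M.T
    if aggregate == "mean":
        Xm = Xm / mask.M.sum(axis=1)
    return PathwayFeatures(list(X.sample_ids), list(mask.pathway_names), Xm)
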