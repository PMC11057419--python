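"""Readers and writers for gene sets, expression matrices, labels and run config.

File formats are deliberately plain: GMT for gene sets (one pathway per
tab-separated line: name, description, member genes), TSV/CSV for expression
matrices and label tables, YAML for run configuration.  Expression values are
assumed already normalised / log-scale; no normalisation happens here.

Gene identifiers are matched as case-sensitive exact strings throughout; on
every expression/collection pairing the intersection size is logged so that a
vocabulary mismatch (e.g. symbols vs Ensembl IDs) is visible immediately.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pbac")

__all__ = [
    "Pathway",
    "PathwayCollection",
    "ExpressionMatrix",
    "ResponseLabels",
    "RunConfig",
    "DEFAULT_MAX_CONC",
    "RECIST_RESPONDER",
    "RECIST_NON_RESPONDER",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
]

#: GDSC maximum screening concentration per drug (IC50 units, micromolar).
#: A cell line with IC50 above the drug's Max Conc is called insensitive.
DEFAULT_MAX_CONC: dict[str, float] = {
    "Bortezomib": 0.02,
    "Cisplatin": 8.00,
    "Docetaxel": 0.125,
    "Paclitaxel": 0.102,
}

#: RECIST-style clinical codes mapped to binary response.
RECIST_RESPONDER = frozenset({"CR", "PR"})
RECIST_NON_RESPONDER = frozenset({"SD", "PD"})


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Pathway:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class PathwayCollection:
    """An ordered collection of named gene sets.

    Order is preserved from the source file and is meaningful downstream: it
    fixes the row order of the mask matrix and hence the spatial axis the
    convolution slides along.
    """

    entries: list[Pathway]

    def __post_init__(self) -> None:
        names = [p.name for p in self.entries]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate pathway names: {dupes}")
        for p in self.entries:
            if not p.genes:
                raise ValueError(f"pathway {p.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, key: int | str) -> Pathway:
        if isinstance(key, str):
            for p in self.entries:
                if p.name == key:
                    return p
            raise KeyError(key)
        return self.entries[key]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.entries]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.entries:
            out |= p.genes
        return frozenset(out)

    def subset(self, names: Iterable[str]) -> "PathwayCollection":
        wanted = set(names)
        return PathwayCollection([p for p in self.entries if p.name in wanted])


@dataclass
class ExpressionMatrix:
    """A samples × genes real matrix with unique sample and gene ids."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite expression value at sample "
                f"{self.sample_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(float))

    def select_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        cols = [idx[g] for g in genes]
        return ExpressionMatrix(list(self.sample_ids), list(genes), self.values[:, cols])

    def select_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in samples]
        return ExpressionMatrix(list(samples), list(self.gene_ids), self.values[rows])


@dataclass
class ResponseLabels:
    """Binary response per sample: 1 = sensitive / responder, 0 = insensitive
    / non-responder.  ``source`` records how the labels were derived."""

    sample_ids: list[str]
    labels: np.ndarray
    source: str = "clinical"  # "ic50_binarized" | "clinical"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels length does not match sample ids")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be strictly binary (0/1)")
        self.labels = self.labels.astype(int)
        if self.source not in ("ic50_binarized", "clinical"):
            raise ValueError(f"unknown label source {self.source!r}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def align_to(self, sample_ids: Sequence[str]) -> "ResponseLabels":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        rows = [idx[s] for s in sample_ids]
        return ResponseLabels(list(sample_ids), self.labels[rows], self.source)


@dataclass
class RunConfig:
    """Run configuration: drug, labeling thresholds, model and training
    hyperparameters, seed, CV fold count and head type."""

    drug: str | None = None
    max_conc: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MAX_CONC))
    latent_dim: int = 16
    conv_channels: int = 4
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    k_folds: int = 5
    head_type: str = "classify"  # "classify" | "regress_ic50"
    expression_orientation: str = "samples_by_genes"  # or "genes_by_samples"

    def __post_init__(self) -> None:
        for drug, thr in self.max_conc.items():
            if thr <= 0:
                raise ValueError(f"Max Conc for {drug!r} must be positive, got {thr}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.head_type not in ("classify", "regress_ic50"):
            raise ValueError(f"unknown head type {self.head_type!r}")
        if self.expression_orientation not in ("samples_by_genes", "genes_by_samples"):
            raise ValueError("orientation must be samples_by_genes or genes_by_samples")

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "max_conc": dict(self.max_conc),
            "latent_dim": self.latent_dim,
            "conv_channels": self.conv_channels,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "seed": self.seed,
            "k_folds": self.k_folds,
            "head_type": self.head_type,
            "expression_orientation": self.expression_orientation,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT file: one pathway per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line collapse to a single membership; a duplicate
    pathway name or a line with fewer than three fields is an error.
    """
    entries: list[Pathway] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            if name in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            seen.add(name)
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            entries.append(Pathway(name, desc, genes))
    return PathwayCollection(entries)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    """Write a collection as GMT.  Genes are sorted within each line so that a
    read→write→read round trip is identity on (name, order, gene set)."""
    with open(path, "w") as fh:
        for p in collection:
            fh.write("\t".join([p.name, p.description, *sorted(p.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression(
    path: str | Path,
    orientation: str = "samples_by_genes",
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table into a samples × genes matrix.

    ``orientation`` declares the file layout (``samples_by_genes``: rows are
    samples; ``genes_by_samples``: rows are genes, as in most GEO series
    matrices).  The orientation is never guessed.  Missing or non-numeric
    cells are an error naming the offending row/column.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):
        raise ParseError(f"{path}: duplicate column ids in header")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate row ids")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna().to_numpy()
    if numeric.isna().any().any():
        mask = numeric.isna().to_numpy() | bad.to_numpy()
        r, c = np.argwhere(mask)[0]
        raise ParseError(
            f"{path}: non-numeric or missing value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if orientation == "genes_by_samples":
        numeric = numeric.T
    elif orientation != "samples_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix.from_frame(numeric)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, sep: str = "\t"
) -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="sample_id")


def log_gene_overlap(matrix: ExpressionMatrix, collection: PathwayCollection) -> int:
    """Log and return the number of genes shared between an expression matrix
    and a pathway collection (case-sensitive exact match)."""
    shared = len(set(matrix.gene_ids) & collection.all_genes())
    logger.info(
        "gene overlap: %d of %d expression genes appear in the %d-pathway collection",
        shared,
        matrix.n_genes,
        len(collection),
    )
    return shared


# ---------------------------------------------------------------------------
# Response labels


def read_labels(
    path: str | Path,
    kind: str = "binary",
    threshold: float | None = None,
    sep: str | None = None,
) -> ResponseLabels:
    """Read a two-column sample_id/value table into binary response labels.

    kind:
      * ``binary`` — values already 0/1;
      * ``recist`` — clinical codes: CR/PR → 1 (responder), SD/PD → 0;
      * ``ic50``   — continuous IC50 values binarised at ``threshold``
        (Max Conc): above threshold → 0 (insensitive), otherwise → 1.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (sample_id, value)")
    if df.empty:
        raise ParseError(f"{path}: label table is empty")
    ids = df.iloc[:, 0].astype(str).tolist()
    vals = df.iloc[:, 1]

    if kind == "binary":
        labels = vals.astype(int).to_numpy()
        source = "clinical"
    elif kind == "recist":
        codes = vals.astype(str).str.strip().str.upper()
        permitted = sorted(RECIST_RESPONDER | RECIST_NON_RESPONDER)
        unknown = sorted(set(codes) - set(permitted))
        if unknown:
            raise ParseError(
                f"{path}: unknown RECIST code(s) {unknown}; permitted: {permitted}"
            )
        labels = codes.isin(RECIST_RESPONDER).astype(int).to_numpy()
        source = "clinical"
    elif kind == "ic50":
        if threshold is None:
            raise ValueError("ic50 labels require a Max Conc threshold")
        ic50 = vals.astype(float).to_numpy()
        labels = (ic50 <= threshold).astype(int)
        source = "ic50_binarized"
    else:
        raise ValueError(f"unknown label kind {kind!r}")
    return ResponseLabels(ids, labels, source)


def write_labels(labels: ResponseLabels, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep=sep, index=False
    )
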