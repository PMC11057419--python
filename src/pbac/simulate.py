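"""Synthetic pathway-structured cohorts with planted driver pathways.

The generator emulates the structure the model assumes in real data: a
response signal carried coherently by the member genes of a few "driver"
pathways.  Background expression is i.i.d. normal noise; pathways are random
gene subsets (overlaps allowed); responder samples have every driver-pathway
member gene shifted down by δ (more sensitive = lower driver expression);
IC50 follows a linear model on mean driver-gene expression plus noise; and
binary labels come from the same Max-Conc rule used for real cell lines, so
labels and IC50 are self-consistent by construction.

Defaults plant 3 drivers of 20 genes among 200 pathways in a 300-sample,
1000-gene cohort at δ = 1 — a signal strength where pathway-aggregated
classification is clearly learnable but single genes are weak predictors.
Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import (
    ExpressionMatrix,
    Pathway,
    PathwayCollection,
    ResponseLabels,
    write_expression,
    write_gmt,
    write_labels,
)

__all__ = ["SynthConfig", "SynthDataset", "generate", "generate_transfer_pair"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    δ (``delta``) is the per-gene downward expression shift applied to driver
    pathway members in responder samples, in the same units as the noise sd.
    The IC50 model couples to driver activity with a strength that scales
    with the planted signal: ``ic50 = base + beta * delta * mean(driver gene
    expression) + N(0, ic50_noise_sd)``.  Responders (shifted down) therefore
    get low IC50 and the Max-Conc rule recovers the planted split up to IC50
    noise, while at δ = 0 the IC50 — hence the labels — is independent of
    expression, a genuine no-signal null.

    ``ic50_base`` defaults to ``max_conc + beta * delta² / 2`` so the
    labeling threshold sits midway between the two class means of the IC50
    distribution at any δ, and the classes stay balanced in the δ = 0 null.
    """

    n_samples: int = 300
    n_genes: int = 1000
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (10, 30)
    n_driver_pathways: int = 3
    driver_pathway_size: int = 20
    delta: float = 1.0
    noise_sd: float = 1.0
    responder_fraction: float = 0.4
    ic50_base: float | None = None  # derived: max_conc + beta*delta^2/2
    ic50_beta: float = 1.0
    ic50_noise_sd: float = 0.2
    max_conc: float = 0.5
    seed: int = 0
    # optional second cohort for across-study transfer tests
    batch_shift: float = 0.3
    panel_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.responder_fraction < 1):
            raise ValueError("responder fraction must be in (0, 1)")
        if self.n_driver_pathways > self.n_pathways:
            raise ValueError("more driver pathways than pathways")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        hi = max(self.pathway_size_range[1], self.driver_pathway_size)
        if hi > self.n_genes:
            raise ValueError("pathway size exceeds gene count")


@dataclass
class SynthDataset:
    expression: ExpressionMatrix
    collection: PathwayCollection
    labels: ResponseLabels
    ic50: np.ndarray
    driver_pathways: list[str]
    responder_truth: np.ndarray  # the planted (pre-IC50-noise) responder flag
    config: SynthConfig = field(repr=False, default=None)

    def write(self, outdir: str | Path, prefix: str = "synth") -> None:
        """Dump expression/labels/IC50 TSVs, the GMT, and a truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression(self.expression, outdir / f"{prefix}_expression.tsv")
        write_labels(self.labels, outdir / f"{prefix}_labels.tsv")
        with open(outdir / f"{prefix}_ic50.tsv", "w") as fh:
            fh.write("sample_id\tic50\n")
            for s, v in zip(self.expression.sample_ids, self.ic50):
                fh.write(f"{s}\t{v:.6g}\n")
        write_gmt(self.collection, outdir / f"{prefix}_pathways.gmt")
        truth = {
            "driver_pathways": self.driver_pathways,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
            },
        }
        (outdir / f"{prefix}_truth.json").write_text(json.dumps(truth, indent=2))


def _make_collection(cfg: SynthConfig, rng: np.random.Generator, genes: list[str]):
    """Random gene subsets; the first n_driver pathways are the drivers and
    have exactly driver_pathway_size genes."""
    lo, hi = cfg.pathway_size_range
    entries = []
    for i in range(cfg.n_pathways):
        if i < cfg.n_driver_pathways:
            size = cfg.driver_pathway_size
            name = f"DRIVER_{i:03d}"
        else:
            size = int(rng.integers(lo, hi + 1))
            name = f"PW_{i:04d}"
        members = rng.choice(cfg.n_genes, size=size, replace=False)
        entries.append(Pathway(name, "synthetic", frozenset(genes[j] for j in members)))
    return PathwayCollection(entries)


def generate(cfg: SynthConfig | None = None, seed: int | None = None) -> SynthDataset:
    """Draw one cohort.  ``seed`` overrides ``cfg.seed`` when given."""
    cfg = cfg or SynthConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    collection = _make_collection(cfg, rng, genes)
    drivers = collection.names[: cfg.n_driver_pathways]

    gene_index = {g: i for i, g in enumerate(genes)}
    driver_gene_idx = sorted(
        {gene_index[g] for name in drivers for g in collection[name].genes}
    )

    X = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_samples, cfg.n_genes))
    n_resp = int(round(cfg.responder_fraction * cfg.n_samples))
    responder = np.zeros(cfg.n_samples, bool)
    responder[rng.choice(cfg.n_samples, size=n_resp, replace=False)] = True
    # responders: coherent downward shift on every driver-pathway member gene
    X[np.ix_(responder, driver_gene_idx)] -= cfg.delta

    driver_activity = X[:, driver_gene_idx].mean(axis=1)
    coupling = cfg.ic50_beta * cfg.delta
    base = (
        cfg.ic50_base
        if cfg.ic50_base is not None
        else cfg.max_conc + cfg.ic50_beta * cfg.delta**2 / 2
    )
    ic50 = (
        base
        + coupling * driver_activity
        + rng.normal(0.0, cfg.ic50_noise_sd, size=cfg.n_samples)
    )
    labels = ResponseLabels(
        samples, (ic50 <= cfg.max_conc).astype(int), source="ic50_binarized"
    )
    return SynthDataset(
        expression=ExpressionMatrix(samples, genes, X),
        collection=collection,
        labels=labels,
        ic50=ic50,
        driver_pathways=drivers,
        responder_truth=responder.astype(int),
        config=cfg,
    )


def generate_transfer_pair(
    cfg: SynthConfig | None = None, seed: int | None = None
) -> tuple[SynthDataset, SynthDataset]:
    """Two cohorts sharing the pathway collection and driver identities but
    differing by an additive batch offset and a reduced gene panel in the
    second cohort — a stand-in for cell-line → clinical transfer."""
    cfg = cfg or SynthConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    first = generate(cfg)
    # second cohort: same collection and driver identities, fresh samples
    rng = np.random.default_rng(cfg.seed + 1)
    genes = first.expression.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    driver_gene_idx = sorted(
        {gene_index[g] for name in first.driver_pathways for g in first.collection[name].genes}
    )
    rng2 = np.random.default_rng((cfg.seed + 500_009) % 2**31)
    X2 = rng2.normal(0.0, cfg.noise_sd, size=(cfg.n_samples, cfg.n_genes))
    n_resp = int(round(cfg.responder_fraction * cfg.n_samples))
    responder = np.zeros(cfg.n_samples, bool)
    responder[rng2.choice(cfg.n_samples, size=n_resp, replace=False)] = True
    X2[np.ix_(responder, driver_gene_idx)] -= cfg.delta
    activity = X2[:, driver_gene_idx].mean(axis=1)
    coupling = cfg.ic50_beta * cfg.delta
    base = (
        cfg.ic50_base
        if cfg.ic50_base is not None
        else cfg.max_conc + cfg.ic50_beta * cfg.delta**2 / 2
    )
    ic50_2 = (
        base
        + coupling * activity
        + rng2.normal(0.0, cfg.ic50_noise_sd, size=cfg.n_samples)
    )
    X2 = X2 + cfg.batch_shift  # global additive batch effect
    samples2 = [f"T{i:04d}" for i in range(cfg.n_samples)]
    # reduced gene panel in the second cohort
    n_keep = int(round(cfg.panel_fraction * cfg.n_genes))
    keep = np.sort(rng.choice(cfg.n_genes, size=n_keep, replace=False))
    expr2 = ExpressionMatrix(samples2, [genes[j] for j in keep], X2[:, keep])
    labels2 = ResponseLabels(
        samples2, (ic50_2 <= cfg.max_conc).astype(int), source="ic50_binarized"
    )
    second = SynthDataset(
        expression=expr2,
        collection=first.collection,
        labels=labels2,
        ic50=ic50_2,
        driver_pathways=first.driver_pathways,
        responder_truth=responder.astype(int),
        config=replace(cfg, seed=(cfg.seed + 500_009) % 2**31),
    )
    return first, second
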