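"""Attention-based pathway importance.

A fitted model's attention weights form a samples × pathways matrix whose
rows are probability vectors.  Pathway importance is the mean attention
weight over all evaluated samples; pathways are ranked by that mean in
descending order with ties broken alphabetically by name.  Group-specific
means (responders vs non-responders) are emitted when labels are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ResponseLabels
from .network import PBACModel

__all__ = ["PathwayRanking", "extract_attention", "rank_pathways"]


@dataclass
class PathwayRanking:
    """Full descending ranking of pathways by mean attention, with a top-k
    view.  Ranks run 1..P; ties share mean but not rank (name order)."""

    table: pd.DataFrame  # columns: pathway, mean_attention, rank (+ groups)
    top_k: int

    @property
    def top(self) -> pd.DataFrame:
        return self.table.head(self.top_k)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def extract_attention(model: PBACModel, X: ExpressionMatrix) -> pd.DataFrame:
    """Run the model and return its attention weights as a samples × pathways
    DataFrame (each row sums to 1)."""
    if model.ablation == "no_attention":
        raise ValueError(
            "the no_attention variant has uniform 1/P weights by construction; "
            "attention extraction is meaningless for it"
        )
    _, att = model.forward(X)
    return pd.DataFrame(att.Wa, index=X.sample_ids, columns=model.mask.pathway_names)


def rank_pathways(
    attention: pd.DataFrame,
    top_k: int = 10,
    labels: ResponseLabels | None = None,
) -> PathwayRanking:
    """Rank pathways by mean attention across samples (descending; ties by
    pathway name).  ``top_k`` larger than the pathway count is clipped with a
    warning.  With ``labels``, per-group mean columns are added."""
    if attention.empty:
        raise ValueError("attention matrix is empty")
    P = attention.shape[1]
    if top_k > P:
        warnings.warn(f"top_k={top_k} clipped to {P} pathways", stacklevel=2)
        top_k = P
    means = attention.mean(axis=0)
    table = pd.DataFrame({"pathway": means.index, "mean_attention": means.to_numpy()})
    if labels is not None:
        aligned = labels.align_to(list(attention.index))
        y = aligned.labels
        table["mean_attention_responder"] = attention[y == 1].mean(axis=0).to_numpy()
        table["mean_attention_non_responder"] = attention[y == 0].mean(axis=0).to_numpy()
    table = table.sort_values(
        ["mean_attention", "pathway"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return PathwayRanking(table=table, top_k=top_k)
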