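"""The PBAC network.

Four stages, applied per sample to gene expression x (length n, z-scored):

1. gene–pathway mask:  Xm = x · Mᵀ / |pathway|  (mean over member genes,
                                                 pathway features, length P)
2. attention:          Wa = softmax(W2ᵀ · tanh(W1ᵀ · Xm)),  Xa = Xm ⊙ Wa
3. 1-D convolution:    Xc = Conv(Xa)          (C channels, kernel 3, stride 1,
                                               zero padding 1 → length P kept)
4. dense head:         Y  = softmax(Wf · vec(Xc) + b)   (classification)
                       ŷ  = Wf · vec(Xc) + b            (IC50 regression)

The attention weights are a per-sample probability vector over pathways
(each row sums to 1); they double as the model's interpretability output.

Two ablation variants are supported: ``no_mask`` replaces the fixed binary
mask with a learned dense layer of the same output shape, and
``no_attention`` freezes the attention weights at the uniform 1/P.

Everything is plain NumPy; gradients are derived by hand and checked against
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import ExpressionMatrix
from .mask import GeneStandardizer, MaskMatrix, PathwayFeatures

__all__ = [
    "AttentionParams",
    "AttentionOutput",
    "ConvParams",
    "HeadParams",
    "PBACModel",
    "attention_forward",
    "conv_forward",
    "head_forward",
    "make_variant",
    "softmax",
]

ABLATIONS = ("none", "no_mask", "no_attention")
HEAD_TYPES = ("classify", "regress_ic50")


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class AttentionParams:
    """W1 projects pathway features to an H-dim latent space; W2 maps the
    tanh-activated latent back to one score per pathway."""

    W1: np.ndarray  # P x H
    W2: np.ndarray  # H x P

    def __post_init__(self) -> None:
        if self.W1.shape[1] != self.W2.shape[0] or self.W1.shape[0] != self.W2.shape[1]:
            raise ValueError(
                f"inconsistent attention shapes {self.W1.shape} / {self.W2.shape}"
            )

    @property
    def n_pathways(self) -> int:
        return self.W1.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.W1.shape[1]


@dataclass
class AttentionOutput:
    Wa: np.ndarray  # samples x P, rows sum to 1
    Xa: np.ndarray  # samples x P


@dataclass
class ConvParams:
    """C width-3 filters over the pathway axis, stride 1, zero padding 1, so
    the output length equals P for every filter."""

    kernels: np.ndarray  # C x 3
    bias: np.ndarray  # C

    def __post_init__(self) -> None:
        if self.kernels.ndim != 2 or self.kernels.shape[1] != 3:
            raise ValueError(f"kernels must be C x 3, got {self.kernels.shape}")
        if self.bias.shape != (self.kernels.shape[0],):
            raise ValueError("bias length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.kernels.shape[0]


@dataclass
class HeadParams:
    Wf: np.ndarray  # (C*P) x K
    b: np.ndarray  # K

    def __post_init__(self) -> None:
        if self.b.shape != (self.Wf.shape[1],):
            raise ValueError("head bias length must match output dim")


# ---------------------------------------------------------------------------
# Stage-wise forward operations (functional surface)


def attention_forward(Xm: PathwayFeatures | np.ndarray, params: AttentionParams) -> AttentionOutput:
    """Per-sample pathway attention: Wa = softmax(W2ᵀ·tanh(W1ᵀ·x)), Xa = x ⊙ Wa."""
    x = Xm.Xm if isinstance(Xm, PathwayFeatures) else np.asarray(Xm, float)
    if x.ndim == 1:
        x = x[None, :]
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in pathway features")
    if x.shape[1] != params.n_pathways:
        raise ValueError(
            f"feature dim {x.shape[1]} does not match attention P={params.n_pathways}"
        )
    T = np.tanh(x @ params.W1)  # B x H
    S = T @ params.W2  # B x P
    Wa = softmax(S, axis=1)
    return AttentionOutput(Wa=Wa, Xa=x * Wa)


def conv_forward(Xa: AttentionOutput | np.ndarray, params: ConvParams) -> np.ndarray:
    """Width-3 cross-correlation with zero padding 1, stride 1 along the
    pathway axis; single input channel, C output channels.  Returns B×C×P."""
    x = Xa.Xa if isinstance(Xa, AttentionOutput) else np.asarray(Xa, float)
    if x.ndim == 1:
        x = x[None, :]
    P = x.shape[1]
    if P < 1:
        raise ValueError("need at least one pathway position")
    xp = np.pad(x, ((0, 0), (1, 1)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, 3, axis=1)  # B x P x 3
    return np.einsum("bpj,cj->bcp", windows, params.kernels) + params.bias[None, :, None]


def head_forward(Xc: np.ndarray, params: HeadParams, head_type: str = "classify") -> np.ndarray:
    """Flatten conv features channel-major and apply the dense head.

    ``classify`` → rows of class probabilities (softmax over K=2);
    ``regress_ic50`` → one real predicted IC50 per sample (no softmax).
    """
    if head_type not in HEAD_TYPES:
        raise ValueError(f"unknown head type {head_type!r}")
    Z = np.asarray(Xc, float)
    if Z.ndim == 3:
        Z = Z.reshape(Z.shape[0], -1)  # channel-major: index c*P + p
    if Z.shape[1] != params.Wf.shape[0]:
        raise ValueError(
            f"flattened dim {Z.shape[1]} does not match head input {params.Wf.shape[0]}"
        )
    logits = Z @ params.Wf + params.b
    if head_type == "classify":
        return softmax(logits, axis=1)
    return logits[:, 0]


# ---------------------------------------------------------------------------
# The assembled model


@dataclass
class PBACModel:
    """All four stages plus ablation flag, head type and frozen gene
    standardization.  ``params`` maps names to arrays; the trainable subset
    depends on the ablation variant (the binary mask itself is never
    trained, and ``no_attention`` has no attention parameters at all)."""

    mask: MaskMatrix
    params: dict[str, np.ndarray]
    latent_dim: int
    conv_channels: int
    ablation: str = "none"
    head_type: str = "classify"
    standardizer: GeneStandardizer | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; expected {ABLATIONS}")
        if self.head_type not in HEAD_TYPES:
            raise ValueError(f"unknown head type {self.head_type!r}")

    # -- construction ------------------------------------------------------

    @classmethod
    def init(
        cls,
        mask: MaskMatrix,
        latent_dim: int = 16,
        conv_channels: int = 4,
        ablation: str = "none",
        head_type: str = "classify",
        seed: int = 0,
    ) -> "PBACModel":
        """Initialise parameters with uniform fan-in scaling U(-1/√fan, 1/√fan)
        from a recorded seed; biases start at zero."""
        if ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {ablation!r}; expected {ABLATIONS}")
        rng = np.random.default_rng(seed)
        P, n = mask.n_pathways, mask.n_genes
        H, C = latent_dim, conv_channels
        K = 2 if head_type == "classify" else 1

        def unif(fan_in: int, *shape: int) -> np.ndarray:
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        params: dict[str, np.ndarray] = {}
        if ablation == "no_mask":
            params["Wd"] = unif(n, n, P)
            params["bd"] = np.zeros(P)
        if ablation != "no_attention":
            params["W1"] = unif(P, P, H)
            params["W2"] = unif(H, H, P)
        params["Wk"] = unif(3, C, 3)
        params["bk"] = np.zeros(C)
        params["Wf"] = unif(C * P, C * P, K)
        params["bf"] = np.zeros(K)
        return cls(
            mask=mask,
            params=params,
            latent_dim=H,
            conv_channels=C,
            ablation=ablation,
            head_type=head_type,
            seed=seed,
        )

    # -- convenience views -------------------------------------------------

    @property
    def n_pathways(self) -> int:
        return self.mask.n_pathways

    @property
    def attention(self) -> AttentionParams:
        if self.ablation == "no_attention":
            raise ValueError("no_attention variant has no attention parameters")
        return AttentionParams(self.params["W1"], self.params["W2"])

    @property
    def conv(self) -> ConvParams:
        return ConvParams(self.params["Wk"], self.params["bk"])

    @property
    def head(self) -> HeadParams:
        return HeadParams(self.params["Wf"], self.params["bf"])

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward -----------------------------------------------------------

    def _standardized(self, X: ExpressionMatrix | np.ndarray) -> np.ndarray:
        if isinstance(X, ExpressionMatrix):
            if X.gene_ids != self.mask.gene_ids:
                raise ValueError("expression gene order does not match model mask")
            values = X.values
        else:
            values = np.asarray(X, float)
            if values.ndim == 1:
                values = values[None, :]
            if values.shape[1] != self.mask.n_genes:
                raise ValueError("gene dimension does not match model mask")
        if self.standardizer is not None:
            values = self.standardizer.transform(values)
        return values

    def forward(
        self, X: ExpressionMatrix | np.ndarray
    ) -> tuple[np.ndarray, AttentionOutput]:
        """Full forward pass; returns (predictions, attention output).

        Predictions are class-probability rows for the classification head or
        a real IC50 per sample for the regression head.  Attention weights
        come back alongside for interpretability (uniform 1/P under the
        ``no_attention`` ablation).
        """
        preds, _, att = self._forward_cached(self._standardized(X))
        return preds, att

    def predict_scores(self, X: ExpressionMatrix | np.ndarray) -> np.ndarray:
        """Scalar decision score per sample: P(sensitive) for classification,
        negated predicted IC50 for regression (higher = more sensitive)."""
        preds, _ = self.forward(X)
        if self.head_type == "classify":
            return preds[:, 1]
        return -preds

    def _forward_cached(self, Xz: np.ndarray):
        """Forward pass keeping every intermediate needed for backprop."""
        p = self.params
        cache: dict[str, np.ndarray] = {"Xz": Xz}
        if self.ablation == "no_mask":
            Xm = Xz @ p["Wd"] + p["bd"]
        else:
            # mean over member genes: sums grow with pathway size and drive
            # the tanh scorer into saturation; means keep it conditioned
            Xm = (Xz @ self.mask.M.T) / self.mask.M.sum(axis=1)
        cache["Xm"] = Xm
        P = Xm.shape[1]

        if self.ablation == "no_attention":
            Wa = np.full_like(Xm, 1.0 / P)
            Xa = Xm / P
        else:
            if not np.isfinite(Xm).all():
                raise ValueError("non-finite values in pathway features")
            T = np.tanh(Xm @ p["W1"])
            Wa = softmax(T @ p["W2"], axis=1)
            Xa = Xm * Wa
            cache["T"] = T
        cache["Wa"], cache["Xa"] = Wa, Xa

        xp = np.pad(Xa, ((0, 0), (1, 1)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, 3, axis=1)
        Xc = np.einsum("bpj,cj->bcp", windows, p["Wk"]) + p["bk"][None, :, None]
        cache["windows"] = windows
        Z = Xc.reshape(Xc.shape[0], -1)
        cache["Z"] = Z
        logits = Z @ p["Wf"] + p["bf"]
        cache["logits"] = logits

        if self.head_type == "classify":
            preds = softmax(logits, axis=1)
        else:
            preds = logits[:, 0]
        return preds, cache, AttentionOutput(Wa=Wa, Xa=Xa)

    # -- backward ----------------------------------------------------------

    def _backward(
        self,
        cache: Mapping[str, np.ndarray],
        dlogits: np.ndarray,
        attn_entropy: float = 0.0,
    ) -> dict[str, np.ndarray]:
        """Backpropagate a gradient w.r.t. the head logits through all stages;
        returns gradients keyed like ``params``.

        ``attn_entropy`` adds the gradient of an entropy bonus on the
        attention distribution (−λ·mean H(Wa)).  With several pathways
        carrying redundant signal, an unregularised softmax tends to collapse
        onto one of them; the bonus keeps the distribution spread so that all
        informative pathways retain weight in the importance ranking."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        Z, windows = cache["Z"], cache["windows"]
        B, P = cache["Xa"].shape
        C = self.conv_channels

        grads["Wf"] = Z.T @ dlogits
        grads["bf"] = dlogits.sum(axis=0)
        dZ = dlogits @ p["Wf"].T
        dXc = dZ.reshape(B, C, P)

        grads["Wk"] = np.einsum("bcp,bpj->cj", dXc, windows)
        grads["bk"] = dXc.sum(axis=(0, 2))
        taps = np.einsum("bcp,cj->bpj", dXc, p["Wk"])
        dxp = np.zeros((B, P + 2))
        for j in range(3):
            dxp[:, j : j + P] += taps[:, :, j]
        dXa = dxp[:, 1 : 1 + P]

        Xm, Wa = cache["Xm"], cache["Wa"]
        if self.ablation == "no_attention":
            dXm = dXa / P
        else:
            T = cache["T"]
            dXm = dXa * Wa
            dWa = dXa * Xm
            dS = Wa * (dWa - (dWa * Wa).sum(axis=1, keepdims=True))
            if attn_entropy:
                logW = np.log(np.maximum(Wa, 1e-300))
                H = -(Wa * logW).sum(axis=1, keepdims=True)
                dS = dS + (attn_entropy / Wa.shape[0]) * Wa * (logW + H)
            grads["W2"] = T.T @ dS
            dT = dS @ p["W2"].T
            dA = dT * (1.0 - T**2)
            grads["W1"] = cache["Xm"].T @ dA
            dXm = dXm + dA @ p["W1"].T

        if self.ablation == "no_mask":
            grads["Wd"] = cache["Xz"].T @ dXm
            grads["bd"] = dXm.sum(axis=0)
        return grads

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize parameters (npz) next to a JSON sidecar with config,
        mask provenance and seed."""
        path = Path(path)
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        arrays["mask_M"] = self.mask.M
        if self.standardizer is not None:
            arrays["std_mean"] = self.standardizer.mean
            arrays["std_sd"] = self.standardizer.sd
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "pathway_names": self.mask.pathway_names,
            "gene_ids": self.mask.gene_ids,
            "latent_dim": self.latent_dim,
            "conv_channels": self.conv_channels,
            "ablation": self.ablation,
            "head_type": self.head_type,
            "seed": self.seed,
            **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "PBACModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arrays = np.load(path.with_suffix(".npz"))
        mask = MaskMatrix(meta["pathway_names"], meta["gene_ids"], arrays["mask_M"])
        params = {
            k[len("param_") :]: arrays[k] for k in arrays.files if k.startswith("param_")
        }
        std = None
        if "std_mean" in arrays.files:
            std = GeneStandardizer(mean=arrays["std_mean"], sd=arrays["std_sd"])
        return cls(
            mask=mask,
            params=params,
            latent_dim=meta["latent_dim"],
            conv_channels=meta["conv_channels"],
            ablation=meta["ablation"],
            head_type=meta["head_type"],
            standardizer=std,
            seed=meta["seed"],
        )


def make_variant(
    mask: MaskMatrix,
    which: str = "none",
    latent_dim: int = 16,
    conv_channels: int = 4,
    head_type: str = "classify",
    seed: int = 0,
) -> PBACModel:
    """Build the full model or one of the two ablation variants.

    ``no_mask`` swaps the fixed binary mask for a learned dense genes→P layer
    of identical output shape; ``no_attention`` fixes the attention weights at
    the uniform 1/P (non-learnable, no W1/W2 parameters).
    """
    return PBACModel.init(
        mask,
        latent_dim=latent_dim,
        conv_channels=conv_channels,
        ablation=which,
        head_type=head_type,
        seed=seed,
    )
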