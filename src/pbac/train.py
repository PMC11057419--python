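"""Labeling rules, training, cross-validation and across-study evaluation.

Cell-line response labels come from the GDSC Max Conc rule: a cell line whose
IC50 exceeds the drug's maximum screening concentration is insensitive (0),
otherwise sensitive (1) — equality counts as sensitive.  Clinical labels are
handled upstream (see ``pbac.io.read_labels``).

Training is full-batch-shuffled mini-batch Adam on either class-weighted
cross-entropy (classification head) or squared error (IC50 regression head).
Gene standardization statistics are fitted on the training split only and
frozen into the model, so held-out data never leaks into them.  Within-study
evaluation is stratified k-fold CV (k = 5 by default); across-study
evaluation trains on one cohort and tests once on another, after restricting
both to their shared gene panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix, PathwayCollection, ResponseLabels
from .mask import GeneStandardizer, build_mask
from .metrics import EvaluationReport, UndefinedMetricError, auprc, auroc
from .network import PBACModel, make_variant

logger = logging.getLogger("pbac")

__all__ = [
    "TrainingConfig",
    "FoldPlan",
    "label_cell_lines",
    "make_folds",
    "train",
    "cross_validate",
    "across_study",
]


@dataclass
class TrainingConfig:
    """Optimiser settings.  Defaults: Adam, lr 1e-3, batch 32, 100 epochs,
    inverse-frequency class weighting on, early stopping off.

    ``attention_entropy`` is the coefficient of an entropy bonus on the
    attention distribution; it counters winner-take-all collapse when several
    pathways carry redundant signal, so the importance ranking reflects all
    of them.  Set 0 to disable."""

    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    loss: str = "auto"  # "cross_entropy" | "squared_error" | "auto" (per head)
    seed: int = 0
    early_stopping_patience: int | None = None  # epochs on a 10% val split
    class_weighting: bool = True
    attention_entropy: float = 1.0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.loss not in ("auto", "cross_entropy", "squared_error"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def for_head(self, head_type: str) -> "TrainingConfig":
        """Resolve ``auto`` to the head's loss; an explicit mismatch is an error."""
        wanted = "cross_entropy" if head_type == "classify" else "squared_error"
        if self.loss == "auto":
            return replace(self, loss=wanted)
        if self.loss != wanted:
            raise ValueError(
                f"loss {self.loss!r} does not match head type {head_type!r} "
                f"(expected {wanted!r})"
            )
        return self


@dataclass
class FoldPlan:
    """A stratified k-fold partition: every sample tests exactly once and
    per-fold class ratios stay within one sample of the global ratio."""

    k: int
    train_ids: list[list[str]]
    test_ids: list[list[str]]
    seed: int

    def __post_init__(self) -> None:
        tested = [s for fold in self.test_ids for s in fold]
        if len(tested) != len(set(tested)):
            raise ValueError("a sample appears in more than one test fold")


def label_cell_lines(
    ic50: dict[str, float] | tuple[list[str], np.ndarray],
    drug: str,
    thresholds: dict[str, float],
) -> ResponseLabels:
    """Binarise per-cell-line IC50 against the drug's Max Conc.

    IC50 > Max Conc → insensitive (0); IC50 ≤ Max Conc → sensitive (1).
    Non-positive IC50s are biologically suspect and draw a warning but are
    labelled by the same rule.
    """
    if drug not in thresholds:
        raise KeyError(f"unknown drug {drug!r}; known: {sorted(thresholds)}")
    if isinstance(ic50, dict):
        ids = list(ic50.keys())
        values = np.array([ic50[s] for s in ids], float)
    else:
        ids, values = list(ic50[0]), np.asarray(ic50[1], float)
    if (values <= 0).any():
        warnings.warn(
            f"{int((values <= 0).sum())} non-positive IC50 value(s); labelled normally",
            stacklevel=2,
        )
    labels = (values <= thresholds[drug]).astype(int)
    return ResponseLabels(ids, labels, source="ic50_binarized")


def make_folds(labels: ResponseLabels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold partition, deterministic under the seed."""
    y = labels.labels
    if y.min() == y.max():
        raise ValueError("cannot stratify: only one class present")
    minority = min(labels.n_pos, labels.n_neg)
    if k > minority:
        raise ValueError(f"k={k} exceeds minority-class count {minority}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    ids = np.asarray(labels.sample_ids)
    train_ids, test_ids = [], []
    for tr, te in skf.split(ids, y):
        train_ids.append(ids[tr].tolist())
        test_ids.append(ids[te].tolist())
    return FoldPlan(k=k, train_ids=train_ids, test_ids=test_ids, seed=seed)


# ---------------------------------------------------------------------------
# Loss + optimiser


def _loss_and_dlogits(model: PBACModel, cache, y, sample_w):
    logits = cache["logits"]
    B = logits.shape[0]
    if model.head_type == "classify":
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        probs = np.exp(logp)
        wsum = sample_w.sum()
        loss = float(-(sample_w * logp[np.arange(B), y]).sum() / wsum)
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), y] = 1.0
        dlogits = (probs - onehot) * (sample_w / wsum)[:, None]
    else:
        pred = logits[:, 0]
        resid = pred - y
        loss = float((resid**2).mean())
        dlogits = (2.0 * resid / B)[:, None]
    return loss, dlogits


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def train(
    model: PBACModel,
    X: ExpressionMatrix,
    targets: ResponseLabels | np.ndarray,
    cfg: TrainingConfig | None = None,
    standardize: bool = True,
) -> tuple[PBACModel, list[float]]:
    """Fit the model in place and return it with the per-epoch loss history.

    ``targets`` is a ResponseLabels for the classification head or a vector
    of continuous IC50 values for the regression head.  Deterministic under
    ``cfg.seed``: identical seed and data give bit-identical parameters.
    """
    cfg = (cfg or TrainingConfig()).for_head(model.head_type)
    if isinstance(targets, ResponseLabels):
        targets = targets.align_to(X.sample_ids)
        y = targets.labels.astype(int)
    else:
        y = np.asarray(targets, float)
        if y.shape != (X.n_samples,):
            raise ValueError("target length does not match sample count")
    if standardize and model.standardizer is None:
        model.standardizer = GeneStandardizer.fit(X.values)
    Xz = model._standardized(X)
    n = Xz.shape[0]

    if model.head_type == "classify" and cfg.class_weighting:
        counts = np.bincount(y.astype(int), minlength=2)
        class_w = n / (2.0 * np.maximum(counts, 1))
        sample_w_all = class_w[y.astype(int)]
    else:
        sample_w_all = np.ones(n)

    rng = np.random.default_rng(cfg.seed)

    # optional early stopping on a held-out 10% validation slice
    val_idx = np.array([], int)
    tr_idx = np.arange(n)
    if cfg.early_stopping_patience is not None and n >= 10:
        perm = rng.permutation(n)
        n_val = max(1, n // 10)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

    opt = _Adam(model.params, cfg.learning_rate)
    history: list[float] = []
    best_val, best_params, stale = np.inf, None, 0

    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(tr_idx))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = tr_idx[order[start : start + cfg.batch_size]]
            _, cache, _ = model._forward_cached(Xz[idx])
            loss, dlogits = _loss_and_dlogits(model, cache, y[idx], sample_w_all[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}; "
                    "try a lower learning rate"
                )
            grads = model._backward(cache, dlogits, attn_entropy=cfg.attention_entropy)
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))

        if len(val_idx):
            _, vcache, _ = model._forward_cached(Xz[val_idx])
            vloss, _ = _loss_and_dlogits(model, vcache, y[val_idx], sample_w_all[val_idx])
            if vloss < best_val - 1e-9:
                best_val, stale = vloss, 0
                best_params = {k: v.copy() for k, v in model.params.items()}
            else:
                stale += 1
                if stale >= cfg.early_stopping_patience:
                    break
    if best_params is not None:
        model.params = best_params
    return model, history


# ---------------------------------------------------------------------------
# Evaluation protocols


def _evaluate(model: PBACModel, X: ExpressionMatrix, labels: ResponseLabels, meta=None):
    labels = labels.align_to(X.sample_ids)
    scores = model.predict_scores(X)
    try:
        a = auroc(scores, labels.labels)
        p = auprc(scores, labels.labels)
    except UndefinedMetricError:
        a = p = None
    return EvaluationReport(
        auroc=a, auprc=p, n_pos=labels.n_pos, n_neg=labels.n_neg, meta=meta or {}
    )


def cross_validate(
    X: ExpressionMatrix,
    labels: ResponseLabels,
    collection: PathwayCollection,
    cfg: TrainingConfig | None = None,
    k: int = 5,
    seed: int = 0,
    ablation: str = "none",
    latent_dim: int = 16,
    conv_channels: int = 4,
) -> EvaluationReport:
    """Within-study stratified k-fold CV.  The mask is built once on the
    matrix's gene panel; per fold, a fresh model is trained on the training
    split (standardization refitted there) and scored on the held-out split.
    The summary AUROC/AUPRC are arithmetic means over defined folds; a fold
    whose test split degenerates to one class is recorded as missing and
    excluded from the mean with a warning.
    """
    cfg = cfg or TrainingConfig(seed=seed)
    labels = labels.align_to(X.sample_ids)
    plan = make_folds(labels, k=k, seed=seed)
    mask = build_mask(collection, X.gene_ids)

    fold_reports: list[EvaluationReport] = []
    for i, (tr_ids, te_ids) in enumerate(zip(plan.train_ids, plan.test_ids)):
        model = make_variant(
            mask,
            which=ablation,
            latent_dim=latent_dim,
            conv_channels=conv_channels,
            seed=seed + i,
        )
        Xtr = X.select_samples(tr_ids)
        model, _ = train(model, Xtr, labels.align_to(tr_ids), replace(cfg, seed=seed + i))
        rep = _evaluate(model, X.select_samples(te_ids), labels.align_to(te_ids), {"fold": i})
        if rep.auroc is None:
            warnings.warn(f"fold {i} has a single test class; excluded from mean", stacklevel=2)
        fold_reports.append(rep)

    defined = [r for r in fold_reports if r.auroc is not None]
    mean_auroc = float(np.mean([r.auroc for r in defined])) if defined else None
    mean_auprc = float(np.mean([r.auprc for r in defined])) if defined else None
    return EvaluationReport(
        auroc=mean_auroc,
        auprc=mean_auprc,
        n_pos=labels.n_pos,
        n_neg=labels.n_neg,
        folds=fold_reports,
        meta={"k": k, "seed": seed, "ablation": ablation},
    )


def across_study(
    X_train: ExpressionMatrix,
    y_train: ResponseLabels,
    X_test: ExpressionMatrix,
    y_test: ResponseLabels,
    collection: PathwayCollection,
    cfg: TrainingConfig | None = None,
    seed: int = 0,
    ablation: str = "none",
    latent_dim: int = 16,
    conv_channels: int = 4,
) -> tuple[EvaluationReport, PBACModel]:
    """Train on one cohort, test once on another.

    Both cohorts are restricted to their shared gene panel (intersection, no
    imputation; training-cohort gene order), the mask is rebuilt on it, and
    standardization statistics from the training cohort are frozen for test
    data.
    """
    shared = [g for g in X_train.gene_ids if g in set(X_test.gene_ids)]
    if not shared:
        raise ValueError("empty gene intersection between cohorts")
    logger.info("across-study gene intersection: %d genes", len(shared))
    Xtr = X_train.select_genes(shared)
    Xte = X_test.select_genes(shared)
    mask = build_mask(collection, shared)
    model = make_variant(
        mask,
        which=ablation,
        latent_dim=latent_dim,
        conv_channels=conv_channels,
        seed=seed,
    )
    cfg = cfg or TrainingConfig(seed=seed)
    model, _ = train(model, Xtr, y_train, replace(cfg, seed=seed))
    report = _evaluate(model, Xte, y_test, {"protocol": "across_study", "seed": seed})
    return report, model
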