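"""End-to-end harness: fusion, losses, LOSO evaluation, model accounting.

Binds the four modules together.  Session embeddings come from the frozen
spatial and heart-rate encoders; the temporal classifier (with optional
latent augmentations) is trained per LOSO fold.  The multimodal fusion is
an elementwise addition of the video embedding VD and the bicubic-expanded
heart-rate embedding B_h — the expansion exists precisely so the lengths
match.

The multi-task loss implements the homoscedastic-uncertainty form
``total = sum_i exp(-w_i) * L_i + w_i`` with learned per-task weights w_i;
its stationary point for a fixed task loss L is w* = ln L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from . import nn
from .augment import AugmNet, AugmNetConfig
from .ecg import ECGSignal, hr_per_second
from .estimators import TemporalPainClassifier
from .hr_encoder import HeartRateEncoder, HREncoderConfig, bicubic_expand
from .spatial import SpatialConfig, SpatialEncoder, video_forward
from .synthetic import LABELS, SyntheticSession
from .temporal import TemporalConfig, TemporalNet

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "ModelSummary",
    "fuse_embeddings",
    "multitask_loss",
    "loso_splits",
    "embed_session",
    "embed_sessions",
    "fit",
    "evaluate",
    "model_summary",
    "BINARY_LABELS",
]

BINARY_LABELS = ("NP", "P4")


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe (AdamW, cosine decay with warmup)."""

    lr: float = 1e-4
    weight_decay: float = 0.1
    warmup_epochs: int = 50
    batch_size: int = 32
    epochs: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.warmup_epochs >= self.epochs:
            raise ValueError("warmup_epochs must be smaller than epochs")


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    per_fold_accuracy: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "confusion": self.confusion.tolist(),
                "per_fold_accuracy": self.per_fold_accuracy}


# ---------------------------------------------------------------------------
# Fusion & losses
# ---------------------------------------------------------------------------

def fuse_embeddings(vd, bh) -> np.ndarray:
    """Elementwise sum of the video and expanded heart-rate embeddings."""
    vd = np.asarray(getattr(vd, "VD", vd), dtype=np.float64)
    bh = np.asarray(getattr(bh, "B_h", bh), dtype=np.float64)
    if vd.shape != bh.shape:
        raise ValueError(f"embedding lengths differ: {vd.shape} vs {bh.shape}")
    return vd + bh


def multitask_loss(losses, weights):
    """Homoscedastic multi-task total: sum_i exp(-w_i)*L_i + w_i.

    Accepts numpy arrays (returns a float) or autodiff tensors (returns a
    scalar tensor differentiable in the weights).
    """
    if isinstance(losses, nn.Tensor) or isinstance(weights, nn.Tensor):
        L = losses if isinstance(losses, nn.Tensor) else nn.Tensor(losses)
        w = weights if isinstance(weights, nn.Tensor) else nn.Tensor(weights)
        return ((-w).exp() * L + w).sum()
    L = np.asarray(losses, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if np.any(L < 0):
        raise ValueError("per-task losses must be non-negative")
    return float(np.sum(np.exp(-w) * L + w))


# ---------------------------------------------------------------------------
# LOSO protocol
# ---------------------------------------------------------------------------

def loso_splits(manifest) -> list[tuple[list, object]]:
    """One fold per subject: (train subjects, held-out test subject)."""
    if isinstance(manifest, pd.DataFrame):
        subjects = list(pd.unique(manifest["subject"]))
    else:
        subjects = list(dict.fromkeys(manifest))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    return [([s for s in subjects if s != test], test) for test in subjects]


# ---------------------------------------------------------------------------
# Embedding extraction
# ---------------------------------------------------------------------------

def embed_session(session: SyntheticSession, modality: str,
                  spatial: SpatialEncoder | None = None,
                  hr_encoder: HeartRateEncoder | None = None,
                  chunk: int = 32) -> np.ndarray:
    """Compute the session embedding for one modality.

    video: VD (length d*f); hr: E_h (2048); fused: VD + bicubic-expanded E_h.
    """
    if modality not in ("video", "hr", "fused"):
        raise ValueError("modality must be video, hr, or fused")
    vd = None
    if modality in ("video", "fused"):
        if spatial is None:
            raise ValueError("video modality needs a spatial encoder")
        vd = video_forward(list(session.frames), spatial, chunk=chunk).VD
        if modality == "video":
            return vd
    if hr_encoder is None:
        raise ValueError("hr modality needs a heart-rate encoder")
    hr = hr_per_second(ECGSignal(session.ecg.samples, session.ecg.fs))
    eh = hr_encoder.embed(hr.values)
    if modality == "hr":
        return eh.E_h
    bh = bicubic_expand(eh, len(vd))
    return fuse_embeddings(vd, bh)


def embed_sessions(sessions, modality: str,
                   spatial: SpatialEncoder | None = None,
                   hr_encoder: HeartRateEncoder | None = None,
                   chunk: int = 32) -> np.ndarray:
    return np.stack([embed_session(s, modality, spatial, hr_encoder, chunk)
                     for s in sessions])


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------

def _filter_task(sessions, task: str):
    if task == "binary":
        keep = [s for s in sessions if s.label in BINARY_LABELS]
    elif task == "mc":
        keep = list(sessions)
    else:
        raise ValueError("task must be 'binary' or 'mc'")
    labels = sorted({s.label for s in keep})
    if len(labels) < 2:
        raise ValueError("training set must contain at least two classes")
    return keep


def fit(train_sessions, modality: str, cfg: TrainConfig | None = None,
        task: str = "binary", spatial: SpatialEncoder | None = None,
        hr_encoder: HeartRateEncoder | None = None,
        estimator_kwargs: dict | None = None,
        ) -> tuple[TemporalPainClassifier, list[float]]:
    """Train the temporal classifier on embeddings of the training sessions.

    The spatial and heart-rate encoders act as frozen feature extractors
    (fresh seeded instances when not supplied); the binary task keeps only
    NP and P4 sessions.  Returns the fitted estimator and its loss curve.
    """
    cfg = cfg or TrainConfig()
    sessions = _filter_task(train_sessions, task)
    if spatial is None and modality in ("video", "fused"):
        spatial = SpatialEncoder(seed=cfg.seed)
    if hr_encoder is None and modality in ("hr", "fused"):
        hr_encoder = HeartRateEncoder(seed=cfg.seed)
    X = embed_sessions(sessions, modality, spatial, hr_encoder)
    y = np.array([s.label for s in sessions])
    kwargs = dict(epochs=cfg.epochs, lr=cfg.lr, batch_size=cfg.batch_size,
                  weight_decay=cfg.weight_decay, warmup_epochs=cfg.warmup_epochs,
                  random_state=cfg.seed)
    kwargs.update(estimator_kwargs or {})
    est = TemporalPainClassifier(**kwargs)
    est.fit(X, y)
    return est, est.loss_curve_


def evaluate(y_true_folds: dict, y_pred_folds: dict,
             labels=None) -> MetricsReport:
    """Pool per-fold confusion matrices and report macro metrics.

    ``y_true_folds`` / ``y_pred_folds`` map fold id -> label arrays.  Fold
    confusion matrices are summed before computing accuracy and the
    macro-averaged precision, recall and F1 (pooling is invariant to fold
    size).
    """
    if not y_true_folds:
        raise ValueError("no folds to evaluate")
    if labels is None:
        labels = sorted({lab for ys in y_true_folds.values() for lab in np.unique(ys)})
    labels = list(labels)
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    per_fold = {}
    for fold, y_true in y_true_folds.items():
        y_pred = y_pred_folds[fold]
        fold_cm = confusion_matrix(y_true, y_pred, labels=labels)
        cm += fold_cm
        per_fold[fold] = float(np.trace(fold_cm) / max(fold_cm.sum(), 1))
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    tp = np.diag(cm).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    return MetricsReport(
        accuracy=float(tp.sum() / cm.sum()),
        precision=float(precision.mean()),
        recall=float(recall.mean()),
        f1=float(f1.mean()),
        confusion=cm,
        per_fold_accuracy=per_fold,
    )


def evaluate_loso(X: np.ndarray, y: np.ndarray, subjects: np.ndarray,
                  estimator_kwargs: dict | None = None,
                  cfg: TrainConfig | None = None) -> MetricsReport:
    """Full LOSO loop on precomputed embeddings."""
    cfg = cfg or TrainConfig()
    subjects = np.asarray(subjects)
    y = np.asarray(y)
    y_true, y_pred = {}, {}
    for _, test_subject in loso_splits(list(subjects)):
        test = subjects == test_subject
        kwargs = dict(epochs=cfg.epochs, lr=cfg.lr, batch_size=cfg.batch_size,
                      weight_decay=cfg.weight_decay,
                      warmup_epochs=cfg.warmup_epochs, random_state=cfg.seed)
        kwargs.update(estimator_kwargs or {})
        est = TemporalPainClassifier(**kwargs)
        est.fit(X[~test], y[~test])
        y_true[test_subject] = y[test]
        y_pred[test_subject] = est.predict(X[test])
    return evaluate(y_true, y_pred, labels=sorted(np.unique(y)))


__all__.append("evaluate_loso")


# ---------------------------------------------------------------------------
# Parameter / FLOP accounting
# ---------------------------------------------------------------------------

@dataclass
class ModelSummary:
    params_m: dict[str, float]      # millions, 2 decimals
    flops_g: dict[str, float]       # giga-FLOPs per forward pass
    total_params_m: float
    inference_params_m: float
    raw_params: dict[str, int]

    def as_dict(self) -> dict:
        return {"params_m": self.params_m, "flops_g": self.flops_g,
                "total_params_m": self.total_params_m,
                "inference_params_m": self.inference_params_m,
                "raw_params": self.raw_params}


def _spatial_flops(cfg: SpatialConfig) -> float:
    """Analytic matmul FLOPs (2mnk) for one 224x224 image forward."""
    n, m, c, d = cfg.n_patches, cfg.n_sub, cfg.inner_dim, cfg.embed_dim
    t = n + 1
    s3 = cfg.sub_patch_size**2 * 3
    total = 2 * n * m * s3 * c + 2 * n * (m * c) * d          # embeddings
    per_block = (
        n * (2 * m * c * 3 * c + 2 * 2 * m * m * c + 2 * m * c * c
             + 2 * 2 * m * c * cfg.fcn_inner_hidden)          # inner
        + 2 * n * (m * c) * d                                 # fold-in
        + 2 * t * d * 3 * d + 2 * 2 * t * t * d + 2 * t * d * d
        + 2 * 2 * t * d * cfg.fcn_outer_hidden                # outer
    )
    total += cfg.depth * per_block + 2 * d * d                # readout
    return total


def _hr_flops(cfg: HREncoderConfig, theta: int = 5) -> float:
    dim, L = cfg.internal_dim, cfg.n_latents
    total = 2 * theta * (2 * cfg.fourier_bands + 2) * dim
    total += 2 * L * dim * dim + 2 * 2 * theta * dim * dim    # q, kv
    total += 2 * 2 * L * theta * dim + 2 * L * dim * dim      # attn, out
    total += 2 * 2 * L * dim * cfg.fcn_hidden
    return total


def _augmnet_flops(cfg: AugmNetConfig) -> float:
    a, b = cfg.enc_hidden
    c = cfg.dec_hidden
    return 2 * (cfg.n * a + a * b + b * c + c * cfg.n)


def _temporal_flops(cfg: TemporalConfig, n_embed: int) -> float:
    t = int(np.ceil(n_embed / cfg.d_token))
    dim, L = cfg.internal_dim, cfg.n_latents
    total = 2 * t * cfg.d_token * dim + 2 * t * (2 * cfg.fourier_bands + 1) * dim
    total += 2 * L * dim * dim + 2 * 2 * t * dim * dim        # cross q, kv
    total += 2 * 2 * L * t * dim + 2 * L * dim * dim
    total += 2 * 2 * L * dim * cfg.fcn_hidden
    per_self = (2 * L * dim * 3 * dim + 2 * 2 * L * L * dim + 2 * L * dim * dim
                + 2 * 2 * L * dim * cfg.fcn_hidden)
    total += cfg.self_blocks * per_self + 2 * dim * cfg.n_classes
    return total


def model_summary(spatial_cfg: SpatialConfig | None = None,
                  hr_cfg: HREncoderConfig | None = None,
                  augm_cfg: AugmNetConfig | None = None,
                  temporal_cfg: TemporalConfig | None = None,
                  n_frames: int = 138, seed: int = 0) -> ModelSummary:
    """Instantiate the four modules and report exact trainable-parameter
    counts (millions, 2 decimals) plus analytic per-forward FLOP estimates.

    The inference total excludes AugmNet, which is active only in training.
    """
    spatial_cfg = spatial_cfg or SpatialConfig()
    hr_cfg = hr_cfg or HREncoderConfig()
    temporal_cfg = temporal_cfg or TemporalConfig()
    n_embed = spatial_cfg.embed_dim * n_frames
    augm_cfg = augm_cfg or AugmNetConfig(n=n_embed)

    modules = {
        "spatial": SpatialEncoder(spatial_cfg, seed=seed),
        "hr_encoder": HeartRateEncoder(hr_cfg, seed=seed),
        "augmnet": AugmNet(augm_cfg, seed=seed),
        "temporal": TemporalNet(temporal_cfg, seed=seed),
    }
    raw = {name: m.n_parameters() for name, m in modules.items()}
    params_m = {name: round(v / 1e6, 2) for name, v in raw.items()}
    flops = {
        "spatial": _spatial_flops(spatial_cfg),
        "hr_encoder": _hr_flops(hr_cfg),
        "augmnet": _augmnet_flops(augm_cfg),
        "temporal": _temporal_flops(temporal_cfg, n_embed),
    }
    total = sum(raw.values())
    inference = total - raw["augmnet"]
    return ModelSummary(
        params_m=params_m,
        flops_g={k: round(v / 1e9, 2) for k, v in flops.items()},
        total_params_m=round(total / 1e6, 2),
        inference_params_m=round(inference / 1e6, 2),
        raw_params=raw,
    )
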