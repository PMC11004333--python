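"""scikit-learn estimator wrapping the temporal classifier training loop.

``TemporalPainClassifier`` follows the sklearn contract (``fit`` /
``predict`` / ``predict_proba``, ``get_params``/``set_params`` via
``BaseEstimator``, fitted attributes with trailing underscores) so it
composes with sklearn model selection.  Input X is the matrix of session
embeddings (video, heart-rate, or fused), y the pain labels.

Training follows the study recipe: AdamW with decoupled weight decay,
linear warmup followed by cosine learning-rate decay, latent-space
augmentations applied only during training (Basic, Masking, and the learned
AugmNet, each optional).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import nn
from .augment import AugmNet, AugmNetConfig, basic_augment, mask_augment
from .temporal import TemporalConfig, TemporalNet

__all__ = ["TemporalPainClassifier", "cross_entropy"]


def cross_entropy(logits: nn.Tensor, y: np.ndarray) -> nn.Tensor:
    """Mean negative log-likelihood of integer targets."""
    logp = logits - logits.logsumexp(axis=-1)
    picked = logp[np.arange(len(y)), y]
    return -picked.mean()


class TemporalPainClassifier(ClassifierMixin, BaseEstimator):
    """Pain-level classifier over session embeddings.

    Parameters mirror the temporal module architecture plus the training
    recipe; all randomness (initialisation, batching, augmentation) derives
    from ``random_state``.
    """

    def __init__(self, internal_dim: int = 128, n_latents: int = 32,
                 self_blocks: int = 3, self_heads: int = 8,
                 cross_heads: int = 1, d_token: int = 100,
                 fourier_bands: int = 32, fcn_hidden: int = 1300,
                 epochs: int = 200, lr: float = 1e-4, batch_size: int = 32,
                 weight_decay: float = 0.1, warmup_epochs: int = 50,
                 augment_p: float = 0.5, use_basic: bool = False,
                 basic_invert_p: float = 0.5, basic_noise_sd: float = 0.1,
                 use_mask: bool = False, use_augmnet: bool = False,
                 augmnet_enc_hidden: tuple[int, int] = (36, 170),
                 augmnet_dec_hidden: int = 36, random_state: int = 0):
        self.internal_dim = internal_dim
        self.n_latents = n_latents
        self.self_blocks = self_blocks
        self.self_heads = self_heads
        self.cross_heads = cross_heads
        self.d_token = d_token
        self.fourier_bands = fourier_bands
        self.fcn_hidden = fcn_hidden
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.warmup_epochs = warmup_epochs
        self.augment_p = augment_p
        self.use_basic = use_basic
        self.basic_invert_p = basic_invert_p
        self.basic_noise_sd = basic_noise_sd
        self.use_mask = use_mask
        self.use_augmnet = use_augmnet
        self.augmnet_enc_hidden = augmnet_enc_hidden
        self.augmnet_dec_hidden = augmnet_dec_hidden
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least two classes")
        self.n_features_in_ = X.shape[1]

        cfg = TemporalConfig(
            internal_dim=self.internal_dim, n_latents=self.n_latents,
            self_blocks=self.self_blocks, self_heads=self.self_heads,
            cross_heads=self.cross_heads, d_token=self.d_token,
            fourier_bands=self.fourier_bands, fcn_hidden=self.fcn_hidden,
            n_classes=len(self.classes_))
        self.model_ = TemporalNet(cfg, seed=self.random_state)
        params = self.model_.parameters()
        self.augmnet_ = None
        if self.use_augmnet:
            self.augmnet_ = AugmNet(
                AugmNetConfig(n=self.n_features_in_,
                              enc_hidden=tuple(self.augmnet_enc_hidden),
                              dec_hidden=self.augmnet_dec_hidden),
                seed=self.random_state + 1)
            params = params + self.augmnet_.parameters()

        opt = nn.AdamW(params, lr=self.lr, weight_decay=self.weight_decay)
        rng = np.random.default_rng(self.random_state)
        n = len(X)
        batch = min(self.batch_size, n)
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            opt.lr = nn.cosine_warmup_lr(epoch, self.lr, self.warmup_epochs,
                                         self.epochs)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                xb, yb = X[idx], y_idx[idx]
                xb = self._augment_batch(xb, rng)
                if self.augmnet_ is not None:
                    emb = self.augmnet_(nn.Tensor(xb))
                    logits = self.model_.forward_tensor(emb)
                else:
                    logits = self.model_.forward(xb)
                loss = cross_entropy(logits, yb)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            self.loss_curve_.append(epoch_loss / n)
        self.model_.eval()
        if self.augmnet_ is not None:
            self.augmnet_.eval()
        return self

    def _augment_batch(self, xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.use_basic and rng.random() < self.augment_p:
            xb = basic_augment(xb, self.basic_invert_p, self.basic_noise_sd,
                               seed=int(rng.integers(2**31 - 1)))
        if self.use_mask and rng.random() < self.augment_p:
            xb = mask_augment(xb, seed=int(rng.integers(2**31 - 1)))
        return xb

    # ------------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; expected {self.n_features_in_}")
        self.model_.eval()
        with nn.no_grad():
            return self.model_.forward(X).data

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]
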