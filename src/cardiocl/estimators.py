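"""scikit-learn style estimators over the library.

``RegionContrastivePretrainer`` is a transformer: ``fit(X)`` runs
self-supervised pretraining on unlabeled multi-lead segments and
``transform(X)`` returns the 8m-dim global features.  ``ECGClassifier``
is a classifier head over an (optionally pretrained, optionally frozen)
multi-branch encoder; with ``encoder=None`` it trains the same
architecture from scratch.  ``X`` is always an array of shape
``(n_samples, input_len, n_leads)`` of preprocessed (z-scored) segments
in the retained lead order.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import nn
from .augment import AugmentationConfig
from .evaluate import _softmax, macro_metrics, train_linear_head
from .io import RETAINED_LEADS, MultiLeadRecord
from .losses import LossConfig
from .model import AnatomyModel, Checkpoint, ModelConfig, model_from_checkpoint
from .pretrain import PretrainConfig, pretrain

__all__ = ["ECGPreprocessor", "RegionContrastivePretrainer", "ECGClassifier"]


def _check_X(X, input_len: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 3:
        raise ValueError("X must have shape (n_samples, input_len, n_leads)")
    if input_len is not None and X.shape[1] != input_len:
        raise ValueError(f"X has length {X.shape[1]}, expected {input_len}")
    return X


def _as_records(X: np.ndarray, sampling_rate: float) -> list[MultiLeadRecord]:
    return [MultiLeadRecord(signal=x, lead_names=RETAINED_LEADS,
                            sampling_rate=sampling_rate,
                            record_id=f"X{i:06d}")
            for i, x in enumerate(X)]


class ECGPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless record preprocessing as a transformer.

    ``transform`` accepts a list of :class:`MultiLeadRecord` (any lead
    superset of the retained eight, any duration) and returns the stacked
    ``(n, target_len, 8)`` array of lead-reduced, duration-standardized,
    resampled, globally z-scored segments.
    """

    def __init__(self, target_s: float = 10.0, target_len: int = 2048):
        self.target_s = target_s
        self.target_len = target_len

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        from .preprocess import preprocess_record
        return np.stack([
            preprocess_record(rec, self.target_s, self.target_len).signal
            for rec in X]).astype(np.float32)


class RegionContrastivePretrainer(TransformerMixin, BaseEstimator):
    """Anatomy-aware contrastive pretraining as a transformer.

    Parameters mirror the pretraining defaults (Adam, lr 0.001, batch 64,
    temperature 0.1, gamma 0.5, 200 epochs); ``sampling_rate`` is the
    effective rate of the (resampled) segments, needed by cardiac-cycle
    masking.  ``fit`` ignores ``y`` entirely (pretraining is label-blind).
    """

    def __init__(self, input_len: int = 2048, alpha: float = 0.125,
                 projector_dim: int = 128, grouping: str = "anatomical",
                 epochs: int = 200, batch_size: int = 64,
                 learning_rate: float = 1e-3, tau: float = 0.1,
                 gamma: float = 0.5,
                 denominator_convention: str = "as_printed",
                 enable_rrc: bool = True, enable_ccm: bool = True,
                 enable_ts: bool = True, sampling_rate: float | None = None,
                 random_state: int = 0):
        self.input_len = input_len
        self.alpha = alpha
        self.projector_dim = projector_dim
        self.grouping = grouping
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.tau = tau
        self.gamma = gamma
        self.denominator_convention = denominator_convention
        self.enable_rrc = enable_rrc
        self.enable_ccm = enable_ccm
        self.enable_ts = enable_ts
        self.sampling_rate = sampling_rate
        self.random_state = random_state

    def _config(self) -> PretrainConfig:
        return PretrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            model=ModelConfig(input_len=self.input_len, alpha=self.alpha,
                              projector_dim=self.projector_dim,
                              grouping=self.grouping,
                              grouping_seed=self.random_state,
                              seed=self.random_state),
            augmentation=AugmentationConfig(enable_rrc=self.enable_rrc,
                                            enable_ccm=self.enable_ccm,
                                            enable_ts=self.enable_ts),
            loss=LossConfig(tau=self.tau, gamma=self.gamma,
                            denominator_convention=self.denominator_convention),
            seed=self.random_state)

    def fit(self, X, y=None):
        X = _check_X(X, self.input_len)
        fs = self.sampling_rate or self.input_len / 10.0
        records = _as_records(X, fs)
        self.model_, self.trace_ = pretrain(records, self._config())
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _check_X(X, self.input_len)
        return self.model_.global_features(X)


class ECGClassifier(ClassifierMixin, BaseEstimator):
    """Linear head over a multi-branch encoder.

    ``encoder`` may be a fitted :class:`RegionContrastivePretrainer`, an
    :class:`AnatomyModel`, a :class:`Checkpoint`, or ``None`` (train the
    same architecture from random initialization).  ``freeze_encoder=True``
    with a pretrained encoder is linear probing; ``False`` is fine-tuning
    (or training from scratch when ``encoder=None``).  Epoch selection is
    by macro AUROC on an internal stratified validation split.
    """

    def __init__(self, encoder=None, freeze_encoder: bool = False,
                 input_len: int = 2048, alpha: float = 0.125,
                 epochs: int = 100, learning_rate: float | None = None,
                 batch_size: int = 64, validation_fraction: float = 0.15,
                 eval_every: int = 1, random_state: int = 0):
        self.encoder = encoder
        self.freeze_encoder = freeze_encoder
        self.input_len = input_len
        self.alpha = alpha
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.eval_every = eval_every
        self.random_state = random_state

    def _resolve_encoder(self) -> AnatomyModel:
        enc = self.encoder
        if enc is None:
            return AnatomyModel(ModelConfig(input_len=self.input_len,
                                            alpha=self.alpha,
                                            seed=self.random_state))
        if isinstance(enc, RegionContrastivePretrainer):
            check_is_fitted(enc, "model_")
            enc = enc.model_
        if isinstance(enc, Checkpoint):
            enc = model_from_checkpoint(enc)
        if not isinstance(enc, AnatomyModel):
            raise TypeError(f"cannot use {type(enc).__name__} as encoder")
        clone = AnatomyModel(enc.config)
        clone.load_state_arrays({k: v.copy()
                                 for k, v in enc.state_arrays().items()})
        clone.grouping = enc.grouping
        return clone

    def fit(self, X, y):
        X = _check_X(X)
        y = np.asarray(y)
        self.classes_ = np.sort(np.unique(y))
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        lut = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([lut[v] for v in y])
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, yi, test_size=self.validation_fraction, stratify=yi,
            random_state=self.random_state)
        rng = np.random.default_rng(self.random_state)
        model = self._resolve_encoder()
        lr = self.learning_rate or (1e-3 if self.freeze_encoder else 1e-4)
        if self.freeze_encoder:
            feat_tr = model.global_features(X_tr)
            feat_val = model.global_features(X_val)
            W, b = train_linear_head(feat_tr, y_tr, feat_val, y_val,
                                     len(self.classes_), self.epochs, lr,
                                     self.batch_size, rng)
            head = nn.Linear(feat_tr.shape[1], len(self.classes_), rng=rng)
            head.w.value[...] = W
            head.b.value[...] = b
        else:
            head = nn.Linear(model.config.global_dim, len(self.classes_),
                             rng=rng, name="head")
            opt = nn.Adam(model.params() + head.params(), lr=lr)
            best = (-np.inf, None)
            n = len(X_tr)
            bs = min(self.batch_size, n)
            for epoch in range(self.epochs):
                order = rng.permutation(n)
                for b0 in range(0, n, bs):
                    idx = order[b0:b0 + bs]
                    h = model.encode(X_tr[idx], train=True)
                    feat = h.reshape(len(idx), -1)
                    _, dlogits = nn.softmax_cross_entropy(
                        head.forward(feat), y_tr[idx])
                    opt.zero_grad()
                    dfeat = head.backward(dlogits)
                    model.backward_embeddings(dfeat.reshape(h.shape))
                    opt.step()
                if (epoch + 1) % self.eval_every and epoch != self.epochs - 1:
                    continue
                scores = _softmax(model.global_features(X_val)
                                  @ head.w.value + head.b.value)
                try:
                    sc = macro_metrics(scores, y_val,
                                       strict=False).macro_auroc
                except ValueError:
                    sc = -np.inf
                if sc > best[0]:
                    best = (sc, ({k: v.copy() for k, v in
                                  model.state_arrays().items()},
                                 head.w.value.copy(), head.b.value.copy()))
            if best[1] is not None:
                model.load_state_arrays(best[1][0])
                head.w.value[...] = best[1][1]
                head.b.value[...] = best[1][2]
        self.model_ = model
        self.head_ = head
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _check_X(X, self.model_.config.input_len)
        feat = self.model_.global_features(X)
        return _softmax(feat @ self.head_.w.value + self.head_.b.value)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
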