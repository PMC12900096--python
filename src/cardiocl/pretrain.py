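"""Self-supervised pretraining loop.

Every epoch shuffles the unlabeled records, draws fresh augmented view
pairs (dynamic augmentation), runs the multi-branch model on the 2N views
of each batch, and takes an Adam step on the regional contrastive loss.
Label information is never read.  Augmentation randomness is drawn from a
per-(epoch, record) substream so the data-loading order cannot change the
draws; the whole run is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentationConfig, make_view_pair
from .io import MultiLeadRecord
from .losses import LossConfig, region_contrast_loss
from .model import AnatomyModel, ModelConfig, save_checkpoint

__all__ = ["PretrainConfig", "pretrain"]


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    model: ModelConfig = field(default_factory=ModelConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    checkpoint_every: int = 0  # 0: only final

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (the loss needs "
                             "negatives)")


def _view_rng(seed: int, epoch: int, rec_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, epoch, rec_index]))


def pretrain(records: list[MultiLeadRecord], config: PretrainConfig,
             out_dir: str | Path | None = None,
             model: AnatomyModel | None = None, start_epoch: int = 0,
             optimizer_state: dict | None = None):
    """Run contrastive pretraining on preprocessed records.

    Records must already be at the model's input length.  Returns
    ``(model, trace)`` where trace is a per-epoch DataFrame of the mean
    intra-region, inter-region and combined losses.
    """
    if len(records) < config.batch_size:
        raise ValueError("fewer records than one batch")
    T = config.model.input_len
    for rec in records:
        if rec.signal.shape != (T, config.model.n_leads):
            raise ValueError(
                f"record {rec.record_id} has shape {rec.signal.shape}, "
                f"expected ({T}, {config.model.n_leads}); preprocess first")

    if model is None:
        model = AnatomyModel(config.model)
    optimizer = nn.Adam(model.params(), lr=config.learning_rate)
    if optimizer_state is not None:
        optimizer.load_state_dict(optimizer_state)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xB0BA]))
    if start_epoch:  # replay shuffles so a resumed run continues the stream
        for _ in range(start_epoch):
            shuffle_rng.permutation(len(records))

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    N = config.batch_size
    for epoch in range(start_epoch, config.epochs):
        order = shuffle_rng.permutation(len(records))
        epoch_terms = []
        for b0 in range(0, len(order) - N + 1, N):  # drop-last
            idx = order[b0:b0 + N]
            views_i, views_j = [], []
            for ri in idx:
                pair = make_view_pair(records[ri], config.augmentation,
                                      _view_rng(config.seed, epoch, int(ri)))
                views_i.append(pair.x_i)
                views_j.append(pair.x_j)
            batch = np.stack(views_i + views_j)  # (2N, T, C); partner k+N
            _, z = model.forward_views(batch, train=True)
            breakdown, dz = region_contrast_loss(z.astype(np.float64),
                                                 config.loss, with_grad=True)
            if not np.isfinite(breakdown.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {breakdown}")
            optimizer.zero_grad()
            model.backward(dz.astype(np.float32))
            optimizer.step()
            epoch_terms.append((breakdown.intra, breakdown.inter,
                                breakdown.total))
        intra, inter, total = np.mean(epoch_terms, axis=0)
        rows.append({"epoch": epoch, "loss_intra": intra,
                     "loss_inter": inter, "loss_region": total})
        if out_dir is not None and config.checkpoint_every and \
                (epoch + 1) % config.checkpoint_every == 0:
            save_checkpoint(out_dir / f"checkpoint_ep{epoch + 1}.npz",
                            model, epoch=epoch + 1, optimizer=optimizer)

    trace = pd.DataFrame(rows)
    if out_dir is not None:
        save_checkpoint(out_dir / "checkpoint_final.npz", model,
                        epoch=config.epochs, optimizer=optimizer)
        trace.to_csv(out_dir / "trace.csv", index=False)
    return model, trace
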