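"""Multi-branch anatomy-aware network.

Each of the 8 retained leads has a *dedicated* VGG-style 1D-CNN encoder
(no weight sharing): four stages of two conv(kernel 3, pad 1) + batch norm
+ ReLU blocks followed by max-pool stride 2, then global average pooling.
Base stage widths (64, 128, 256, 512) are scaled by the width factor
``alpha`` (default 0.125, giving widths 8/16/32/64 and a per-lead embedding
of m = 64), so the single-lead encoder is one-eighth the width of a
conventional multi-lead encoder.

Lead embeddings are fused into D = 4 region features by concatenating the
two member leads of each anatomical region (anterior, inferior, septal,
lateral) and passed through region-specific 2-layer MLP projectors
(2m -> 2m -> 128).  Downstream tasks discard the projectors and use the
concatenation of all 8 lead embeddings (the 8m-dim global feature).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io import RETAINED_LEADS
from .regions import REGION_NAMES, anatomical_grouping, random_grouping

__all__ = ["ModelConfig", "AnatomyModel", "split_leads", "fuse_regions",
           "global_feature", "save_checkpoint", "load_checkpoint"]

BASE_WIDTHS = (64, 128, 256, 512)
N_STAGES = len(BASE_WIDTHS)


@dataclass(frozen=True)
class ModelConfig:
    n_leads: int = 8
    lead_order: tuple[str, ...] = RETAINED_LEADS
    alpha: float = 0.125
    input_len: int = 2048
    projector_dim: int = 128
    grouping: str = "anatomical"  # or "random"
    grouping_seed: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_leads != len(self.lead_order):
            raise ValueError("n_leads must match lead_order")
        if self.input_len % (2 ** N_STAGES):
            raise ValueError(
                f"input_len must be divisible by {2 ** N_STAGES} "
                f"(the pooling stages)")
        if self.grouping not in ("anatomical", "random"):
            raise ValueError("grouping must be 'anatomical' or 'random'")

    @property
    def stage_widths(self) -> tuple[int, ...]:
        return tuple(max(1, int(round(w * self.alpha))) for w in BASE_WIDTHS)

    @property
    def embedding_dim(self) -> int:
        """Per-lead embedding dimension m."""
        return self.stage_widths[-1]

    @property
    def global_dim(self) -> int:
        return self.n_leads * self.embedding_dim


def split_leads(view: np.ndarray, n_leads: int = 8) -> list[np.ndarray]:
    """Split a (T, C) view into C single-lead signals, order preserved."""
    if view.ndim != 2 or view.shape[1] != n_leads:
        raise ValueError(f"expected a (T, {n_leads}) view, got {view.shape}")
    return [view[:, c] for c in range(n_leads)]


def fuse_regions(embeddings: list[np.ndarray] | np.ndarray,
                 grouping: tuple[tuple[int, int], ...]) -> list[np.ndarray]:
    """Concatenate the two member-lead embeddings of each region.

    ``embeddings`` is a length-8 list (or (8, m) array) of per-lead
    vectors; batched (B, m) entries work the same (concatenation on the
    last axis)."""
    flat = [i for pair in grouping for i in pair]
    if sorted(flat) != list(range(len(embeddings))):
        raise ValueError("grouping must be a disjoint partition of the leads")
    return [np.concatenate([embeddings[a], embeddings[b]], axis=-1)
            for a, b in grouping]


def global_feature(embeddings: list[np.ndarray]) -> np.ndarray:
    """Concatenate all lead embeddings in lead order (dim 8m)."""
    return np.concatenate(list(embeddings), axis=-1)


def _build_encoder(cfg: ModelConfig, rng: np.random.Generator,
                   name: str) -> nn.Sequential:
    layers: list[nn.Layer] = []
    cin = 1
    for s, width in enumerate(cfg.stage_widths):
        for b in range(2):
            layers.append(nn.Conv1d(cin, width, 3, 1, rng=rng,
                                    name=f"{name}.s{s}.conv{b}"))
            layers.append(nn.BatchNorm1d(width, name=f"{name}.s{s}.bn{b}"))
            layers.append(nn.ReLU())
            cin = width
        layers.append(nn.MaxPool1d(2))
    layers.append(nn.GlobalAvgPool1d())
    return nn.Sequential(*layers)


def _build_projector(cfg: ModelConfig, rng: np.random.Generator,
                     name: str) -> nn.Sequential:
    two_m = 2 * cfg.embedding_dim
    return nn.Sequential(
        nn.Linear(two_m, two_m, rng=rng, name=f"{name}.fc0"),
        nn.ReLU(),
        nn.Linear(two_m, cfg.projector_dim, rng=rng, name=f"{name}.fc1"),
    )


class AnatomyModel:
    """The full pretraining stack: 8 lead encoders, 4 region projectors."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoders = [_build_encoder(config, rng, f"enc{c}")
                         for c in range(config.n_leads)]
        self.projectors = [_build_projector(config, rng, f"proj{d}")
                           for d in range(len(REGION_NAMES))]
        if config.grouping == "anatomical":
            self.grouping = anatomical_grouping()
        else:
            self.grouping = random_grouping(
                np.random.default_rng(config.grouping_seed))

    # ---- forward / backward -------------------------------------------

    def encode(self, views: np.ndarray, train: bool = True) -> np.ndarray:
        """Per-lead embeddings for a batch of views.

        ``views``: (B, T, C) -> returns h of shape (B, C, m).
        """
        B, T, C = views.shape
        if C != self.config.n_leads:
            raise ValueError(f"expected {self.config.n_leads} leads, got {C}")
        h = np.empty((B, C, self.config.embedding_dim), dtype=np.float32)
        for c, enc in enumerate(self.encoders):
            x = np.ascontiguousarray(
                views[:, :, c], dtype=np.float32)[:, None, :]  # (B, 1, T)
            h[:, c, :] = enc.forward(x, train=train)
        return h

    def project(self, h: np.ndarray, train: bool = True) -> np.ndarray:
        """Region projections z of shape (B, D, p) from embeddings
        (B, C, m)."""
        fused = fuse_regions([h[:, c, :] for c in range(h.shape[1])],
                             self.grouping)
        z = np.stack([proj.forward(f.astype(np.float32), train=train)
                      for proj, f in zip(self.projectors, fused)], axis=1)
        return z

    def forward_views(self, views: np.ndarray, train: bool = True):
        """(B, T, C) -> (h, z) with z the RegionProjectionSet batch."""
        h = self.encode(views, train=train)
        return h, self.project(h, train=train)

    def backward(self, dz: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the projections (B, D, p) into
        all parameter gradients (projectors then encoders)."""
        B = dz.shape[0]
        m = self.config.embedding_dim
        dh = np.zeros((B, self.config.n_leads, m), dtype=np.float32)
        for d, proj in enumerate(self.projectors):
            dfused = proj.backward(np.ascontiguousarray(
                dz[:, d, :], dtype=np.float32))
            a, b = self.grouping[d]
            dh[:, a, :] += dfused[:, :m]
            dh[:, b, :] += dfused[:, m:]
        self.backward_embeddings(dh)

    def backward_embeddings(self, dh: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the lead embeddings (B, C, m)
        through the encoders."""
        for c, enc in enumerate(self.encoders):
            enc.backward(np.ascontiguousarray(dh[:, c, :], dtype=np.float32))

    def global_features(self, views: np.ndarray,
                        train: bool = False) -> np.ndarray:
        """(B, T, C) -> (B, 8m) downstream features (projectors unused)."""
        h = self.encode(views, train=train)
        return h.reshape(h.shape[0], -1)

    # ---- parameter access ---------------------------------------------

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for enc in self.encoders:
            out.extend(enc.params())
        for proj in self.projectors:
            out.extend(proj.params())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters plus batch-norm running statistics."""
        state = {p.name: p.value for p in self.params()}
        for mod_list, tag in ((self.encoders, "enc"),
                              (self.projectors, "proj")):
            for i, mod in enumerate(mod_list):
                for j, layer in enumerate(mod.layers):
                    if isinstance(layer, nn.BatchNorm1d):
                        state[f"{tag}{i}.l{j}.running_mean"] = layer.running_mean
                        state[f"{tag}{i}.l{j}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        if set(own) != set(state):
            raise ValueError("checkpoint parameter names do not match model")
        for name, arr in own.items():
            src = state[name]
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            arr[...] = src


@dataclass
class Checkpoint:
    model_config: ModelConfig
    state: dict[str, np.ndarray]
    epoch: int = 0
    optimizer_state: dict | None = None


def save_checkpoint(path, model: AnatomyModel, epoch: int = 0,
                    optimizer: nn.Adam | None = None) -> None:
    """Single-archive checkpoint (npz) holding config, parameters, batch
    norm statistics and optionally optimizer state; round-trips bit-exactly."""
    payload: dict[str, np.ndarray] = {
        f"state/{k}": v for k, v in model.state_arrays().items()}
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in model.config.__dict__.items()}
    payload["meta"] = np.frombuffer(
        json.dumps({"config": cfg, "epoch": int(epoch)}).encode(), dtype=np.uint8)
    if optimizer is not None:
        opt = optimizer.state_dict()
        payload["opt/t"] = np.asarray(opt["t"])
        for i, (m, v) in enumerate(zip(opt["m"], opt["v"])):
            payload[f"opt/m{i}"] = m
            payload[f"opt/v{i}"] = v
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path) -> Checkpoint:
    try:
        with np.load(path) as npz:
            data = {k: npz[k] for k in npz.files}
    except Exception as exc:  # corrupted / not an archive
        raise ValueError(f"unreadable checkpoint {path}: {exc}") from exc
    if "meta" not in data:
        raise ValueError("checkpoint missing metadata")
    meta = json.loads(bytes(data["meta"].tobytes()).decode())
    cfg_d = meta["config"]
    cfg = ModelConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                         for k, v in cfg_d.items()})
    state = {k[len("state/"):]: v for k, v in data.items()
             if k.startswith("state/")}
    opt_state = None
    if "opt/t" in data:
        n = sum(1 for k in data if k.startswith("opt/m"))
        opt_state = {"t": int(data["opt/t"]),
                     "m": [data[f"opt/m{i}"] for i in range(n)],
                     "v": [data[f"opt/v{i}"] for i in range(n)]}
    return Checkpoint(model_config=cfg, state=state,
                      epoch=int(meta["epoch"]), optimizer_state=opt_state)


def model_from_checkpoint(ckpt: Checkpoint) -> AnatomyModel:
    model = AnatomyModel(ckpt.model_config)
    model.load_state_arrays(ckpt.state)
    return model
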