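"""Transfer evaluation: subject-wise splits, linear probing, fine-tuning,
training from scratch, label-efficiency curves, and macro AUROC/AUPRC.

Splits are assigned at the *subject* level (all records of a subject land
in one partition) to prevent identity leakage: a random 20% of subjects
form the test set and the rest are split 9:1 into train/validation.

Metrics follow the one-vs-rest macro-averaging convention: each class in
turn is the positive class, AUROC (midrank / Mann-Whitney convention) and
AUPRC (average-precision step rule) are computed per class and averaged
arithmetically.  Threshold-0.5 confusion counts (recall, precision, FPR)
are reported per class for completeness but never used for model
selection; selection across epochs is by validation macro AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import nn
from .io import DatasetManifest, MultiLeadRecord
from .model import AnatomyModel, ModelConfig

__all__ = [
    "SplitSpec", "subject_wise_split",
    "auroc", "auprc", "macro_metrics", "MetricReport",
    "ProbeConfig", "FinetuneConfig",
    "linear_probe", "fine_tune", "train_from_scratch",
    "label_fraction_subsample", "label_fraction_curve",
]


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    train_val_ratio: tuple[int, int] = (9, 1)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")


def subject_wise_split(manifest: DatasetManifest,
                       spec: SplitSpec) -> DatasetManifest:
    """Assign train/validation/test splits by whole subjects."""
    df = manifest.entries.copy()
    if df["subject_id"].isna().any():
        raise ValueError("every record needs a subject_id for subject-wise "
                         "splitting")
    subjects = np.sort(df["subject_id"].unique())
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(subjects))
    n_test = max(1, int(round(spec.test_fraction * len(subjects))))
    a, b = spec.train_val_ratio
    n_rest = len(subjects) - n_test
    n_val = max(1, int(round(n_rest * b / (a + b))))
    test_s = set(subjects[perm[:n_test]])
    val_s = set(subjects[perm[n_test:n_test + n_val]])
    split = ["test" if s in test_s else "validation" if s in val_s
             else "train" for s in df["subject_id"]]
    df["split"] = split
    return DatasetManifest(df)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Binary AUROC (midrank convention for ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Binary AUPRC via the average-precision step rule."""
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise ValueError("AUPRC undefined: no positive samples")
    return float(average_precision_score(labels,
                                         np.asarray(scores, dtype=float)))


@dataclass
class MetricReport:
    per_class: pd.DataFrame = field(repr=False)
    macro_auroc: float = float("nan")
    macro_auprc: float = float("nan")
    n_classes: int = 0


def macro_metrics(scores: np.ndarray, labels: np.ndarray,
                  classes: np.ndarray | None = None,
                  strict: bool = True) -> MetricReport:
    """One-vs-rest macro metrics from a (n, K) score matrix.

    ``labels`` are integer class indices into the score columns.  In strict
    mode a class absent from the labels raises; otherwise it is excluded
    and the macro average runs over the K' present classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    K = scores.shape[1]
    if K < 2:
        raise ValueError("need at least 2 classes")
    if classes is None:
        classes = np.arange(K)
    rows = []
    for k in range(K):
        y = (labels == k).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            if strict:
                raise ValueError(f"class {classes[k]} absent from labels")
            continue
        s = scores[:, k]
        pred = (s >= 0.5).astype(int)
        tp = int(np.sum((pred == 1) & (y == 1)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        tn = int(np.sum((pred == 0) & (y == 0)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        rows.append({
            "class": classes[k],
            "auroc": auroc(s, y),
            "auprc": auprc(s, y),
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "fpr": fp / (fp + tn) if fp + tn else float("nan"),
        })
    per_class = pd.DataFrame(rows)
    return MetricReport(per_class=per_class,
                        macro_auroc=float(per_class["auroc"].mean()),
                        macro_auprc=float(per_class["auprc"].mean()),
                        n_classes=len(per_class))


# --------------------------------------------------------------------------
# heads and training loops
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeConfig:
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 64
    label_fraction: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class FinetuneConfig:
    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 64
    label_fraction: float = 1.0
    eval_every: int = 1
    seed: int = 0


def _encode_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    classes = np.array(sorted(set(labels)))
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in labels]), classes


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def train_linear_head(feat_tr, y_tr, feat_val, y_val, n_classes,
                      epochs, lr, batch_size, rng):
    """Softmax regression by minibatch Adam on fixed features; the epoch
    with the best validation macro AUROC wins.  Returns (W, b)."""
    d = feat_tr.shape[1]
    head = nn.Linear(d, n_classes, rng=rng, name="head")
    opt = nn.Adam(head.params(), lr=lr)
    best = (-np.inf, head.w.value.copy(), head.b.value.copy())
    n = len(feat_tr)
    bs = min(batch_size, n)
    for _ in range(epochs):
        order = rng.permutation(n)
        for b0 in range(0, n, bs):
            idx = order[b0:b0 + bs]
            logits = head.forward(feat_tr[idx].astype(np.float32))
            _, dlogits = nn.softmax_cross_entropy(logits, y_tr[idx])
            opt.zero_grad()
            head.backward(dlogits)
            opt.step()
        val_scores = _softmax(feat_val @ head.w.value + head.b.value)
        try:
            score = macro_metrics(val_scores, y_val, strict=False).macro_auroc
        except ValueError:
            score = -np.inf
        if score > best[0]:
            best = (score, head.w.value.copy(), head.b.value.copy())
    return best[1], best[2]


def _stack_views(records: list[MultiLeadRecord]) -> np.ndarray:
    return np.stack([r.signal for r in records]).astype(np.float32)


def _split_records(records, manifest: DatasetManifest):
    by_id = {r.record_id: r for r in records}
    out = {}
    for split in ("train", "validation", "test"):
        sub = manifest.entries[manifest.entries["split"] == split]
        out[split] = ([by_id[i] for i in sub["record_id"]],
                      list(sub["label"]))
    return out


def _clone_model(model: AnatomyModel) -> AnatomyModel:
    clone = AnatomyModel(model.config)
    clone.load_state_arrays({k: v.copy()
                             for k, v in model.state_arrays().items()})
    clone.grouping = model.grouping
    return clone


def linear_probe(model: AnatomyModel, records, manifest: DatasetManifest,
                 config: ProbeConfig = ProbeConfig()):
    """Frozen-encoder linear evaluation.  Returns (head, MetricReport).

    The encoder is used purely as a feature extractor (eval mode, never
    updated); a linear softmax classifier is trained on the 8m-dim global
    features of the train split, selected on validation macro AUROC, and
    reported on the test split.
    """
    rng = np.random.default_rng(config.seed)
    parts = _split_records(records, manifest)
    tr_recs, tr_labels = parts["train"]
    if config.label_fraction < 1.0:
        keep = label_fraction_subsample(
            manifest, config.label_fraction, rng)
        tr_recs = [r for r in tr_recs if r.record_id in keep]
        tr_labels = [l for r, l in zip(parts["train"][0], parts["train"][1])
                     if r.record_id in keep]
    y_tr, classes = _encode_labels(tr_labels)
    if len(classes) < 2:
        raise ValueError("training subset lost all but one class; change "
                         "the seed or label fraction")
    feat_tr = model.global_features(_stack_views(tr_recs))
    feat_val = model.global_features(_stack_views(parts["validation"][0]))
    feat_te = model.global_features(_stack_views(parts["test"][0]))
    lut = {c: i for i, c in enumerate(classes)}
    y_val = np.array([lut[v] for v in parts["validation"][1]])
    y_te = np.array([lut[v] for v in parts["test"][1]])
    W, b = train_linear_head(feat_tr, y_tr, feat_val, y_val, len(classes),
                             config.epochs, config.learning_rate,
                             config.batch_size, rng)
    report = macro_metrics(_softmax(feat_te @ W + b), y_te, classes=classes)
    return (W, b), report


def _joint_train(model: AnatomyModel, records, manifest, *, epochs, lr,
                 batch_size, label_fraction, eval_every, seed):
    """Shared loop for fine-tuning and training from scratch (encoder
    unfrozen, jointly optimized with the head)."""
    rng = np.random.default_rng(seed)
    parts = _split_records(records, manifest)
    tr_recs, tr_labels = parts["train"]
    if label_fraction < 1.0:
        keep = label_fraction_subsample(manifest, label_fraction, rng)
        pairs = [(r, l) for r, l in zip(tr_recs, tr_labels)
                 if r.record_id in keep]
        tr_recs = [p[0] for p in pairs]
        tr_labels = [p[1] for p in pairs]
    y_tr, classes = _encode_labels(tr_labels)
    if len(classes) < 2:
        raise ValueError("training subset lost all but one class; change "
                         "the seed or label fraction")
    lut = {c: i for i, c in enumerate(classes)}
    y_val = np.array([lut[v] for v in parts["validation"][1]])
    y_te = np.array([lut[v] for v in parts["test"][1]])
    X_tr = _stack_views(tr_recs)
    X_val = _stack_views(parts["validation"][0])
    X_te = _stack_views(parts["test"][0])

    head = nn.Linear(model.config.global_dim, len(classes), rng=rng,
                     name="head")
    opt = nn.Adam(model.params() + head.params(), lr=lr)
    best_score = -np.inf
    best_state = None
    n = len(X_tr)
    bs = min(batch_size, n)
    for epoch in range(epochs):
        order = rng.permutation(n)
        for b0 in range(0, n, bs):
            idx = order[b0:b0 + bs]
            h = model.encode(X_tr[idx], train=True)
            feat = h.reshape(len(idx), -1)
            logits = head.forward(feat)
            _, dlogits = nn.softmax_cross_entropy(logits, y_tr[idx])
            opt.zero_grad()
            dfeat = head.backward(dlogits)
            model.backward_embeddings(dfeat.reshape(h.shape))
            opt.step()
        if (epoch + 1) % eval_every and epoch != epochs - 1:
            continue
        val_scores = _softmax(model.global_features(X_val) @ head.w.value
                              + head.b.value)
        try:
            score = macro_metrics(val_scores, y_val,
                                  strict=False).macro_auroc
        except ValueError:
            score = -np.inf
        if score > best_score:
            best_score = score
            best_state = ({k: v.copy() for k, v in
                           model.state_arrays().items()},
                          head.w.value.copy(), head.b.value.copy())
    if best_state is not None:
        model.load_state_arrays(best_state[0])
        head.w.value[...] = best_state[1]
        head.b.value[...] = best_state[2]
    report = macro_metrics(
        _softmax(model.global_features(X_te) @ head.w.value + head.b.value),
        y_te, classes=classes)
    return (model, head), report


def fine_tune(model: AnatomyModel, records, manifest: DatasetManifest,
              config: FinetuneConfig = FinetuneConfig()):
    """Fine-tune a (copy of a) pretrained model jointly with a linear head.

    The input model is not mutated; the trained copy is returned with the
    test-split MetricReport."""
    work = _clone_model(model)
    return _joint_train(work, records, manifest, epochs=config.epochs,
                        lr=config.learning_rate,
                        batch_size=config.batch_size,
                        label_fraction=config.label_fraction,
                        eval_every=config.eval_every, seed=config.seed)


def train_from_scratch(records, manifest: DatasetManifest,
                       config: FinetuneConfig = FinetuneConfig(),
                       model_config: ModelConfig = ModelConfig()):
    """The TFS comparison arm: identical architecture and optimization as
    fine-tuning, but from random initialization."""
    model = AnatomyModel(model_config)
    return _joint_train(model, records, manifest, epochs=config.epochs,
                        lr=config.learning_rate,
                        batch_size=config.batch_size,
                        label_fraction=config.label_fraction,
                        eval_every=config.eval_every, seed=config.seed)


def label_fraction_subsample(manifest: DatasetManifest, fraction: float,
                             rng: np.random.Generator) -> set[str]:
    """Subject-grouped, class-stratified subsample of the train split.

    Whole subjects are added (in random order) until every class reaches
    its target count ``max(1, round(fraction * class_count))``.  Returns
    the kept record ids."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    df = manifest.entries[manifest.entries["split"] == "train"]
    counts = df["label"].value_counts()
    target = {c: max(1, int(round(fraction * n)))
              for c, n in counts.items()}
    got = {c: 0 for c in target}
    subjects = rng.permutation(np.sort(df["subject_id"].unique()))
    keep: set[str] = set()
    for s in subjects:
        if all(got[c] >= t for c, t in target.items()):
            break
        sub = df[df["subject_id"] == s]
        keep.update(sub["record_id"])
        for lab in sub["label"]:
            got[lab] += 1
    missing = [c for c in target if got[c] == 0]
    if missing:
        raise ValueError(f"classes {missing} absent after subsampling; "
                         f"change the seed or fraction")
    return keep


def label_fraction_curve(model: AnatomyModel, records,
                         manifest: DatasetManifest,
                         fractions=(0.1, 0.2, 0.5, 1.0),
                         seeds=(0, 1, 2),
                         config: FinetuneConfig = FinetuneConfig()):
    """Paired fine-tune vs train-from-scratch sweep over label fractions.

    Per (fraction, seed) both arms see the identical labeled subset (same
    seed drives the subsample).  Returns a tidy DataFrame of per-run macro
    metrics plus mean/std aggregates."""
    rows = []
    for frac in fractions:
        for seed in seeds:
            cfg = FinetuneConfig(epochs=config.epochs,
                                 learning_rate=config.learning_rate,
                                 batch_size=config.batch_size,
                                 label_fraction=frac,
                                 eval_every=config.eval_every, seed=seed)
            _, rep_ft = fine_tune(model, records, manifest, cfg)
            _, rep_tfs = train_from_scratch(
                records, manifest, cfg, model_config=model.config)
            for arm, rep in (("finetune", rep_ft), ("tfs", rep_tfs)):
                rows.append({"fraction": frac, "seed": seed, "arm": arm,
                             "macro_auroc": rep.macro_auroc,
                             "macro_auprc": rep.macro_auprc})
    df = pd.DataFrame(rows)
    agg = (df.groupby(["fraction", "arm"])[["macro_auroc", "macro_auprc"]]
             .agg(["mean", "std"]).reset_index())
    return df, agg
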