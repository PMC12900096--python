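"""Splits, metrics, probing/fine-tuning contracts, estimator compliance."""

import numpy as np
import pandas as pd
import pytest

from cardiocl.evaluate import (FinetuneConfig, ProbeConfig, SplitSpec, auprc,
                               auroc, fine_tune, label_fraction_subsample,
                               linear_probe, macro_metrics,
                               subject_wise_split, train_from_scratch)
from cardiocl.io import DatasetManifest


def brute_auroc(scores, labels):
    """Pairwise concordance with 0.5 credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def brute_auprc(scores, labels):
    """Average-precision step sum over descending unique thresholds."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    s = np.asarray(scores)[order]
    tp = fp = 0
    prev_recall = 0.0
    total_pos = int(y.sum())
    ap = 0.0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            tp += int(y[j] == 1)
            fp += int(y[j] == 0)
            j += 1
        recall = tp / total_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def make_manifest(n_subjects, records_per_subject=1, labels=None):
    rows = []
    i = 0
    for s in range(n_subjects):
        for _ in range(records_per_subject):
            rows.append({"record_id": f"r{i}", "path": f"r{i}.csv",
                         "subject_id": f"s{s}",
                         "label": labels[i] if labels else "C0",
                         "split": "unlabeled"})
            i += 1
    return DatasetManifest(pd.DataFrame(rows))


class TestSubjectWiseSplit:
    def test_ten_subjects_two_in_test(self):
        man = subject_wise_split(make_manifest(10), SplitSpec(seed=0))
        by_split = man.entries.groupby("split")["subject_id"].nunique()
        assert by_split["test"] == 2

    def test_hundred_subjects_72_8_20(self):
        man = subject_wise_split(make_manifest(100), SplitSpec(seed=1))
        counts = man.entries["split"].value_counts()
        assert counts["train"] == 72
        assert counts["validation"] == 8
        assert counts["test"] == 20

    def test_no_subject_in_two_splits_over_many_seeds(self, rng):
        for seed in range(100):
            n = int(rng.integers(5, 40))
            rp = int(rng.integers(1, 4))
            man = subject_wise_split(make_manifest(n, rp),
                                     SplitSpec(seed=seed))
            overlap = man.entries.groupby("subject_id")["split"].nunique()
            assert (overlap == 1).all()

    def test_deterministic_under_seed(self):
        a = subject_wise_split(make_manifest(30, 2), SplitSpec(seed=5))
        b = subject_wise_split(make_manifest(30, 2), SplitSpec(seed=5))
        assert a.entries.equals(b.entries)

    def test_missing_subject_ids_rejected(self):
        man = make_manifest(5)
        df = man.entries.copy()
        df.loc[0, "subject_id"] = None
        with pytest.raises(ValueError, match="subject_id"):
            subject_wise_split(DatasetManifest(df), SplitSpec())


class TestBinaryMetrics:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0
        assert auprc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_hand_example_three_quarters(self):
        assert auroc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_score_negation_symmetry(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        assert auroc(-scores, labels) == pytest.approx(
            1 - auroc(scores, labels), abs=1e-12)

    def test_constant_scores_auprc_is_prevalence(self):
        labels = [1, 0, 0, 1, 0]
        assert auprc([0.5] * 5, labels) == pytest.approx(0.4)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert auprc(np.exp(scores), labels) == pytest.approx(
            auprc(scores, labels), abs=1e-12)
        assert auroc(np.exp(scores), labels) == pytest.approx(
            auroc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            auprc([0.1, 0.2], [0, 0])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.normal(size=n), 2)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert auroc(scores, labels) == pytest.approx(
                brute_auroc(scores, labels), abs=1e-9)
            assert auprc(scores, labels) == pytest.approx(
                brute_auprc(scores, labels), abs=1e-9)


class TestMacroMetrics:
    def test_macro_is_mean_of_per_class(self, rng):
        scores = rng.uniform(size=(60, 3))
        labels = rng.integers(0, 3, size=60)
        rep = macro_metrics(scores, labels)
        assert rep.macro_auroc == pytest.approx(
            rep.per_class["auroc"].mean())
        assert rep.macro_auprc == pytest.approx(
            rep.per_class["auprc"].mean())
        assert rep.n_classes == 3

    def test_binary_symmetric_complementary_scores(self, rng):
        s1 = rng.uniform(size=50)
        scores = np.column_stack([1 - s1, s1])
        labels = rng.integers(0, 2, size=50)
        rep = macro_metrics(scores, labels)
        aurocs = rep.per_class["auroc"].to_numpy()
        assert aurocs[0] == pytest.approx(aurocs[1], abs=1e-12)

    def test_absent_class_strict_vs_lenient(self, rng):
        scores = rng.uniform(size=(20, 3))
        labels = rng.integers(0, 2, size=20)  # class 2 never appears
        labels[:2] = [0, 1]
        with pytest.raises(ValueError, match="absent"):
            macro_metrics(scores, labels)
        rep = macro_metrics(scores, labels, strict=False)
        assert rep.n_classes == 2

    def test_confusion_counts_sum(self, rng):
        scores = rng.uniform(size=(40, 2))
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        rep = macro_metrics(scores, labels)
        for _, row in rep.per_class.iterrows():
            assert row["tp"] + row["fp"] + row["tn"] + row["fn"] == 40


class TestLabelFractionSubsample:
    def test_subject_grouped_and_all_classes_present(self, rng):
        labels = [f"C{i % 3}" for i in range(60)]
        man = make_manifest(20, 3, labels=labels)
        man = subject_wise_split(man, SplitSpec(seed=0))
        keep = label_fraction_subsample(man, 0.2, rng)
        df = man.entries
        kept_df = df[df["record_id"].isin(keep)]
        assert set(kept_df["label"]) == {"C0", "C1", "C2"}
        # whole subjects: every kept subject contributes all its train records
        for s in kept_df["subject_id"].unique():
            subj_train = df[(df["subject_id"] == s) & (df["split"] == "train")]
            assert set(subj_train["record_id"]) <= keep

    def test_invalid_fraction_rejected(self, rng):
        man = subject_wise_split(make_manifest(10), SplitSpec(seed=0))
        with pytest.raises(ValueError):
            label_fraction_subsample(man, 0.0, rng)


class TestDownstreamContracts:
    """Probe / fine-tune / TFS on the shared desk-scale fixture."""

    def test_probe_never_mutates_encoder(self, pretrained, preprocessed):
        model, _ = pretrained
        prep, manifest = preprocessed
        man = subject_wise_split(manifest, SplitSpec(seed=0))
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        _, report = linear_probe(model, prep, man,
                                 ProbeConfig(epochs=10, seed=0))
        after = model.state_arrays()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        assert 0.0 <= report.macro_auroc <= 1.0

    def test_probe_on_permuted_labels_is_chance(self, pretrained,
                                                preprocessed):
        model, _ = pretrained
        prep, manifest = preprocessed
        aurocs = []
        for seed in range(10):
            df = manifest.entries.copy()
            df["label"] = np.random.default_rng(seed).permutation(
                df["label"].to_numpy())
            man = subject_wise_split(DatasetManifest(df), SplitSpec(seed=seed))
            _, rep = linear_probe(model, prep, man,
                                  ProbeConfig(epochs=10, seed=seed))
            aurocs.append(rep.macro_auroc)
        mean = float(np.mean(aurocs))
        half_ci = 1.96 * float(np.std(aurocs)) / np.sqrt(len(aurocs))
        assert mean - half_ci <= 0.5 <= mean + half_ci

    def test_finetune_changes_encoder_and_preserves_input_model(
            self, pretrained, preprocessed):
        model, _ = pretrained
        prep, manifest = preprocessed
        man = subject_wise_split(manifest, SplitSpec(seed=1))
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        (tuned, _), _ = fine_tune(model, prep, man,
                                  FinetuneConfig(epochs=1, seed=1))
        after = model.state_arrays()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        conv_changed = any(
            not np.array_equal(tuned.state_arrays()[k], before[k])
            for k in before if k.startswith("enc"))
        assert conv_changed

    def test_tfs_runs_and_is_deterministic(self, preprocessed, pretrained):
        model, _ = pretrained
        prep, manifest = preprocessed
        man = subject_wise_split(manifest, SplitSpec(seed=2))
        cfg = FinetuneConfig(epochs=1, seed=2)
        _, rep1 = train_from_scratch(prep, man, cfg,
                                     model_config=model.config)
        _, rep2 = train_from_scratch(prep, man, cfg,
                                     model_config=model.config)
        assert rep1.macro_auroc == rep2.macro_auroc


def test_label_fraction_curve_pairs_arms(rng):
    """Tiny curve run: per (fraction, seed) both arms appear with finite
    metrics and the aggregate table has nonnegative std columns."""
    from cardiocl.evaluate import label_fraction_curve
    from cardiocl.model import AnatomyModel, ModelConfig
    from .test_pretrain import tiny_records

    records = tiny_records(24, seed=4)
    rows = []
    for i, r in enumerate(records):
        rows.append({"record_id": r.record_id, "path": f"{r.record_id}.csv",
                     "subject_id": f"s{i // 2}", "label": f"C{i % 2}",
                     "split": "unlabeled"})
    manifest = subject_wise_split(DatasetManifest(pd.DataFrame(rows)),
                                  SplitSpec(seed=0))
    model = AnatomyModel(ModelConfig(input_len=128, seed=0))
    df, agg = label_fraction_curve(model, records, manifest,
                                   fractions=(1.0,), seeds=(0,),
                                   config=FinetuneConfig(epochs=2,
                                                         batch_size=8))
    assert set(df["arm"]) == {"finetune", "tfs"}
    assert len(df) == 2
    assert df["macro_auroc"].between(0, 1).all()
    assert (agg[("macro_auroc", "mean")] >= 0).all()


class TestEstimatorCompliance:
    def test_get_set_params_and_clone(self):
        from sklearn.base import clone
        from cardiocl.estimators import (ECGClassifier,
                                         RegionContrastivePretrainer)
        pre = RegionContrastivePretrainer(input_len=128, epochs=2,
                                          batch_size=4, random_state=3)
        params = pre.get_params()
        assert params["input_len"] == 128
        cloned = clone(pre)
        assert cloned.get_params() == params
        clf = ECGClassifier(freeze_encoder=True, epochs=5)
        assert clone(clf).get_params()["freeze_encoder"] is True

    def test_pretrainer_fit_transform_and_classifier(self, rng):
        from cardiocl.estimators import (ECGClassifier,
                                         RegionContrastivePretrainer)
        X = rng.normal(size=(12, 128, 8)).astype(np.float32)
        y = np.array(["a", "b"] * 6)
        pre = RegionContrastivePretrainer(input_len=128, epochs=2,
                                          batch_size=4, random_state=0)
        feats = pre.fit(X).transform(X)
        assert feats.shape == (12, 512)
        assert len(pre.trace_) == 2
        clf = ECGClassifier(encoder=pre, freeze_encoder=True, epochs=5,
                            validation_fraction=0.25, random_state=0)
        clf.fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (12, 2)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert set(clf.predict(X)) <= {"a", "b"}
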