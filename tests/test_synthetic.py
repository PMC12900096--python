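"""Synthetic ECG generator: templates, records, datasets, 12-lead synthesis."""

import dataclasses

import numpy as np
import pytest

from cardiocl.io import RETAINED_LEADS
from cardiocl.regions import REGION_LEADS, REGION_NAMES
from cardiocl.synthetic import (BeatMorphology, SynthConfig,
                                generate_beat_template, generate_dataset,
                                generate_record, generate_twelve_lead)

V5 = RETAINED_LEADS.index("V5")


class TestBeatTemplate:
    def test_zero_amplitudes_give_zero_template(self):
        waves = {w: (0.0, c, wd) for w, (a, c, wd) in
                 BeatMorphology().waves.items()}
        morph = BeatMorphology(waves=waves)
        tpl = generate_beat_template(morph, 500)
        assert tpl.shape == (8, 500)
        assert np.all(tpl == 0.0)

    def test_single_r_bump_peaks_at_center(self):
        waves = dict(BeatMorphology().waves)
        for w in ("P", "Q", "S", "T"):
            a, c, wd = waves[w]
            waves[w] = (0.0, c, wd)
        waves["R"] = (1.0, 0.4, 0.02)
        tpl = generate_beat_template(BeatMorphology(waves=waves), 500)
        for lead in range(8):
            assert int(np.argmax(tpl[lead])) == 200

    def test_default_morphology_r_peak_location(self, default_morphology):
        tpl = generate_beat_template(default_morphology, 500)
        assert int(np.argmax(tpl[V5])) == round(0.4 * 500)

    def test_invalid_morphology_rejected(self):
        waves = dict(BeatMorphology().waves)
        waves["Q"] = (-0.1, 0.5, 0.01)  # Q after R
        with pytest.raises(ValueError, match="increasing"):
            BeatMorphology(waves=waves)

    def test_v5_dominance_enforced(self):
        with pytest.raises(ValueError, match="V5"):
            BeatMorphology(lead_scales=(1.0,) * 8)

    def test_st_offset_applied_between_s_and_t(self, default_morphology):
        morph = dataclasses.replace(default_morphology, st_offset=0.5,
                                    st_leads=(0, 1))
        base = generate_beat_template(default_morphology, 500)
        shifted = generate_beat_template(morph, 500)
        diff = shifted - base
        s_c, t_c = morph.waves["S"][1], morph.waves["T"][1]
        window = (np.arange(500) / 500 > s_c) & (np.arange(500) / 500 < t_c)
        assert np.allclose(diff[0, window], 0.5)
        assert np.allclose(diff[2:], 0.0)
        assert np.allclose(diff[:, ~window], 0.0)


class TestGenerateRecord:
    def make(self, rng, **kw):
        cfg = SynthConfig(heart_rate_range=(60.0, 60.0), rr_jitter=0.0,
                          noise_std=0.0, **kw)
        return generate_record(cfg, BeatMorphology(), rng)

    def test_fixed_60bpm_gives_10_evenly_spaced_peaks(self, rng):
        record, truth = self.make(rng)
        assert len(truth.r_peak_indices) == 10
        assert np.all(np.abs(np.diff(truth.r_peak_indices) - 500) <= 1)
        assert record.signal.shape == (5000, 8)

    def test_120bpm_gives_20_peaks_mean_rr_250(self, rng):
        cfg = SynthConfig(heart_rate_range=(120.0, 120.0), rr_jitter=0.0,
                          noise_std=0.0)
        _, truth = generate_record(cfg, BeatMorphology(), rng)
        assert len(truth.r_peak_indices) == 20
        assert float(np.diff(truth.r_peak_indices).mean()) == \
            pytest.approx(250, abs=1)

    def test_same_seed_bitwise_identical(self):
        cfg = SynthConfig(seed=5)
        a, _ = generate_record(cfg, BeatMorphology(),
                               np.random.default_rng(5))
        b, _ = generate_record(cfg, BeatMorphology(),
                               np.random.default_rng(5))
        assert np.array_equal(a.signal, b.signal)

    def test_ground_truth_peaks_align_with_reference_maxima(self, rng):
        record, truth = self.make(rng)
        v5 = record.signal[:, V5]
        for p in truth.r_peak_indices:
            lo, hi = max(0, p - 5), min(len(v5), p + 6)
            assert abs(lo + int(np.argmax(v5[lo:hi])) - p) <= 1

    def test_too_slow_heart_rate_rejected(self, rng):
        cfg = SynthConfig(duration=2.0, heart_rate_range=(30.0, 30.0))
        with pytest.raises(ValueError, match="two cardiac cycles"):
            generate_record(cfg, BeatMorphology(), rng)


class TestGenerateDataset:
    def test_counts_subjects_and_balance(self):
        cfg = SynthConfig(n_subjects=10, records_per_subject=2, n_classes=2,
                          seed=1)
        records, manifest = generate_dataset(cfg)
        assert len(records) == 20
        assert manifest.entries["subject_id"].nunique() == 10
        counts = manifest.entries["label"].value_counts()
        assert sorted(counts) == [10, 10]

    def test_balance_within_one_record(self):
        cfg = SynthConfig(n_subjects=25, records_per_subject=2, n_classes=4,
                          seed=2)
        _, manifest = generate_dataset(cfg)
        counts = manifest.entries["label"].value_counts()
        assert counts.max() - counts.min() <= 1

    def test_st_offset_localized_to_class_region(self):
        cfg = SynthConfig(n_subjects=8, records_per_subject=4, n_classes=4,
                          noise_std=0.0, baseline_wander_amp=0.0, seed=3)
        records, manifest = generate_dataset(cfg)
        labels = dict(zip(manifest.entries["record_id"],
                          manifest.entries["label"]))
        # mean absolute ST-segment amplitude per lead, per class
        for cls in range(4):
            region = REGION_NAMES[cls]
            region_idx = [RETAINED_LEADS.index(l)
                          for l in REGION_LEADS[region]]
            seg_means = np.zeros(8)
            n = 0
            for rec in records:
                if labels[rec.record_id] != f"C{cls}":
                    continue
                for r0, r1 in zip(rec.r_peaks[:-1], rec.r_peaks[1:]):
                    rr = r1 - r0
                    lo = r0 + int(0.10 * rr)
                    hi = r0 + int(0.22 * rr)
                    seg_means += np.abs(rec.signal[lo:hi]).mean(axis=0)
                    n += 1
            seg_means /= n
            top2 = set(np.argsort(seg_means)[-2:])
            assert top2 == set(region_idx), (cls, seg_means)

    def test_determinism(self):
        cfg = SynthConfig(n_subjects=3, records_per_subject=2, seed=9)
        r1, m1 = generate_dataset(cfg)
        r2, m2 = generate_dataset(cfg)
        assert m1.entries.equals(m2.entries)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.signal, b.signal)


class TestTwelveLead:
    def test_constant_leads_substitution(self, rng):
        cfg = SynthConfig(heart_rate_range=(60.0, 60.0), noise_std=0.0)
        record, _ = generate_record(cfg, BeatMorphology(), rng)
        sig = record.signal.copy()
        sig[:, 0] = 2.0  # II
        sig[:, 1] = 1.0  # III
        rec12 = generate_twelve_lead(record.with_(signal=sig, r_peaks=None))
        assert np.allclose(rec12.lead("I"), 1.0)
        assert np.allclose(rec12.lead("aVR"), -1.5)
        assert np.allclose(rec12.lead("aVL"), 0.0)
        assert np.allclose(rec12.lead("aVF"), 1.5)

    def test_goldberger_sum_identity(self, rng):
        cfg = SynthConfig(seed=4)
        record, _ = generate_record(cfg, BeatMorphology(), rng)
        rec12 = generate_twelve_lead(record)
        total = rec12.lead("aVR") + rec12.lead("aVL") + rec12.lead("aVF")
        assert np.allclose(total, 0.0, atol=1e-12)
        assert np.allclose(rec12.lead("I"),
                           rec12.lead("II") - rec12.lead("III"))

    def test_equal_limb_leads(self, rng):
        cfg = SynthConfig(heart_rate_range=(60.0, 60.0), noise_std=0.0)
        record, _ = generate_record(cfg, BeatMorphology(), rng)
        sig = record.signal.copy()
        sig[:, 1] = sig[:, 0]  # III == II
        rec12 = generate_twelve_lead(record.with_(signal=sig, r_peaks=None))
        assert np.allclose(rec12.lead("I"), 0.0)
        assert np.allclose(rec12.lead("aVF"), rec12.lead("II"))
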