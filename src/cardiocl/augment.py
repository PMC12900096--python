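"""Physiology-aware view generation for contrastive pretraining.

Three rhythm-preserving operations compose (default order RRC -> CCM -> TS)
into the positive-pair pipeline:

* **Random resized crop (RRC)** — extract a random 80-100% subsequence and
  Fourier-resample it back to the target length; simulates truncated
  acquisitions.
* **Cardiac-cycle masking (CCM)** — detect R-peaks on lead V5, compute the
  mean RR interval, and zero one contiguous window of 20% of the cycle
  length strictly inside every complete inter-peak cycle, identically
  across all leads; the window never touches an R-peak.  When fewer than
  two peaks are detectable, a nominal 0.8 s cycle grid is used instead.
* **Temporal shift (TS)** — shift all leads synchronously by an integer
  offset drawn uniformly within +/-80% of the length, zero-padding the
  vacated region.

No operation injects noise or rescales amplitudes; the only new values are
zeros.  Each operation accepts explicit draw overrides (``frac``,
``offset`` ...) so tests can force deterministic corner cases, and returns
its sampled provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.signal

from .io import RETAINED_LEADS, MultiLeadRecord
from .rpeaks import NOMINAL_CYCLE_S, detect_rpeaks, mean_rr_interval

__all__ = [
    "AugmentationConfig",
    "ViewPair",
    "random_resized_crop",
    "cardiac_cycle_mask",
    "temporal_shift",
    "make_view_pair",
]

V5_INDEX = RETAINED_LEADS.index("V5")


@dataclass(frozen=True)
class AugmentationConfig:
    crop_min_frac: float = 0.8
    crop_max_frac: float = 1.0
    mask_cycle_frac: float = 0.2
    shift_max_frac: float = 0.8
    enable_rrc: bool = True
    enable_ccm: bool = True
    enable_ts: bool = True

    def __post_init__(self):
        if not 0 < self.crop_min_frac <= self.crop_max_frac <= 1:
            raise ValueError("need 0 < crop_min_frac <= crop_max_frac <= 1")
        if not 0 < self.mask_cycle_frac < 1:
            raise ValueError("mask_cycle_frac must lie in (0, 1)")
        if not 0 <= self.shift_max_frac <= 1:
            raise ValueError("shift_max_frac must lie in [0, 1]")


@dataclass
class ViewPair:
    x_i: np.ndarray
    x_j: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)
    record_id: str = ""


def _fourier_resample(x: np.ndarray, target_len: int) -> np.ndarray:
    if x.shape[0] == target_len:
        return x.copy()
    return scipy.signal.resample(x, target_len, axis=0)


def random_resized_crop(signal: np.ndarray, cfg: AugmentationConfig,
                        rng: np.random.Generator, *,
                        frac: float | None = None,
                        start: int | None = None):
    """Crop a random subsequence (same window on all leads) and resample it
    back to the original length.  Returns ``(augmented, provenance)``."""
    length = signal.shape[0]
    if frac is None:
        frac = float(rng.uniform(cfg.crop_min_frac, cfg.crop_max_frac))
    crop_len = int(np.floor(frac * length + 0.5))
    crop_len = max(2, min(crop_len, length))
    if start is None:
        start = int(rng.integers(0, length - crop_len + 1))
    out = _fourier_resample(signal[start:start + crop_len], length)
    return out, {"op": "rrc", "frac": frac, "start": start,
                 "crop_len": crop_len}


def cardiac_cycle_mask(signal: np.ndarray, cfg: AugmentationConfig,
                       rng: np.random.Generator, fs: float, *,
                       detector=detect_rpeaks):
    """Zero one window per complete cardiac cycle, all leads synchronously.

    Returns ``(augmented, provenance)``; provenance lists the detected
    peaks and every ``(start, stop)`` masked window.
    """
    length = signal.shape[0]
    peaks = detector(signal[:, V5_INDEX], fs)
    fallback = peaks.size < 2
    if fallback:
        cycle = max(2, int(round(NOMINAL_CYCLE_S * fs)))
        peaks = np.arange(0, length, cycle, dtype=np.int64)
        mean_rr = float(cycle)
    else:
        mean_rr = mean_rr_interval(peaks)
    mask_len = int(np.floor(cfg.mask_cycle_frac * mean_rr + 0.5))
    out = signal.copy()
    windows: list[tuple[int, int]] = []
    if mask_len >= 1:
        for r0, r1 in zip(peaks[:-1], peaks[1:]):
            lo, hi = int(r0) + 1, int(r1) - mask_len  # keep window off peaks
            if hi < lo:
                continue
            start = int(rng.integers(lo, hi + 1))
            out[start:start + mask_len, :] = 0.0
            windows.append((start, start + mask_len))
    return out, {"op": "ccm", "fallback": fallback, "mean_rr": mean_rr,
                 "mask_len": mask_len, "peaks": peaks.tolist(),
                 "windows": windows}


def temporal_shift(signal: np.ndarray, cfg: AugmentationConfig,
                   rng: np.random.Generator, *,
                   offset: int | None = None):
    """Shift all leads by the same integer offset, zero-padding the vacated
    region.  Positive offsets move content to later times."""
    length = signal.shape[0]
    s_max = int(np.floor(cfg.shift_max_frac * length))
    if offset is None:
        offset = int(rng.integers(-s_max, s_max + 1))
    out = np.zeros_like(signal)
    if offset >= 0:
        out[offset:, :] = signal[:length - offset, :]
    else:
        out[:length + offset, :] = signal[-offset:, :]
    return out, {"op": "ts", "offset": offset, "max_offset": s_max}


def _augment_once(signal: np.ndarray, cfg: AugmentationConfig,
                  rng: np.random.Generator, fs: float):
    prov = []
    x = signal
    if cfg.enable_rrc:
        x, p = random_resized_crop(x, cfg, rng)
        prov.append(p)
    if cfg.enable_ccm:
        x, p = cardiac_cycle_mask(x, cfg, rng, fs)
        prov.append(p)
    if cfg.enable_ts:
        x, p = temporal_shift(x, cfg, rng)
        prov.append(p)
    return x, prov


def make_view_pair(record: MultiLeadRecord, cfg: AugmentationConfig,
                   rng: np.random.Generator) -> ViewPair:
    """Two independent draws of the composed pipeline on one preprocessed
    record.  With every operation disabled both views equal the input."""
    x_i, prov_i = _augment_once(record.signal, cfg, rng, record.sampling_rate)
    x_j, prov_j = _augment_once(record.signal, cfg, rng, record.sampling_rate)
    return ViewPair(x_i=x_i, x_j=x_j,
                    provenance={"view_i": prov_i, "view_j": prov_j},
                    record_id=record.record_id)
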