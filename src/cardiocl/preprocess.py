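"""Preprocessing pipeline: lead reduction, duration standardization,
resampling to a fixed number of time steps, and global z-score
normalization.

The 12-lead system is linearly redundant: by Einthoven's law and the
Goldberger definitions, leads I, aVR, aVL and aVF are linear combinations
of II and III,

    I   = II - III
    aVR = -(I + II) / 2
    aVL = I - II / 2          (equivalently (I - III) / 2)
    aVF = II - I / 2

so dropping them loses no information.  The retained 8-lead order is
(II, III, V1..V6) throughout.

Normalization is *global* (one mean/std over all leads and time points of a
record) rather than per lead, which preserves the clinically meaningful
relative amplitude pattern across leads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .io import RETAINED_LEADS, MultiLeadRecord

__all__ = [
    "LEAD_ALIASES",
    "NormalizationStats",
    "select_leads",
    "reconstruct_limb_leads",
    "standardize_duration",
    "resample_to_length",
    "global_zscore",
    "preprocess_record",
]

#: common alternative lead spellings, lowercased
LEAD_ALIASES = {"mlii": "ii", "mliii": "iii"}


@dataclass(frozen=True)
class NormalizationStats:
    mean: float
    std: float


def _canonical(name: str) -> str:
    low = name.strip().lower()
    return LEAD_ALIASES.get(low, low)


def select_leads(record: MultiLeadRecord) -> MultiLeadRecord:
    """Reduce to the 8 retained leads in the fixed order (II, III, V1-V6).

    Raises a lead-missing error naming the first absent lead.
    """
    available = {_canonical(n): i for i, n in enumerate(record.lead_names)}
    cols = []
    for want in RETAINED_LEADS:
        key = _canonical(want)
        if key not in available:
            raise KeyError(f"missing lead {want}")
        cols.append(available[key])
    return record.with_(signal=record.signal[:, cols],
                        lead_names=RETAINED_LEADS)


def reconstruct_limb_leads(lead_ii: np.ndarray, lead_iii: np.ndarray):
    """Derive (I, aVR, aVL, aVF) from leads II and III, elementwise."""
    lead_ii = np.asarray(lead_ii, dtype=np.float64)
    lead_iii = np.asarray(lead_iii, dtype=np.float64)
    if lead_ii.shape != lead_iii.shape:
        raise ValueError("leads II and III must have equal length")
    lead_i = lead_ii - lead_iii
    avr = -(lead_i + lead_ii) / 2.0
    avl = lead_i - lead_ii / 2.0
    avf = lead_ii - lead_i / 2.0
    return lead_i, avr, avl, avf


def standardize_duration(record: MultiLeadRecord,
                         target_s: float = 10.0) -> MultiLeadRecord:
    """Fix the record length to ``target_s`` seconds: truncate the tail of
    longer records, zero-pad the end of shorter ones.  Ground-truth R-peaks
    falling outside the kept window are dropped."""
    if target_s <= 0:
        raise ValueError("target duration must be positive")
    target_n = int(round(target_s * record.sampling_rate))
    sig = record.signal
    if sig.shape[0] >= target_n:
        sig = sig[:target_n]
    else:
        pad = np.zeros((target_n - sig.shape[0], sig.shape[1]))
        sig = np.vstack([sig, pad])
    peaks = record.r_peaks
    if peaks is not None:
        peaks = peaks[peaks < target_n]
    return record.with_(signal=sig, r_peaks=peaks)


def resample_to_length(record: MultiLeadRecord,
                       target_len: int = 2048) -> MultiLeadRecord:
    """Resample every lead to ``target_len`` samples with the band-limited
    Fourier method; the effective sampling rate becomes
    ``target_len / duration`` and R-peak indices are rescaled (round half
    up, a 1-sample discrepancy is inherent)."""
    n = record.n_samples
    if n < 2:
        raise ValueError("record too short to resample")
    if target_len == n:
        return record
    sig = scipy.signal.resample(record.signal, target_len, axis=0)
    new_fs = record.sampling_rate * target_len / n
    peaks = record.r_peaks
    if peaks is not None:
        peaks = np.floor(peaks * (target_len / n) + 0.5).astype(np.int64)
        peaks = np.unique(np.clip(peaks, 0, target_len - 1))
    return record.with_(signal=sig, sampling_rate=new_fs, r_peaks=peaks)


def global_zscore(record: MultiLeadRecord):
    """Normalize to zero mean, unit variance over *all* leads and time
    points jointly.  Returns (record, NormalizationStats)."""
    mu = float(record.signal.mean())
    delta = float(record.signal.std())
    if delta <= 0:
        raise ValueError("degenerate record: zero global standard deviation")
    out = record.with_(signal=(record.signal - mu) / delta)
    return out, NormalizationStats(mean=mu, std=delta)


def preprocess_record(record: MultiLeadRecord, target_s: float = 10.0,
                      target_len: int = 2048) -> MultiLeadRecord:
    """Full pipeline: select 8 leads -> standardize duration -> resample to
    ``target_len`` -> global z-score."""
    rec = select_leads(record)
    rec = standardize_duration(rec, target_s)
    rec = resample_to_length(rec, target_len)
    rec, _ = global_zscore(rec)
    return rec
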