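"""Pan-Tompkins-style R-peak detection and RR statistics.

The classic pipeline: band-pass (5-15 Hz, zero-phase), differentiate,
square, moving-window integration (150 ms), peak picking with a refractory
period, then refinement of each detection to the local maximum of the raw
signal.  It is fully deterministic and self-contained; the ``detector``
argument of :func:`detect_rpeaks_record` allows an external toolkit to be
swapped in for real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .io import MultiLeadRecord

__all__ = ["RPeakResult", "detect_rpeaks", "mean_rr_interval",
           "detect_rpeaks_record", "DEFAULT_REFERENCE_LEAD",
           "NOMINAL_CYCLE_S"]

DEFAULT_REFERENCE_LEAD = "V5"

#: fallback cardiac cycle length (seconds) when fewer than 2 peaks are found
NOMINAL_CYCLE_S = 0.8


@dataclass(frozen=True)
class RPeakResult:
    peak_indices: np.ndarray
    mean_rr: float | None
    reference_lead_name: str = DEFAULT_REFERENCE_LEAD


def detect_rpeaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-wave maxima in a single-lead signal.

    Returns 0-based sample indices, strictly increasing; an empty array is a
    valid result (flat or sub-threshold input).
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if x.size < int(2 * fs * 0.2):
        raise ValueError("signal too short for QRS detection")
    if np.max(np.abs(x)) < 1e-9:
        return np.empty(0, dtype=np.int64)

    nyq = fs / 2.0
    low, high = 5.0 / nyq, min(15.0, 0.9 * nyq) / nyq
    if low >= high:  # degenerate sampling rate; skip band-pass
        filtered = x - x.mean()
    else:
        b, a = scipy.signal.butter(2, [low, high], btype="band")
        filtered = scipy.signal.filtfilt(b, a, x)

    squared = np.diff(filtered, prepend=filtered[0]) ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = max(1, int(round(0.25 * fs)))
    height = 0.25 * mwi.max()
    cand, _ = scipy.signal.find_peaks(mwi, height=height, distance=refractory)
    if cand.size == 0:
        return np.empty(0, dtype=np.int64)

    # refine each candidate to the raw-signal maximum nearby
    half = max(1, int(round(0.10 * fs)))
    refined = []
    for c in cand:
        lo = max(0, c - half)
        hi = min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(np.asarray(refined, dtype=np.int64))
    # enforce the refractory period after refinement (keep larger peak)
    keep: list[int] = []
    for p in peaks:
        if keep and p - keep[-1] < refractory:
            if x[p] > x[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return np.asarray(keep, dtype=np.int64)


def mean_rr_interval(peak_indices: np.ndarray) -> float:
    """Arithmetic mean of successive R-R differences, in samples."""
    peaks = np.asarray(peak_indices)
    if peaks.size < 2:
        raise ValueError("need at least 2 R-peaks for an RR interval")
    return float(np.diff(peaks).mean())


def detect_rpeaks_record(record: MultiLeadRecord,
                         lead: str = DEFAULT_REFERENCE_LEAD,
                         detector=detect_rpeaks) -> RPeakResult:
    """Detect on the named reference lead of a record."""
    peaks = detector(record.lead(lead), record.sampling_rate)
    mean_rr = mean_rr_interval(peaks) if peaks.size >= 2 else None
    return RPeakResult(peak_indices=peaks, mean_rr=mean_rr,
                       reference_lead_name=lead)
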