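"""Record and manifest containers plus on-disk formats.

Signals are stored as a plain CSV matrix (one column per lead, header row
of lead names) with a JSON sidecar ``<stem>.json`` carrying sampling rate,
identifiers, the optional label, and ground-truth R-peak indices.  The
format is deliberately human-inspectable; it round-trips losslessly up to
float formatting (full ``repr`` precision is written).

Manifests are CSV files with the fixed header
``record_id,path,subject_id,label,split``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RETAINED_LEADS",
    "TWELVE_LEADS",
    "MultiLeadRecord",
    "read_record",
    "write_record",
    "load_manifest",
    "save_manifest",
    "ALLOWED_SPLITS",
]

#: the 8-lead order used everywhere downstream (limb II, III then precordial)
RETAINED_LEADS = ("II", "III", "V1", "V2", "V3", "V4", "V5", "V6")

#: conventional 12-lead order
TWELVE_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
                "V1", "V2", "V3", "V4", "V5", "V6")

ALLOWED_SPLITS = ("train", "validation", "test", "unlabeled")

MANIFEST_COLUMNS = ["record_id", "path", "subject_id", "label", "split"]


@dataclass
class MultiLeadRecord:
    """A multi-lead ECG segment: ``signal`` is (time, leads) in arbitrary
    amplitude units; ``r_peaks`` (optional) are 0-based sample indices of
    ground-truth or detected R waves in this record's time frame."""

    signal: np.ndarray
    lead_names: tuple[str, ...]
    sampling_rate: float
    record_id: str = "record"
    subject_id: str | None = None
    label: str | None = None
    r_peaks: np.ndarray | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a (time, leads) matrix")
        self.lead_names = tuple(self.lead_names)
        if self.signal.shape[1] != len(self.lead_names):
            raise ValueError(
                f"signal has {self.signal.shape[1]} columns but "
                f"{len(self.lead_names)} lead names were given")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.r_peaks is not None:
            self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
            if self.r_peaks.size and (
                    np.any(np.diff(self.r_peaks) <= 0)
                    or self.r_peaks[0] < 0
                    or self.r_peaks[-1] >= self.signal.shape[0]):
                raise ValueError("r_peaks must be strictly increasing and "
                                 "inside the record")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        """Column of the named lead (case-insensitive)."""
        lowered = [n.lower() for n in self.lead_names]
        try:
            idx = lowered.index(name.lower())
        except ValueError:
            raise KeyError(f"missing lead {name}") from None
        return self.signal[:, idx]

    def with_(self, **kwargs) -> "MultiLeadRecord":
        return replace(self, **kwargs)


def write_record(record: MultiLeadRecord, path: str | Path) -> Path:
    """Write a record as CSV matrix + JSON sidecar; returns the CSV path."""
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    df = pd.DataFrame(record.signal, columns=list(record.lead_names))
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "sampling_rate": record.sampling_rate,
        "record_id": record.record_id,
        "subject_id": record.subject_id,
        "label": record.label,
        "r_peaks": None if record.r_peaks is None else
                   [int(i) for i in record.r_peaks],
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_record(path: str | Path) -> MultiLeadRecord:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta_path = path.with_suffix(".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"sidecar {meta_path} not found")
    meta = json.loads(meta_path.read_text())
    return MultiLeadRecord(
        signal=df.to_numpy(dtype=np.float64),
        lead_names=tuple(df.columns),
        sampling_rate=float(meta["sampling_rate"]),
        record_id=str(meta.get("record_id", path.stem)),
        subject_id=meta.get("subject_id"),
        label=meta.get("label"),
        r_peaks=None if meta.get("r_peaks") is None else
                np.asarray(meta["r_peaks"], dtype=np.int64),
    )


@dataclass
class DatasetManifest:
    """Record list with identities and split assignments."""

    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=MANIFEST_COLUMNS))

    def __post_init__(self):
        df = pd.DataFrame(self.entries)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        df = df[MANIFEST_COLUMNS].reset_index(drop=True)
        if df["record_id"].duplicated().any():
            dupes = df.loc[df["record_id"].duplicated(), "record_id"].tolist()
            raise ValueError(f"duplicate record ids: {dupes}")
        bad = set(df["split"].dropna()) - set(ALLOWED_SPLITS)
        if bad:
            raise ValueError(f"invalid split values: {sorted(bad)}")
        self.entries = df

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(self.entries[self.entries["split"] == split])

    def validate_paths(self, root: str | Path = ".") -> None:
        root = Path(root)
        for p in self.entries["path"]:
            if not (root / p).exists():
                raise FileNotFoundError(p)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.entries.to_csv(path, index=False)
    return path


def load_manifest(path: str | Path) -> DatasetManifest:
    df = pd.read_csv(Path(path), dtype={"record_id": str, "path": str,
                                        "subject_id": str, "label": str})
    return DatasetManifest(df)
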