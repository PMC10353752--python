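"""Cohort container and file I/O.

A :class:`CohortEEG` holds a multi-subject EEG recording on a shared clock:
one ``subjects x channels x time`` array plus sampling rate, channel
labels, unit-sphere electrode positions, and a channel -> scalp-region map
(frontal/central/parietal/temporal/occipital).  Cohorts round-trip through
a single HDF5 container; raw per-subject recordings are read from
BrainVision or EDF files through MNE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

REGIONS = ("F", "C", "P", "T", "O")


def region_of(channel: str) -> str:
    """Scalp region from the first letter of a 10-20 channel label."""
    first = channel.strip()[0].upper()
    if first not in REGIONS:
        raise ValueError(f"cannot assign region for channel {channel!r}")
    return first


@dataclass
class CohortEEG:
    """Multi-subject EEG on a shared clock.

    ``data`` is subjects x channels x time; ``positions`` are 3-D electrode
    coordinates normalised to the unit sphere; ``region`` maps each channel
    label to one of F/C/P/T/O.
    """

    data: np.ndarray
    fs_hz: float
    channel_names: list
    positions: np.ndarray
    region: dict = field(default_factory=dict)
    bad_channels: Optional[list] = None  # per-subject lists of labels

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("data must be subjects x channels x time")
        n_ch = self.data.shape[1]
        if len(self.channel_names) != n_ch:
            raise ValueError("one label per channel required")
        self.positions = np.asarray(self.positions, float)
        if self.positions.shape != (n_ch, 3):
            raise ValueError("positions must be channels x 3")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms == 0):
            raise ValueError("electrode at origin")
        self.positions = self.positions / norms[:, None]
        if not self.region:
            self.region = {c: region_of(c) for c in self.channel_names}
        missing = [c for c in self.channel_names if c not in self.region]
        if missing:
            raise ValueError(f"region map missing channels: {missing}")
        if self.bad_channels is None:
            self.bad_channels = [[] for _ in range(self.data.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def copy_with(self, data: np.ndarray, fs_hz: Optional[float] = None) -> "CohortEEG":
        return CohortEEG(
            data=data,
            fs_hz=self.fs_hz if fs_hz is None else fs_hz,
            channel_names=list(self.channel_names),
            positions=self.positions.copy(),
            region=dict(self.region),
            bad_channels=[list(b) for b in self.bad_channels],
        )


def standard_positions(channel_names) -> np.ndarray:
    """Unit-sphere 3-D positions for 10-20 labels from the standard cap montage."""
    import mne

    montage = mne.channels.make_standard_montage("easycap-M1")
    pos = montage.get_positions()["ch_pos"]
    out = []
    for name in channel_names:
        if name not in pos:
            raise KeyError(f"channel {name!r} not in standard montage")
        out.append(pos[name])
    out = np.asarray(out, float)
    return out / np.linalg.norm(out, axis=1)[:, None]


# ---------------------------------------------------------------------------
# HDF5 cohort container
# ---------------------------------------------------------------------------

def save_cohort(path, cohort: CohortEEG, engagement: Optional[np.ndarray] = None) -> None:
    """Write a cohort (and optionally an engagement trace) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=cohort.data)
        f.create_dataset("montage", data=cohort.positions)
        f.create_dataset(
            "labels", data=np.array(cohort.channel_names, dtype=h5py.string_dtype())
        )
        f.attrs["fs_hz"] = cohort.fs_hz
        f.attrs["region"] = json.dumps(cohort.region)
        f.attrs["bad_channels"] = json.dumps(cohort.bad_channels)
        if engagement is not None:
            f.create_dataset("engagement", data=np.asarray(engagement, float))


def load_cohort(path):
    """Read a cohort HDF5 container; returns (CohortEEG, engagement-or-None)."""
    with h5py.File(path, "r") as f:
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]]
        cohort = CohortEEG(
            data=f["eeg"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            channel_names=labels,
            positions=f["montage"][()],
            region=json.loads(f.attrs["region"]),
            bad_channels=json.loads(f.attrs["bad_channels"]),
        )
        engagement = f["engagement"][()] if "engagement" in f else None
    return cohort, engagement


# ---------------------------------------------------------------------------
# Raw EEG readers (MNE-backed) and sidecar montage
# ---------------------------------------------------------------------------

def _read_raw(path):
    import mne

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".vhdr":
        return mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    if suffix == ".edf":
        return mne.io.read_raw_edf(path, preload=True, verbose="error")
    raise ValueError(f"unsupported raw EEG format: {path.name}")


def read_montage_csv(path) -> tuple:
    """Sidecar montage CSV with columns label,x,y,z -> (labels, positions)."""
    df = pd.read_csv(path)
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError("montage CSV needs columns label,x,y,z")
    return list(df["label"]), df[["x", "y", "z"]].to_numpy(float)


def load_raw_cohort(paths, montage_csv=None) -> CohortEEG:
    """Build a cohort from per-subject BrainVision/EDF files.

    All recordings must agree on channel labels and sampling rate; the
    common time span is truncated to the shortest recording.  Positions
    come from the recordings themselves when present, else from a sidecar
    montage CSV, else from the standard cap montage.
    """
    raws = [_read_raw(p) for p in paths]
    names = raws[0].ch_names
    fs = float(raws[0].info["sfreq"])
    for r in raws[1:]:
        if r.ch_names != names:
            raise ValueError("subjects disagree on channel labels")
        if float(r.info["sfreq"]) != fs:
            raise ValueError("subjects disagree on sampling rate")
    n_t = min(r.n_times for r in raws)
    data = np.stack([r.get_data()[:, :n_t] for r in raws])
    if montage_csv is not None:
        labels, pos = read_montage_csv(montage_csv)
        order = [labels.index(n) for n in names]
        positions = pos[order]
    else:
        mpos = raws[0].get_montage()
        if mpos is not None and all(n in mpos.get_positions()["ch_pos"] for n in names):
            positions = np.array([mpos.get_positions()["ch_pos"][n] for n in names])
        else:
            positions = standard_positions(names)
    return CohortEEG(data=data, fs_hz=fs, channel_names=list(names), positions=positions)


# ---------------------------------------------------------------------------
# Behavioral CSV formats
# ---------------------------------------------------------------------------

def read_ratings_csv(path) -> pd.DataFrame:
    """Continuous ratings: columns rater_id, time_s, value."""
    df = pd.read_csv(path)
    if not {"rater_id", "time_s", "value"}.issubset(df.columns):
        raise ValueError("ratings CSV needs columns rater_id,time_s,value")
    return df


def read_stamps_csv(path) -> pd.DataFrame:
    """Phase-boundary stamps: columns rater_id, phase, start_s."""
    df = pd.read_csv(path)
    if not {"rater_id", "phase", "start_s"}.issubset(df.columns):
        raise ValueError("stamps CSV needs columns rater_id,phase,start_s")
    return df


def read_recall_dir(path) -> dict:
    """Recall documents named ``<subject>_<phase>.txt`` -> nested dict."""
    docs: dict = {}
    for p in sorted(Path(path).glob("*.txt")):
        stem = p.stem
        if "_" not in stem:
            raise ValueError(f"recall file {p.name} must be <subject>_<phase>.txt")
        subject, phase = stem.split("_", 1)
        docs.setdefault(subject, {})[phase] = p.read_text(encoding="utf-8")
    return docs
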