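"""On-disk formats: BrainVision EEG triplets, montages, TSV tables, run config.

Conventions
-----------
* All on-disk event times are **sample indices** (0-based in memory; the
  BrainVision marker file stores them 1-based per the format definition).
* In-memory EEG data are always microvolts, channels x samples.
* Stimulus markers are ``S<go|nogo><color_id>`` (e.g. ``Sgo3``, ``Snogo0``);
  response markers are ``R1`` (first press) and ``R2`` (error-signaling
  second press).  The original recordings' marker scheme is not public, so
  this convention is fixed here and used by the synthesizer and all readers.
"""

from __future__ import annotations

import configparser
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Montage",
    "UnsupportedDialectError",
    "read_brainvision",
    "write_brainvision",
    "read_montage",
    "load_default_montage",
    "read_trial_table",
    "write_trial_table",
    "read_subject_meta",
    "write_subject_meta",
    "read_config",
    "write_config",
]

#: Channel labels treated as electro-oculogram, excluded from all analyses.
EOG_LABELS = ("VEOGu", "VEOGo", "HEOGl", "HEOGr")

TRIAL_COLUMNS = [
    "trial", "block", "stimulus_kind", "color_id",
    "stimulus_onset_ms", "rt1_ms", "rt2_ms", "category",
]


class UnsupportedDialectError(ValueError):
    """Raised for BrainVision dialects we refuse to guess at."""


@dataclass
class Recording:
    """Continuous multichannel EEG with event markers.

    data is channels x samples in microvolts; events are (sample_index, code)
    pairs with 0-based sample indices.
    """

    channel_labels: list[str]
    channel_kinds: list[str]          # "scalp" | "eog", parallel to labels
    sampling_rate: float
    data: np.ndarray
    events: list[tuple[int, str]]
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def scalp_picks(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == "scalp"])

    def validate(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be channels x samples matching channel_labels")
        if len(self.channel_kinds) != len(self.channel_labels):
            raise ValueError("channel_kinds must parallel channel_labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for s, code in self.events:
            if not 0 <= s < self.n_samples:
                raise ValueError(f"event {code!r} at sample {s} outside [0, {self.n_samples})")


@dataclass
class Montage:
    """Electrode labels with unit-sphere positions."""

    labels: list[str]
    positions: np.ndarray             # n x 3, each row unit length
    head_radius: float = 0.09         # meters

    def validate(self, require: Sequence[str] = ()) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels in montage")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage positions must be unit-normalized")
        missing = [r for r in require if r not in self.labels]
        if missing:
            raise ValueError(f"montage lacks required electrodes: {missing}")

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.labels.index(label)]


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

def _parse_vhdr(header_path: str) -> configparser.ConfigParser:
    cp = configparser.ConfigParser()
    cp.optionxform = str
    with open(header_path, "r", encoding="utf-8") as f:
        lines = [ln for ln in f if not ln.startswith(";")]
    # first line is the format banner, not INI
    cp.read_string("".join(ln for ln in lines if not ln.startswith("Brain Vision")))
    return cp


def read_brainvision(header_path: str) -> Recording:
    """Read a BrainVision .vhdr/.vmrk/.eeg triplet into a :class:`Recording`.

    Supports multiplexed INT_16 (scaled by per-channel resolution) and
    IEEE_FLOAT_32 binary data; anything else raises
    :class:`UnsupportedDialectError` rather than misreading silently.
    """
    if not os.path.exists(header_path):
        raise FileNotFoundError(header_path)
    cp = _parse_vhdr(header_path)
    common = cp["Common Infos"]
    base = os.path.dirname(os.path.abspath(header_path))
    for key in ("DataFile", "MarkerFile"):
        companion = os.path.join(base, common[key])
        if not os.path.exists(companion):
            raise FileNotFoundError(f"{key} named by header is missing: {companion}")
    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation != "MULTIPLEXED":
        raise UnsupportedDialectError(f"unsupported DataOrientation {orientation!r}")
    fmt = cp["Binary Infos"]["BinaryFormat"].upper()
    if fmt not in ("INT_16", "IEEE_FLOAT_32"):
        raise UnsupportedDialectError(f"unsupported BinaryFormat {fmt!r}")

    # Delegate the actual decode to MNE, then convert V -> uV.
    import mne

    raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6
    sfreq = float(raw.info["sfreq"])
    events: list[tuple[int, str]] = []
    for ann in raw.annotations:
        desc = ann["description"]
        if "/" in desc:
            kind, code = desc.split("/", 1)
        else:
            kind, code = "", desc
        if kind == "New Segment":
            continue
        events.append((int(round(ann["onset"] * sfreq)), code))
    labels = list(raw.ch_names)
    kinds = ["eog" if lab in EOG_LABELS or "EOG" in lab.upper() else "scalp" for lab in labels]
    rec = Recording(labels, kinds, sfreq, np.asarray(data, dtype=np.float64),
                    events, meta={"source": os.path.abspath(header_path)})
    rec.validate()
    return rec


def write_brainvision(rec: Recording, basepath: str,
                      binary_format: str = "IEEE_FLOAT_32",
                      resolution: float = 0.1) -> tuple[str, str, str]:
    """Write *rec* as a BrainVision triplet ``basepath + {.vhdr,.vmrk,.eeg}``.

    ``binary_format`` is IEEE_FLOAT_32 (default) or INT_16; INT_16 stores
    ``round(value / resolution)`` with the resolution recorded per channel,
    so values quantize to ``resolution`` microvolts.
    """
    rec.validate()
    binary_format = binary_format.upper()
    if binary_format not in ("INT_16", "IEEE_FLOAT_32"):
        raise UnsupportedDialectError(f"unsupported BinaryFormat {binary_format!r}")
    base = os.path.basename(basepath)
    vhdr, vmrk, eeg = (basepath + ext for ext in (".vhdr", ".vmrk", ".eeg"))

    if binary_format == "IEEE_FLOAT_32":
        payload = rec.data.T.astype("<f4").tobytes()
        res_field = "1"
    else:
        q = np.round(rec.data / resolution)
        if np.abs(q).max(initial=0) > 32767:
            raise ValueError("data exceed INT_16 range at this resolution")
        payload = q.T.astype("<i2").tobytes()
        res_field = repr(resolution)

    sampling_interval_us = 1e6 / rec.sampling_rate
    with open(vhdr, "w", encoding="utf-8") as f:
        f.write("Brain Vision Data Exchange Header File Version 1.0\n")
        f.write("; Written by errmon\n\n[Common Infos]\nCodepage=UTF-8\n")
        f.write(f"DataFile={base}.eeg\nMarkerFile={base}.vmrk\n")
        f.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        f.write(f"NumberOfChannels={len(rec.channel_labels)}\n")
        f.write(f"SamplingInterval={sampling_interval_us:g}\n\n")
        f.write(f"[Binary Infos]\nBinaryFormat={binary_format}\n\n[Channel Infos]\n")
        for i, lab in enumerate(rec.channel_labels, start=1):
            f.write(f"Ch{i}={lab},,{res_field},µV\n")

    with open(vmrk, "w", encoding="utf-8") as f:
        f.write("Brain Vision Data Exchange Marker File, Version 1.0\n\n")
        f.write(f"[Common Infos]\nCodepage=UTF-8\nDataFile={base}.eeg\n\n[Marker Infos]\n")
        f.write("Mk1=New Segment,,1,1,0,0\n")
        for k, (sample, code) in enumerate(rec.events, start=2):
            mtype = "Stimulus" if code.startswith("S") else (
                "Response" if code.startswith("R") else "Comment")
            f.write(f"Mk{k}={mtype},{code},{sample + 1},1,0\n")

    with open(eeg, "wb") as f:
        f.write(payload)
    return vhdr, vmrk, eeg


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def read_montage(path: str, head_radius: float = 0.09,
                 require: Sequence[str] = ()) -> Montage:
    """Read a montage TSV with columns (label, x, y, z) or (label, theta, phi).

    Cartesian rows are normalized to the unit sphere; spherical rows use
    polar angle theta (degrees from +z) and azimuth phi (degrees from +x).
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if {"x", "y", "z"}.issubset(cols):
        pos = df[["x", "y", "z"]].to_numpy(dtype=float)
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length electrode position")
        pos = pos / norms[:, None]
    elif {"theta", "phi"}.issubset(cols):
        th = np.deg2rad(df["theta"].to_numpy(dtype=float))
        ph = np.deg2rad(df["phi"].to_numpy(dtype=float))
        pos = np.column_stack([np.sin(th) * np.cos(ph),
                               np.sin(th) * np.sin(ph),
                               np.cos(th)])
    else:
        raise ValueError("montage needs columns label,x,y,z or label,theta,phi")
    mont = Montage(list(df["label"].astype(str)), pos, head_radius=head_radius)
    mont.validate(require=require)
    return mont


def load_default_montage(head_radius: float = 0.09) -> Montage:
    """The packaged 61-electrode 10-10 montage (includes FCz and Cz)."""
    with resources.as_file(resources.files("errmon.data") / "montage_61ch.tsv") as p:
        return read_montage(str(p), head_radius=head_radius, require=("FCz", "Cz"))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_trial_table(trials: pd.DataFrame, path: str) -> None:
    trials.to_csv(path, sep="\t", index=False, na_rep="")


def read_trial_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "category"]
    if missing:
        raise ValueError(f"trial table lacks columns: {missing}")
    if "category" not in df.columns:
        df["category"] = ""
    df["category"] = df["category"].fillna("")
    return df


def write_subject_meta(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False, na_rep="")


def read_subject_meta(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Flat key-value run configuration
# ---------------------------------------------------------------------------

def write_config(cfg: dict, path: str) -> None:
    """Write a flat ``key = value`` config; nested keys use dots."""
    with open(path, "w", encoding="utf-8") as f:
        for k in sorted(cfg):
            f.write(f"{k} = {cfg[k]}\n")


def read_config(path: str) -> dict:
    cfg: dict = {}
    with open(path, "r", encoding="utf-8") as f:
        for ln in f:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            if "=" not in ln:
                raise ValueError(f"malformed config line: {ln!r}")
            k, v = (s.strip() for s in ln.split("=", 1))
            cfg[k] = _coerce(v)
    return cfg


def _coerce(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    if v.lower() in ("true", "false"):
        return v.lower() == "true"
    return v
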