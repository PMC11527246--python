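"""Continuous-recording I/O and electrode-grid geometry.

Recordings travel as BrainVision triplets (``.vhdr``/``.vmrk``/``.eeg``,
multiplexed IEEE float32, microvolt resolution), optionally arranged in an
EEG-BIDS-style directory layout.  The built-in montages describe the
17-electrode spinal grids used for electrospinography: a midline column of
five electrodes at 2 cm vertical spacing (the third being the anatomical
target over the spinal cord), flanking columns of four electrodes at
±1 cm, and outer columns of two electrodes at ±5 cm.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChannelInfo",
    "Recording",
    "MontageSpec",
    "FormatError",
    "read_recording",
    "write_recording",
    "builtin_montage",
    "montage_to_tsv",
    "montage_from_tsv",
    "grid_adjacency",
]

ROLES = ("esg", "eeg", "ecg", "eng", "other")
PATCHES = ("cervical", "lumbar", "none")


class FormatError(RuntimeError):
    """Raised when an on-disk recording is malformed or incomplete."""


@dataclass
class ChannelInfo:
    """Metadata for one channel: label, functional role, patch, grid position."""

    label: str
    role: str = "other"
    patch: str = "none"
    position: tuple[float, float] | None = None  # (x, y) in cm, grid frame

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.patch not in PATCHES:
            raise ValueError(f"unknown patch {self.patch!r}")


@dataclass
class Recording:
    """A continuous multichannel signal in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : list of ChannelInfo
        Per-channel metadata, in row order of ``data``.
    reference : str
        Label of the recording reference.
    events : list of (int, str)
        Stimulus/annotation markers as (0-based sample index, code).
    """

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    reference: str = ""
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel metadata does not match data rows")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        for s, _ in self.events:
            if not 0 <= s < self.n_samples:
                raise ValueError(f"event sample {s} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def ch_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None

    def pick(self, labels: list[str]) -> "Recording":
        """Sub-recording with the given channels, in the given order."""
        idx = [self.ch_index(lab) for lab in labels]
        return Recording(
            self.data[idx].copy(),
            self.fs,
            [replace(self.channels[i]) for i in idx],
            self.reference,
            list(self.events),
        )

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(),
            self.fs,
            [replace(c) for c in self.channels],
            self.reference,
            list(self.events),
        )

    def event_samples(self, code: str | None = None) -> np.ndarray:
        """Sample indices of events, optionally restricted to one code."""
        return np.array(
            [s for s, c in self.events if code is None or c == code], dtype=int
        )


@dataclass
class MontageSpec:
    """An electrode-grid geometry: labels, patches and planar positions in cm."""

    name: str
    electrodes: list[tuple[str, str, float, float]]  # (label, patch, x, y)
    target_label: str
    reference_label: str

    @property
    def labels(self) -> list[str]:
        return [e[0] for e in self.electrodes]

    @property
    def positions(self) -> dict[str, tuple[float, float]]:
        return {lab: (x, y) for lab, _, x, y in self.electrodes}

    def channel_infos(self, role: str = "esg") -> list[ChannelInfo]:
        return [
            ChannelInfo(lab, role=role, patch=patch, position=(x, y))
            for lab, patch, x, y in self.electrodes
        ]


def _grid_electrodes(patch: str, target: str, prefix: str):
    """17-electrode grid: midline 5 @ 2 cm, ±1 cm columns of 4, ±5 cm columns of 2."""
    electrodes = []
    # midline column of five; third electrode is the anatomical target
    for i, y in enumerate((4.0, 2.0, 0.0, -2.0, -4.0)):
        lab = target if y == 0.0 else f"{prefix}M{i + 1}"
        electrodes.append((lab, patch, 0.0, y))
    # columns of four, 1 cm right/left of the midline, interleaved rows
    for side, x in (("R", 1.0), ("L", -1.0)):
        for j, y in enumerate((3.0, 1.0, -1.0, -3.0)):
            electrodes.append((f"{prefix}{side}1_{j + 1}", patch, x, y))
    # columns of two, 5 cm right/left
    for side, x in (("R", 5.0), ("L", -5.0)):
        for j, y in enumerate((1.0, -1.0)):
            electrodes.append((f"{prefix}{side}5_{j + 1}", patch, x, y))
    return electrodes


_BUILTIN = {
    "cervical": ("SC6", "C", "TH6"),
    "lumbar": ("L1", "LU", "TH6"),
}


def builtin_montage(name: str) -> MontageSpec:
    """Built-in spinal grid montage, ``"cervical"`` or ``"lumbar"``.

    Both grids hold exactly 17 electrodes around the spinal target electrode
    (SC6 over the sixth cervical vertebra, L1 over the first lumbar
    vertebra), referenced to TH6.
    """
    try:
        target, prefix, ref = _BUILTIN[name]
    except KeyError:
        raise KeyError(f"unknown montage {name!r}; choose from {sorted(_BUILTIN)}")
    return MontageSpec(name, _grid_electrodes(name, target, prefix), target, ref)


def montage_to_tsv(montage: MontageSpec, path: str) -> None:
    with open(path, "w", encoding="utf-8") as f:
        f.write("label\tpatch\tx_cm\ty_cm\n")
        for lab, patch, x, y in montage.electrodes:
            f.write(f"{lab}\t{patch}\t{x:g}\t{y:g}\n")


def montage_from_tsv(path: str, name: str = "", target_label: str = "",
                     reference_label: str = "") -> MontageSpec:
    electrodes = []
    with open(path, encoding="utf-8") as f:
        header = f.readline()
        if not header.startswith("label"):
            raise FormatError("montage TSV must start with a 'label...' header")
        for line in f:
            if not line.strip():
                continue
            lab, patch, x, y = line.rstrip("\n").split("\t")
            electrodes.append((lab, patch, float(x), float(y)))
    return MontageSpec(name or os.path.basename(path), electrodes,
                       target_label, reference_label)


def grid_adjacency(montage: MontageSpec, max_dist_cm: float = 2.5) -> np.ndarray:
    """Boolean channel-adjacency matrix: neighbours within ``max_dist_cm``.

    The default of 2.5 cm links the 1 cm and 2 cm neighbours of the grid;
    the outer ±5 cm columns (whose nearest neighbours sit 4 cm away) remain
    isolated islands.  Analyses restricted to the three central columns are
    unaffected; the cluster test warns when an adjacency has islands.
    """
    pos = np.array([(x, y) for _, _, x, y in montage.electrodes])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d <= max_dist_cm) & (d > 0)
    return adj


# ---------------------------------------------------------------------------
# BrainVision triplet I/O


def write_recording(rec: Recording, path: str) -> None:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg).

    ``path`` names the header file (with or without the ``.vhdr`` suffix);
    the data payload is multiplexed IEEE float32 in microvolts and markers
    are written 1-based as the format requires.
    """
    base, ext = os.path.splitext(path)
    if ext not in ("", ".vhdr"):
        raise ValueError("path must name the .vhdr header")
    stem = os.path.basename(base)
    os.makedirs(os.path.dirname(base) or ".", exist_ok=True)
    with open(base + ".vhdr", "w", encoding="utf-8") as f:
        f.write("Brain Vision Data Exchange Header File Version 1.0\n")
        f.write("[Common Infos]\nCodepage=UTF-8\n")
        f.write(f"DataFile={stem}.eeg\nMarkerFile={stem}.vmrk\n")
        f.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        f.write(f"NumberOfChannels={rec.n_channels}\n")
        f.write(f"SamplingInterval={1e6 / rec.fs:.10g}\n")
        f.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n")
        f.write("[Channel Infos]\n")
        for i, ch in enumerate(rec.channels):
            f.write(f"Ch{i + 1}={ch.label},,1,µV\n")
    with open(base + ".vmrk", "w", encoding="utf-8") as f:
        f.write("Brain Vision Data Exchange Marker File, Version 1.0\n")
        f.write(f"[Common Infos]\nCodepage=UTF-8\nDataFile={stem}.eeg\n")
        f.write("[Marker Infos]\n")
        f.write("Mk1=New Segment,,1,1,0,00000000000000000000\n")
        for k, (sample, code) in enumerate(rec.events):
            typ, _, desc = code.partition("/")
            if not desc:
                typ, desc = "Stimulus", typ
            f.write(f"Mk{k + 2}={typ},{desc},{sample + 1},1,0\n")
    payload = np.ascontiguousarray(rec.data.T, dtype=np.float32)
    payload.tofile(base + ".eeg")


def _find_bids_vhdr(root: str) -> str:
    hits = []
    for dirpath, _, files in os.walk(root):
        hits.extend(os.path.join(dirpath, f) for f in files if f.endswith(".vhdr"))
    if not hits:
        raise FormatError(f"no .vhdr found under {root}")
    if len(hits) > 1:
        raise FormatError(f"ambiguous BIDS layout: {len(hits)} headers under {root}")
    return hits[0]


def read_recording(
    path: str,
    dialect: str = "brainvision",
    roles: dict[str, tuple[str, str]] | None = None,
    montage: MontageSpec | None = None,
) -> Recording:
    """Read a BrainVision triplet (or a BIDS directory holding one).

    Parameters
    ----------
    path
        Header file for ``dialect="brainvision"``; dataset directory for
        ``dialect="bids"`` (the single ``.vhdr`` underneath is located).
    roles
        Optional map label -> (role, patch) assigning channel semantics that
        the BrainVision format itself does not carry.
    montage
        Optional grid geometry; matching labels receive their position.
    """
    import mne

    if dialect == "bids":
        path = _find_bids_vhdr(path)
    elif dialect != "brainvision":
        raise ValueError(f"unknown dialect {dialect!r}")
    if not os.path.exists(path):
        raise FormatError(f"missing header {path}")
    base = os.path.splitext(path)[0]
    for sib in (".vmrk", ".eeg"):
        if not os.path.exists(base + sib):
            raise FormatError(f"missing sibling file {base + sib}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    # mne works in volts; snap back to the float32 payload grid so the
    # microvolt round trip is bit-exact
    data = (raw.get_data() * 1e6).astype(np.float32).astype(float)
    if not np.isfinite(data).all():
        raise FormatError("non-finite samples after ingestion")
    positions = montage.positions if montage is not None else {}
    channels = []
    for lab in raw.ch_names:
        role, patch = (roles or {}).get(lab, ("other", "none"))
        channels.append(ChannelInfo(lab, role=role, patch=patch,
                                    position=positions.get(lab)))
    events = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("New Segment"):
            continue
        events.append((int(round(ann["onset"] * fs)), desc))
    events.sort()
    return Recording(data, fs, channels, reference="", events=events)
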