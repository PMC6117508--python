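"""Core containers and readers for volumes, motion files, events and EEG.

Conventions used throughout the toolbox:

* voxel indices and time indices are 0-based;
* event times are seconds from recording start;
* intervals (bad blocks, windows) are half-open ``[start, end)``;
* EEG signals are stored in microvolts;
* the repetition time (TR) is taken from the NIfTI header (``pixdim[4]``)
  unless the caller overrides it — the override always wins, because
  headers written by conversion tools are frequently wrong, and Analyze
  images carry no reliable TR at all.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ContractError, FormatError

__all__ = [
    "Volume4D",
    "BrainMask",
    "MotionParams",
    "EventTable",
    "EEGRecording",
    "read_volume4d",
    "write_volume3d",
    "write_volume4d",
    "read_motion_params",
    "write_motion_params",
    "read_events_tsv",
    "write_events_tsv",
    "read_eeg",
    "write_eeg_edf",
    "write_eeg_brainvision",
    "auto_brain_mask",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Volume4D:
    """A 4-D BOLD grid indexed ``(x, y, z, t)`` with acquisition metadata.

    ``tr_seconds`` is the sampling interval of the time axis.  A plain 3-D
    image is represented with ``t = 1``; operations that need a time series
    must check :attr:`is_timeseries` and reject such volumes.
    """

    data: np.ndarray
    tr_seconds: float
    voxel_size_mm: np.ndarray
    affine: np.ndarray
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ContractError(
                f"Volume4D expects 3-D or 4-D data, got {self.data.ndim}-D"
            )
        if not self.tr_seconds > 0:
            raise ContractError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float).reshape(3)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]

    @property
    def is_timeseries(self) -> bool:
        return self.n_vols >= 2

    def require_timeseries(self, op: str = "this operation") -> None:
        if not self.is_timeseries:
            raise ContractError(
                f"{op} needs a 4-D time series (t >= 2); this volume has t = "
                f"{self.n_vols}"
            )

    def with_data(self, data: np.ndarray) -> "Volume4D":
        """Copy of this volume with ``data`` replaced, metadata preserved."""
        return dataclasses.replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass
class BrainMask:
    """Boolean in-brain flags on a 3-D grid."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 3:
            raise ContractError(f"BrainMask must be 3-D, got {self.flags.ndim}-D")

    @property
    def count(self) -> int:
        return int(self.flags.sum())

    def check_compatible(self, vol: Volume4D) -> None:
        if self.flags.shape != vol.shape3d:
            raise ContractError(
                f"mask shape {self.flags.shape} != volume grid {vol.shape3d}"
            )
        if self.count < 1:
            raise ContractError("mask is empty")


@dataclass
class MotionParams:
    """Rigid-body realignment series: T rows of [X, Y, Z, pitch, yaw, roll].

    Translations in mm, rotations in radians — the layout of realignment
    "rp_*.txt" files.
    """

    series: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=np.float64))
        if self.series.shape[1] != 6:
            raise ContractError(
                f"motion series must have 6 columns, got {self.series.shape[1]}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]


_EVENT_COLS = ["onset_s", "duration_s", "type"]


class EventTable:
    """Ordered table of (onset_s, duration_s, type) rows.

    Rows are kept sorted by onset (stable, so equal onsets preserve
    insertion order); duplicates are allowed.
    """

    def __init__(self, rows=None):
        if rows is None:
            df = pd.DataFrame(columns=_EVENT_COLS)
        elif isinstance(rows, pd.DataFrame):
            df = rows[_EVENT_COLS].copy()
        else:
            df = pd.DataFrame(list(rows), columns=_EVENT_COLS)
        df["onset_s"] = df["onset_s"].astype(float)
        df["duration_s"] = df["duration_s"].astype(float)
        df["type"] = df["type"].astype(str)
        if (df["onset_s"] < 0).any():
            raise ContractError("event onsets must be >= 0")
        if (df["duration_s"] < 0).any():
            raise ContractError("event durations must be >= 0")
        self._df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def onsets(self) -> np.ndarray:
        return self._df["onset_s"].to_numpy()

    @property
    def durations(self) -> np.ndarray:
        return self._df["duration_s"].to_numpy()

    @property
    def types(self) -> np.ndarray:
        return self._df["type"].to_numpy()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self._df.equals(other._df)

    def rows(self) -> list[tuple[float, float, str]]:
        return list(self._df.itertuples(index=False, name=None))

    def select(self, types) -> "EventTable":
        """Rows whose type is in ``types`` (any iterable of strings)."""
        wanted = {str(t) for t in types}
        return EventTable(self._df[self._df["type"].isin(wanted)])


@dataclass
class EEGRecording:
    """Multichannel EEG: a channels x samples matrix in microvolts."""

    signals: np.ndarray
    srate_hz: float
    channel_labels: list[str]
    events: EventTable = field(default_factory=EventTable)
    bad_blocks: list[tuple[float, float]] = field(default_factory=list)
    reference: str = "original"

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=np.float64))
        if not self.srate_hz > 0:
            raise ContractError("srate_hz must be > 0")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ContractError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signals.shape[0]} channels"
            )
        dur = self.duration_s
        for start, end in self.bad_blocks:
            if not (0 <= start < end):
                raise ContractError(f"bad block [{start}, {end}) is ill-formed")
            if start >= dur:
                raise ContractError(f"bad block [{start}, {end}) outside recording")
        if len(self.events) and self.events.onsets.max() > dur:
            raise ContractError("event onset beyond end of recording")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ContractError(
                f"unknown channel {label!r}; available: {self.channel_labels}"
            ) from None


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def read_volume4d(path, tr: float | None = None, space_tag: str = "") -> Volume4D:
    """Read a NIfTI-1 or Analyze image as a :class:`Volume4D`.

    TR is taken from the header unless ``tr`` is given; a header TR that is
    missing or nonpositive *requires* the override (Analyze images in
    particular carry no trustworthy TR).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several classes here
        raise FormatError(f"cannot read {path} as NIfTI/Analyze: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected 3-D or 4-D image, got {data.ndim}-D")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) >= 4 else 0.0
    if tr is not None:
        tr_seconds = float(tr)
    elif header_tr > 0:
        tr_seconds = header_tr
    else:
        raise FormatError(
            f"{path}: header field pixdim[4] (TR) is {header_tr!r}; pass tr= "
            "explicitly (Analyze images have no reliable TR)"
        )
    return Volume4D(
        data=data,
        tr_seconds=tr_seconds,
        voxel_size_mm=np.asarray(zooms[:3], dtype=float),
        affine=np.asarray(img.affine, dtype=float),
        space_tag=space_tag,
    )


def write_volume3d(map3d: np.ndarray, reference_affine: np.ndarray, path) -> Path:
    """Write a 3-D map as NIfTI-1; NaN (e.g. outside-mask) values survive."""
    map3d = np.asarray(map3d, dtype=np.float64)
    if map3d.ndim != 3:
        raise ContractError(f"expected a 3-D map, got {map3d.ndim}-D")
    affine = np.asarray(reference_affine, dtype=float)
    if affine.shape != (4, 4):
        raise ContractError(f"affine must be 4x4, got {affine.shape}")
    path = Path(path)
    nib.Nifti1Image(map3d, affine).to_filename(str(path))
    return path


def write_volume4d(vol: Volume4D, path) -> Path:
    """Write a :class:`Volume4D` as NIfTI-1, recording TR in pixdim[4]."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data, vol.affine)
    zooms = list(vol.voxel_size_mm) + [vol.tr_seconds]
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    img.to_filename(str(path))
    return path


# ---------------------------------------------------------------------------
# motion parameters
# ---------------------------------------------------------------------------


def read_motion_params(path) -> MotionParams:
    """Read a whitespace-delimited T x 6 realignment text file.

    The dialect is strict: six numeric columns, no header line.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such motion file: {path}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                values = [float(p) for p in parts]
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric token (headers are not "
                    "accepted in rp motion files)"
                ) from None
            if len(values) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 columns, got {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise FormatError(f"{path}: empty motion file")
    return MotionParams(np.asarray(rows, dtype=np.float64))


def write_motion_params(motion: MotionParams, path) -> Path:
    path = Path(path)
    np.savetxt(path, motion.series, fmt="%.10e")
    return path


# ---------------------------------------------------------------------------
# event tables (BIDS-style TSV)
# ---------------------------------------------------------------------------


def read_events_tsv(path) -> EventTable:
    """Read a TSV with columns onset, duration, trial_type."""
    df = pd.read_csv(path, sep="\t")
    missing = {"onset", "duration", "trial_type"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing event columns {sorted(missing)}")
    return EventTable(
        df.rename(
            columns={"onset": "onset_s", "duration": "duration_s",
                     "trial_type": "type"}
        )[_EVENT_COLS]
    )


def write_events_tsv(events: EventTable, path) -> Path:
    path = Path(path)
    df = events.frame.rename(
        columns={"onset_s": "onset", "duration_s": "duration", "type": "trial_type"}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------


def _events_from_annotations(annotations) -> EventTable:
    rows = []
    for onset, duration, desc in zip(
        annotations.onset, annotations.duration, annotations.description
    ):
        desc = str(desc)
        if desc.startswith("New Segment"):
            continue
        # BrainVision markers arrive as "Stimulus/1001" etc.
        if "/" in desc:
            desc = desc.rsplit("/", 1)[1]
        rows.append((float(onset), float(duration), desc.strip()))
    return EventTable(rows)


def read_eeg(path) -> EEGRecording:
    """Read an EDF file or a BrainVision triplet into an :class:`EEGRecording`.

    Signals are returned in microvolts; annotations/markers populate the
    event table with onsets in seconds from recording start.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such EEG file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".edf", ".bdf"):
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        elif suffix == ".vhdr":
            for companion in (".vmrk", ".eeg"):
                # header names the companions, but the common failure is a
                # missing sibling file, so check eagerly for a clear error
                if not path.with_suffix(companion).exists():
                    raise FormatError(
                        f"{path}: BrainVision companion {companion} file missing"
                    )
            raw = mne.io.read_raw_brainvision(str(path), preload=True,
                                              verbose="error")
        else:
            raise FormatError(
                f"{path}: unsupported EEG format {suffix!r} "
                "(EDF and BrainVision are supported)"
            )
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read EEG file {path}: {exc}") from exc
    signals_uv = raw.get_data() * 1e6  # MNE holds volts internally
    return EEGRecording(
        signals=signals_uv,
        srate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=_events_from_annotations(raw.annotations),
        reference="original",
    )


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_eeg_edf(eeg: EEGRecording, path) -> Path:
    """Write an EDF+C file (16-bit samples plus a TAL annotations channel).

    A minimal writer for fixture generation: one-second data records, so
    the sampling rate must be a positive integer.  Event onsets/types are
    stored as EDF+ annotations in the record containing the onset.
    """
    path = Path(path)
    srate = eeg.srate_hz
    if abs(srate - round(srate)) > 1e-9 or srate < 1:
        raise ContractError("EDF writer needs an integer sampling rate")
    srate = int(round(srate))
    n_records = int(np.ceil(eeg.n_samples / srate))
    total = n_records * srate
    padded = np.zeros((eeg.n_channels, total))
    padded[:, : eeg.n_samples] = eeg.signals
    # physical scaling: symmetric range covering the data
    phys_max = float(np.ceil(max(np.abs(padded).max() * 1.01, 1.0)))
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * scale + dig_min).astype("<i2")

    # annotations: one TAL stream per record
    ann_per_record: list[bytes] = []
    events_by_record: dict[int, list] = {}
    for onset, duration, etype in eeg.events.rows():
        events_by_record.setdefault(int(onset // 1), []).append(
            (onset, duration, etype)
        )
    ann_samples = 0
    for rec in range(n_records):
        tal = f"+{rec}\x14\x14\x00".encode("ascii")
        for onset, duration, etype in events_by_record.get(rec, []):
            entry = f"+{onset:g}"
            if duration > 0:
                entry += f"\x15{duration:g}"
            entry += f"\x14{etype}\x14\x00"
            tal += entry.encode("utf-8")
        ann_per_record.append(tal)
        ann_samples = max(ann_samples, (len(tal) + 1) // 2)
    ann_samples = max(ann_samples, 8)

    ns = eeg.n_channels + 1  # + annotations channel
    header_bytes = 256 * (1 + ns)
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))
        fh.write(_edf_field("Startdate X X X X", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(header_bytes, 8))
        fh.write(_edf_field("EDF+C", 44))
        fh.write(_edf_field(n_records, 8))
        fh.write(_edf_field(1, 8))  # record duration, seconds
        fh.write(_edf_field(ns, 4))
        labels = list(eeg.channel_labels) + ["EDF Annotations"]
        for lab in labels:
            fh.write(_edf_field(lab, 16))
        for _ in labels:
            fh.write(_edf_field("", 80))  # transducer
        for i in range(ns):
            fh.write(_edf_field("uV" if i < eeg.n_channels else "", 8))
        for i in range(ns):
            fh.write(_edf_field(f"{phys_min:g}" if i < eeg.n_channels else -1, 8))
        for i in range(ns):
            fh.write(_edf_field(f"{phys_max:g}" if i < eeg.n_channels else 1, 8))
        for i in range(ns):
            fh.write(_edf_field(dig_min, 8))
        for i in range(ns):
            fh.write(_edf_field(dig_max, 8))
        for _ in range(ns):
            fh.write(_edf_field("", 80))  # prefiltering
        for i in range(ns):
            fh.write(_edf_field(srate if i < eeg.n_channels else ann_samples, 8))
        for _ in range(ns):
            fh.write(_edf_field("", 32))
        for rec in range(n_records):
            fh.write(digital[:, rec * srate:(rec + 1) * srate].tobytes())
            tal = ann_per_record[rec]
            fh.write(tal.ljust(2 * ann_samples, b"\x00"))
    return path


def write_eeg_brainvision(eeg: EEGRecording, vhdr_path) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk text + float32 .eeg).

    Events become Stimulus markers; marker positions are 1-based sample
    indices per the format.
    """
    vhdr_path = Path(vhdr_path)
    if vhdr_path.suffix != ".vhdr":
        raise ContractError("BrainVision header path must end in .vhdr")
    stem = vhdr_path.stem
    eeg_path = vhdr_path.with_suffix(".eeg")
    vmrk_path = vhdr_path.with_suffix(".vmrk")
    interval_us = 1e6 / eeg.srate_hz
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={eeg.n_channels}",
        f"SamplingInterval={interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(eeg.channel_labels, start=1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (onset, duration, etype) in enumerate(eeg.events.rows(), start=2):
        pos = int(round(onset * eeg.srate_hz)) + 1
        size = max(int(round(duration * eeg.srate_hz)), 1)
        mlines.append(f"Mk{k}=Stimulus,{etype},{pos},{size},0")
    vmrk_path.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    eeg.signals.T.astype("<f4").tofile(eeg_path)  # multiplexed: sample-major
    return vhdr_path


# ---------------------------------------------------------------------------
# automatic brain mask
# ---------------------------------------------------------------------------


def auto_brain_mask(vol: Volume4D, fraction: float = 0.2) -> BrainMask:
    """Threshold the temporal-mean image at ``fraction`` of its maximum.

    A voxel is in-brain iff its temporal mean exceeds
    ``fraction * max(temporal mean)``.  Monotone: a higher fraction always
    yields a subset mask.
    """
    if not 0 < fraction < 1:
        raise ContractError(f"fraction must be in (0, 1), got {fraction}")
    mean_img = vol.data.mean(axis=3)
    flags = mean_img > fraction * mean_img.max()
    if not flags.any():
        raise ContractError(
            f"auto_brain_mask produced an empty mask at fraction={fraction}; "
            "try a lower fraction"
        )
    return BrainMask(flags)
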