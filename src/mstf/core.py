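"""Domain containers and serialization for microstate analysis.

The package works in microvolts throughout, with time in milliseconds and
stimulus onset at 0 ms.  Epochs are stored as ``(epoch, channel, time)``
arrays; sample *i* of an epoch sits at ``t0_offset_ms + i * 1000 / srate``.
Label sequences use sample indices internally and milliseconds only at I/O
boundaries.

The native epoch store is a directory holding a JSON sidecar (metadata) and
a raw ``.npy`` array payload, giving bitwise round-trips without committing
to a vendor format.  EDF and BrainVision files are read through MNE when it
is installed (``pip install mstf[io]``).
"""

from __future__ import annotations

import json
import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelInfo",
    "EpochSet",
    "Topography",
    "TemplateSet",
    "LabelSequence",
    "FeatureTable",
    "FormatError",
    "DataError",
    "normalize_map",
    "load_epochs",
    "save_epochs",
    "save_templates",
    "load_templates",
    "save_labels",
    "load_labels",
    "save_feature_table",
    "load_feature_table",
]

BANDS = ("original", "delta", "theta", "alpha", "beta")


class FormatError(ValueError):
    """Malformed or unrecognized on-disk data."""


class DataError(ValueError):
    """Structurally valid input whose values are unusable (NaN/Inf, empty)."""


def normalize_map(v: np.ndarray) -> np.ndarray:
    """Return ``v`` re-referenced to zero mean and scaled to unit L2 norm."""
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise DataError("cannot normalize a flat (zero-variance) map")
    return v / nrm


@dataclass(frozen=True)
class ChannelInfo:
    """Ordered channel labels with an EOG mask.

    EOG channels are carried through the pipeline but excluded from GFP,
    artifact-rejection thresholds, clustering and backfitting.
    """

    labels: tuple
    eog_mask: tuple

    def __init__(self, labels: Sequence[str], eog_mask: Sequence[bool] | None = None):
        labels = tuple(str(x) for x in labels)
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if eog_mask is None:
            eog_mask = tuple(lbl.upper().startswith(("EOG", "HEOG", "VEOG")) for lbl in labels)
        else:
            eog_mask = tuple(bool(x) for x in eog_mask)
        if len(eog_mask) != len(labels):
            raise ValueError("eog_mask length must equal the number of channels")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "eog_mask", eog_mask)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def scalp_indices(self) -> np.ndarray:
        """Indices of non-EOG channels, in recording order."""
        return np.flatnonzero(~np.asarray(self.eog_mask, dtype=bool))


@dataclass
class EpochSet:
    """Epoched multichannel potentials in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_times)
    srate : float
        Sampling rate in Hz.
    t0_offset_ms : float
        Time of the first sample relative to stimulus onset, in ms
        (e.g. -200 for a -200..+800 ms epoch).
    channels : ChannelInfo
    condition, band : str
        Free condition tag and frequency-band tag.
    epoch_ids : sequence of str, optional
    """

    data: np.ndarray
    srate: float
    t0_offset_ms: float
    channels: ChannelInfo
    condition: str = ""
    band: str = "original"
    epoch_ids: tuple = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epoch, channel, time)")
        if self.data.shape[1] != self.channels.n_channels:
            raise ValueError("data channel axis does not match ChannelInfo")
        if not np.isfinite(self.data).all():
            raise DataError("epoch data contains NaN or Inf")
        if not self.srate > 0:
            raise ValueError("srate must be positive")
        if not self.epoch_ids:
            self.epoch_ids = tuple(f"ep{i:04d}" for i in range(self.data.shape[0]))
        else:
            self.epoch_ids = tuple(str(x) for x in self.epoch_ids)
        if len(self.epoch_ids) != self.data.shape[0]:
            raise ValueError("epoch_ids length must equal the number of epochs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_offset_ms + np.arange(self.n_times) * (1000.0 / self.srate)

    def sample_at(self, t_ms: float) -> int:
        """Nearest sample index to a time in ms."""
        return int(round((t_ms - self.t0_offset_ms) * self.srate / 1000.0))

    def window_slice(self, window_ms: tuple) -> slice:
        """Half-open sample slice covering ``[lo, hi)`` ms."""
        lo = max(0, self.sample_at(window_ms[0]))
        hi = min(self.n_times, self.sample_at(window_ms[1]))
        return slice(lo, hi)

    def permute_channels(self, order: Sequence[int]) -> "EpochSet":
        order = list(order)
        ch = ChannelInfo(
            [self.channels.labels[i] for i in order],
            [self.channels.eog_mask[i] for i in order],
        )
        return EpochSet(self.data[:, order, :], self.srate, self.t0_offset_ms, ch,
                        self.condition, self.band, self.epoch_ids)

    def copy_with(self, **kw) -> "EpochSet":
        base = dict(data=self.data, srate=self.srate, t0_offset_ms=self.t0_offset_ms,
                    channels=self.channels, condition=self.condition, band=self.band,
                    epoch_ids=self.epoch_ids)
        base.update(kw)
        return EpochSet(**base)


@dataclass
class Topography:
    """A scalp map: one potential value per channel."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.normalized:
            if abs(self.values.mean()) > 1e-9 or abs(np.linalg.norm(self.values) - 1) > 1e-9:
                raise ValueError("map flagged normalized is not zero-mean unit-norm")

    def normalize(self) -> "Topography":
        return Topography(normalize_map(self.values), normalized=True)


@dataclass
class TemplateSet:
    """K normalized microstate template maps for one condition x band."""

    maps: np.ndarray  # (k, n_channels), each row zero-mean unit-norm
    condition: str = ""
    band: str = "original"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.maps.shape[0] < 1:
            raise ValueError("TemplateSet needs at least one template")
        means = self.maps.mean(axis=1)
        norms = np.linalg.norm(self.maps, axis=1)
        if np.abs(means).max() > 1e-8 or np.abs(norms - 1).max() > 1e-8:
            raise ValueError("templates must be zero-mean and unit-norm")
        if self.k > 1:
            # zero-mean unit-norm rows: pairwise dot == spatial Pearson r
            r = self.maps @ self.maps.T
            iu = np.triu_indices(self.k, 1)
            if np.any(np.isclose(np.abs(r[iu]), 1.0, atol=1e-12)):
                raise ValueError("two templates are identical up to sign")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def templates(self) -> list:
        return [Topography(row, normalized=True) for row in self.maps]


@dataclass
class LabelSequence:
    """Per-sample microstate assignment for one epoch (or grand average).

    ``labels`` holds template indices, with -1 meaning unassigned
    (zero-variance timepoint).  ``fit_r`` is the winning spatial Pearson
    correlation per sample.  ``corr`` optionally stores the full K x T
    correlation matrix produced by backfitting; the label smoother uses it
    to re-assign samples of rejected short runs.
    """

    labels: np.ndarray
    fit_r: np.ndarray
    srate: float
    t0_offset_ms: float = 0.0
    corr: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.fit_r = np.asarray(self.fit_r, dtype=float)
        if self.labels.shape != self.fit_r.shape:
            raise ValueError("labels and fit_r must have the same length")
        if self.corr is not None:
            self.corr = np.asarray(self.corr, dtype=float)
            if self.corr.shape[1] != self.labels.size:
                raise ValueError("corr must be (k, n_times)")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_offset_ms + np.arange(len(self)) * (1000.0 / self.srate)


class FeatureTable:
    """Observation x feature matrix with class labels and group ids.

    Thin wrapper over a pandas DataFrame; feature columns are every column
    except ``class_label`` and ``group_id`` and the ``absent__*`` flags.
    """

    RESERVED = ("class_label", "group_id")

    def __init__(self, frame: pd.DataFrame):
        if frame.columns.duplicated().any():
            raise ValueError("feature column names must be unique")
        for col in self.RESERVED:
            if col not in frame.columns:
                raise ValueError(f"FeatureTable requires a {col!r} column")
        feats = frame.drop(columns=list(self.RESERVED))
        if feats.isna().any().any():
            raise ValueError("feature table contains missing values")
        self.frame = frame.reset_index(drop=True)

    @property
    def feature_names(self) -> list:
        return [c for c in self.frame.columns
                if c not in self.RESERVED and not c.startswith("absent__")]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["class_label"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# Epoch store I/O
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path) -> None:
    """Write the native store: ``<path>/epochs.json`` + ``<path>/data.npy``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "srate": epochs.srate,
        "t0_offset_ms": epochs.t0_offset_ms,
        "condition": epochs.condition,
        "band": epochs.band,
        "labels": list(epochs.channels.labels),
        "eog_mask": [bool(x) for x in epochs.channels.eog_mask],
        "epoch_ids": list(epochs.epoch_ids),
    }
    (path / "epochs.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    np.save(path / "data.npy", epochs.data.astype(np.float64))


def _load_native(path: Path) -> EpochSet:
    meta_file = path / "epochs.json"
    if not meta_file.exists():
        raise FormatError(f"{path} is not a native epoch store (missing epochs.json)")
    meta = json.loads(meta_file.read_text())
    data = np.load(path / "data.npy")
    ch = ChannelInfo(meta["labels"], meta["eog_mask"])
    return EpochSet(data, meta["srate"], meta["t0_offset_ms"], ch,
                    meta["condition"], meta["band"], meta["epoch_ids"])


def _load_delimited(path: Path, srate: float, t0_offset_ms: float, delimiter: str = ",") -> EpochSet:
    """Read epochs from text: header ``epoch_id,<ch1>,...``, one row per sample."""
    txt = path.read_text().strip()
    if not txt:
        raise FormatError(f"{path} is empty")
    lines = txt.splitlines()
    header = [h.strip() for h in lines[0].split(delimiter)]
    if len(header) < 2 or header[0] != "epoch_id":
        raise FormatError("delimited epochs need an 'epoch_id' column followed by channels")
    labels = header[1:]
    by_epoch: dict = {}
    order: list = []
    for ln in lines[1:]:
        cells = ln.split(delimiter)
        if len(cells) != len(header):
            raise FormatError(f"row with {len(cells)} columns, expected {len(header)}")
        eid = cells[0].strip()
        if eid not in by_epoch:
            by_epoch[eid] = []
            order.append(eid)
        by_epoch[eid].append([float(c) for c in cells[1:]])
    lengths = {len(v) for v in by_epoch.values()}
    if len(lengths) != 1:
        raise FormatError("epochs have inconsistent sample counts")
    data = np.stack([np.asarray(by_epoch[e]).T for e in order])  # (ep, ch, t)
    if not np.isfinite(data).all():
        raise DataError("delimited epochs contain NaN or Inf")
    return EpochSet(data, srate, t0_offset_ms, ChannelInfo(labels), epoch_ids=order)


def save_epochs_delimited(epochs: EpochSet, path, delimiter: str = ",") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["epoch_id", *epochs.channels.labels])
        for e in range(epochs.n_epochs):
            for t in range(epochs.n_times):
                w.writerow([epochs.epoch_ids[e],
                            *(repr(float(v)) for v in epochs.data[e, :, t])])


def _load_mne(path: Path, reader: str) -> EpochSet:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError("reading EDF/BrainVision requires mne (pip install mstf[io])") from exc
    if reader == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    if not np.isfinite(data).all():
        raise DataError(f"{path} contains NaN or Inf")
    ch = ChannelInfo(raw.ch_names)
    # a continuous record is exposed as a single epoch starting at t = 0
    return EpochSet(data[np.newaxis], raw.info["sfreq"], 0.0, ch)


def load_epochs(path, format: str = "native", srate: float = 1000.0,
                t0_offset_ms: float = -200.0) -> EpochSet:
    """Load an :class:`EpochSet`.

    ``format`` is one of ``native``, ``delimited``, ``edf``, ``brainvision``.
    ``srate``/``t0_offset_ms`` apply to the delimited dialect only (the text
    format carries no timing metadata).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native":
        return _load_native(path)
    if format == "delimited":
        return _load_delimited(path, srate, t0_offset_ms)
    if format in ("edf", "brainvision"):
        return _load_mne(path, format)
    raise ValueError(f"unknown epoch format: {format!r}")


# ---------------------------------------------------------------------------
# Template / label / feature serialization
# ---------------------------------------------------------------------------

def save_templates(ts: TemplateSet, path) -> None:
    """JSON sidecar + ``.npy`` array payload next to it."""
    path = Path(path)
    payload = path.with_suffix(".npy")
    meta = {"k": ts.k, "condition": ts.condition, "band": ts.band,
            "meta": ts.meta, "payload": payload.name}
    path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    np.save(payload, ts.maps.astype(np.float64))


def load_templates(path) -> TemplateSet:
    path = Path(path)
    meta = json.loads(path.read_text())
    maps = np.load(path.parent / meta["payload"])
    ts = TemplateSet(maps, meta["condition"], meta["band"], meta["meta"])
    if ts.k != meta["k"]:
        raise FormatError("template payload does not match sidecar k")
    return ts


def save_labels(seq: LabelSequence, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ms", "label", "corr"])
        for t_ms, lab, r in zip(seq.times_ms, seq.labels, seq.fit_r):
            w.writerow([repr(float(t_ms)), int(lab), repr(float(r))])


def load_labels(path, srate: float) -> LabelSequence:
    rows = list(csv.reader(Path(path).open()))
    if rows and rows[0] == ["time_ms", "label", "corr"]:
        rows = rows[1:]
    if not rows:
        return LabelSequence(np.empty(0, int), np.empty(0), srate)
    times = np.array([float(r[0]) for r in rows])
    labels = np.array([int(r[1]) for r in rows])
    fit_r = np.array([float(r[2]) for r in rows])
    return LabelSequence(labels, fit_r, srate, t0_offset_ms=times[0])


def save_feature_table(ft: FeatureTable, path) -> None:
    ft.frame.to_csv(path, index=False)


def load_feature_table(path) -> FeatureTable:
    return FeatureTable(pd.read_csv(path))
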