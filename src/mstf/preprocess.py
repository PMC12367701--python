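"""Epoching, baseline correction, artifact rejection, referencing and band filters.

The default pipeline mirrors standard ERP practice: 0-30 Hz band-pass,
-200..+800 ms epochs baseline-corrected on -200..0 ms, +/-100 uV peak
rejection on non-EOG channels, and an average (mean) reference.  Frequency
splitting uses conventional band edges (delta 0.5-4, theta 4-8, alpha 8-13,
beta 13-30 Hz) applied with a zero-phase forward-backward 4th-order
Butterworth filter, so segment timing is preserved.

Eye-artifact correction by ICA is deliberately not reimplemented here; the
pipeline expects pre-cleaned data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import ChannelInfo, EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "BANDS",
    "RejectionReport",
    "epoch_and_baseline",
    "baseline_correct",
    "reject_artifacts",
    "average_reference",
    "bandpass",
    "split_bands",
]


@dataclass(frozen=True)
class BandSpec:
    """A named passband.  ``lo_hz = 0`` means a pure low-pass."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not (0 <= self.lo_hz < self.hi_hz):
            raise ValueError(f"invalid band edges {self.lo_hz}-{self.hi_hz}")


#: Conventional EEG band boundaries, compatible with a 0-30 Hz overall band-pass.
BANDS = {
    "original": BandSpec("original", 0.0, 30.0),
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
}


@dataclass
class RejectionReport:
    n_in: int
    n_rejected: int
    reasons: dict = field(default_factory=dict)  # epoch_id -> reason

    def __post_init__(self):
        if self.n_rejected > self.n_in:
            raise ValueError("cannot reject more epochs than supplied")


def epoch_and_baseline(continuous: np.ndarray, srate: float, channels: ChannelInfo,
                       events: list, window_ms: tuple = (-200.0, 800.0),
                       baseline_ms: tuple = (-200.0, 0.0),
                       condition: str = "") -> EpochSet:
    """Cut stimulus-locked epochs out of a continuous record and baseline them.

    Parameters
    ----------
    continuous : ndarray (n_channels, n_samples)
    events : list of int
        Stimulus-onset sample indices.  Events whose window falls outside the
        record are skipped and logged.
    window_ms, baseline_ms : (lo, hi)
        Epoch extent and baseline interval relative to onset, in ms.
    """
    continuous = np.asarray(continuous, dtype=float)
    lo = int(round(window_ms[0] * srate / 1000.0))
    hi = int(round(window_ms[1] * srate / 1000.0))
    n_samples = continuous.shape[1]
    epochs, kept = [], []
    for k, ev in enumerate(events):
        if ev + lo < 0 or ev + hi > n_samples:
            logger.warning("event at sample %d too close to record edge; skipped", ev)
            continue
        epochs.append(continuous[:, ev + lo:ev + hi])
        kept.append(f"ev{k:04d}")
    if not epochs:
        raise ValueError("no event window fits inside the record")
    es = EpochSet(np.stack(epochs), srate, window_ms[0], channels,
                  condition=condition, epoch_ids=kept)
    return baseline_correct(es, baseline_ms)


def baseline_correct(epochs: EpochSet, baseline_ms: tuple = (-200.0, 0.0)) -> EpochSet:
    """Subtract each channel's mean over the baseline interval."""
    sl = epochs.window_slice(baseline_ms)
    if sl.stop <= sl.start:
        raise ValueError("baseline interval contains no samples")
    base = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 100.0):
    """Drop epochs whose absolute potential exceeds ``threshold_uv`` on any
    non-EOG channel.  Returns ``(surviving EpochSet, RejectionReport)``."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    scalp = epochs.channels.scalp_indices
    peak = np.abs(epochs.data[:, scalp, :]).max(axis=(1, 2))
    keep = peak <= threshold_uv
    reasons = {epochs.epoch_ids[i]: "amplitude" for i in np.flatnonzero(~keep)}
    report = RejectionReport(epochs.n_epochs, int((~keep).sum()), reasons)
    if not keep.any():
        logger.warning("all %d epochs rejected at %.1f uV", epochs.n_epochs, threshold_uv)
        survivors = epochs.copy_with(data=epochs.data[:0], epoch_ids=())
    else:
        survivors = epochs.copy_with(
            data=epochs.data[keep],
            epoch_ids=tuple(np.asarray(epochs.epoch_ids)[keep]))
    return survivors, report


def average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous mean over non-EOG channels."""
    scalp = epochs.channels.scalp_indices
    if scalp.size < 2:
        raise ValueError("average reference needs at least two non-EOG channels")
    mean = epochs.data[:, scalp, :].mean(axis=1, keepdims=True)
    return epochs.copy_with(data=epochs.data - mean)


def _design(band: BandSpec, srate: float, order: int = 4):
    nyq = srate / 2.0
    if band.hi_hz > nyq:
        raise ValueError(f"band edge {band.hi_hz} Hz above Nyquist ({nyq} Hz)")
    if band.lo_hz <= 0:
        return signal.butter(order, band.hi_hz, btype="lowpass", fs=srate, output="sos")
    return signal.butter(order, [band.lo_hz, band.hi_hz], btype="bandpass",
                         fs=srate, output="sos")


def bandpass(epochs: EpochSet, band: BandSpec | str, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass; updates the epoch band tag.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective order
    and cancels group delay, so microstate segment boundaries are not shifted.
    Epoch edges are handled by odd reflective padding of one settling length.
    """
    if isinstance(band, str):
        band = BANDS[band]
    sos = _design(band, epochs.srate, order)
    padlen = min(epochs.n_times - 1, 3 * int(epochs.srate / max(band.lo_hz, 1.0)))
    out = signal.sosfiltfilt(sos, epochs.data, axis=2, padlen=padlen)
    return epochs.copy_with(data=out, band=band.name)


def split_bands(epochs: EpochSet, bands=("delta", "theta", "alpha", "beta")) -> dict:
    """Filter one EpochSet into each requested band; keys are band names."""
    return {name: bandpass(epochs, BANDS[name] if isinstance(name, str) else name)
            for name in bands}
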