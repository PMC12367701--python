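"""Global field power and GFP-peak topography extraction.

GFP at time *t* is the spatial standard deviation of the scalp map across
non-EOG electrodes.  Its local maxima mark moments of high signal-to-noise
and quasi-stable topography; the maps at those peaks are the substrate for
microstate clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DataError, EpochSet, normalize_map

__all__ = ["GfpSeries", "PeakMapSet", "compute_gfp", "find_gfp_peaks", "collect_peak_maps"]


@dataclass
class GfpSeries:
    """Per-timepoint GFP for one epoch, plus detected peak indices."""

    values: np.ndarray
    srate: float
    t0_offset_ms: float = 0.0
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("GFP values must be non-negative")


@dataclass
class PeakMapSet:
    """Normalized GFP-peak maps pooled across epochs of one condition x band.

    ``maps`` is (n_maps, n_scalp_channels); ``source`` records the
    ``(epoch_id, sample_index)`` provenance of each map.
    """

    maps: np.ndarray
    source: list
    polarity_mode: str = "signed"

    def __post_init__(self):
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if len(self.source) != self.maps.shape[0]:
            raise ValueError("source entries must match the number of maps")
        if self.polarity_mode not in ("signed", "unsigned"):
            raise ValueError("polarity_mode must be 'signed' or 'unsigned'")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


def compute_gfp(epoch: np.ndarray, srate: float = 1000.0, t0_offset_ms: float = 0.0,
                scalp_indices=None, convention: str = "rms") -> GfpSeries:
    """GFP of a single epoch ``(n_channels, n_times)``.

    ``convention='rms'`` (default) gives the Lehmann-Skrandies definition
    sqrt(mean_i (v_i - vbar)^2); ``'sumsq'`` gives the un-normalized
    sum of squared deviations.  The two are a monotone transform of each
    other per fixed channel count, so peak locations are identical.
    """
    epoch = np.asarray(epoch, dtype=float)
    if scalp_indices is not None:
        epoch = epoch[np.asarray(scalp_indices)]
    n_ch = epoch.shape[0]
    if n_ch < 2:
        raise ValueError("GFP needs at least two non-EOG channels")
    dev = epoch - epoch.mean(axis=0, keepdims=True)
    ss = (dev ** 2).sum(axis=0)
    if convention == "rms":
        vals = np.sqrt(ss / n_ch)
    elif convention == "sumsq":
        vals = ss
    else:
        raise ValueError("convention must be 'rms' or 'sumsq'")
    return GfpSeries(vals, srate, t0_offset_ms)


def find_gfp_peaks(gfp: GfpSeries, min_separation_ms: float = 10.0,
                   restrict_window_ms: tuple | None = (0.0, 800.0)) -> np.ndarray:
    """Indices of strict local GFP maxima.

    A peak satisfies ``values[t-1] < values[t] >= values[t+1]``.  When two
    peaks fall within ``min_separation_ms`` the larger is kept (greedy, in
    descending height, ties to the earlier sample).  ``restrict_window_ms``
    limits the search to the analysis window (default 0-800 ms post-stimulus).
    """
    v = gfp.values
    if v.size < 3:
        raise ValueError("series too short for peak detection")
    cand = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])) + 1
    if restrict_window_ms is not None:
        t_ms = gfp.t0_offset_ms + cand * (1000.0 / gfp.srate)
        cand = cand[(t_ms >= restrict_window_ms[0]) & (t_ms < restrict_window_ms[1])]
    if cand.size == 0 or min_separation_ms <= 0:
        return np.sort(cand)
    min_sep = min_separation_ms * gfp.srate / 1000.0
    order = cand[np.lexsort((cand, -v[cand]))]  # height desc, index asc on ties
    kept: list = []
    for idx in order:
        if all(abs(idx - k) >= min_sep for k in kept):
            kept.append(idx)
    return np.sort(np.asarray(kept, dtype=int))


def collect_peak_maps(epochs: EpochSet, polarity_mode: str = "signed",
                      min_separation_ms: float = 10.0,
                      restrict_window_ms: tuple | None = (0.0, 800.0),
                      gfp_convention: str = "rms") -> PeakMapSet:
    """Pool normalized GFP-peak topographies across all epochs.

    Maps are restricted to non-EOG channels and normalized to zero mean and
    unit norm, so spatial Pearson correlation reduces to a dot product.
    """
    if epochs.n_epochs == 0:
        raise DataError("cannot collect peak maps from an empty EpochSet")
    scalp = epochs.channels.scalp_indices
    maps, source = [], []
    for e in range(epochs.n_epochs):
        gfp = compute_gfp(epochs.data[e], epochs.srate, epochs.t0_offset_ms,
                          scalp_indices=scalp, convention=gfp_convention)
        for t in find_gfp_peaks(gfp, min_separation_ms, restrict_window_ms):
            vec = epochs.data[e, scalp, t]
            try:
                maps.append(normalize_map(vec))
            except DataError:
                continue  # flat map carries no topography
            source.append((epochs.epoch_ids[e], int(t)))
    if not maps:
        raise DataError("no GFP peaks found; nothing to cluster")
    return PeakMapSet(np.asarray(maps), source, polarity_mode)
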