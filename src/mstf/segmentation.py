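"""Backfitting, label smoothing, sub-stage division and microstate properties.

Backfitting assigns each timepoint's scalp map to the template with the
highest spatial Pearson correlation (|r| in polarity-ignoring mode),
producing a continuous microstate label sequence.  A minimum-duration
smoother then removes short noise runs, re-assigning their samples to
whichever neighbouring run's template fits better at each sample.  Runs of
the smoothed grand-average sequence are the processing sub-stages; run-length
statistics of per-epoch sequences give the duration / coverage / occurrence
/ transition features.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import EpochSet, LabelSequence, TemplateSet

__all__ = [
    "SegmentRun",
    "PropertySet",
    "backfit",
    "smooth_labels",
    "divide_substages",
    "label_runs",
    "compute_properties",
    "transition_matrix",
    "save_segments",
    "load_segments",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class SegmentRun:
    """A contiguous run of one microstate class, half-open in ms."""

    state: int
    start_ms: float
    end_ms: float

    def __post_init__(self):
        if not self.end_ms > self.start_ms:
            raise ValueError("run must have positive duration")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class PropertySet:
    """Per-state microstate statistics plus the run-transition matrix.

    duration_ms : mean dwell time per state (ms); coverage : fraction of
    assigned time occupied; occurrence : runs per second of assigned time.
    ``transition[i, j]`` is P(next run = j | current run = i) with a
    structurally zero diagonal; rows with no outgoing transitions are
    all-zero and flagged in ``empty_rows``.  States with no runs carry zeros
    and an ``absent`` flag.
    """

    duration_ms: np.ndarray
    coverage: np.ndarray
    occurrence: np.ndarray
    transition: np.ndarray
    absent: np.ndarray
    empty_rows: np.ndarray
    condition: str = ""
    band: str = "original"
    n_obs: int = 1

    def __post_init__(self):
        for name in ("duration_ms", "coverage", "occurrence"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.transition = np.asarray(self.transition, dtype=float)
        self.absent = np.asarray(self.absent, dtype=bool)
        self.empty_rows = np.asarray(self.empty_rows, dtype=bool)
        k = self.duration_ms.size
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix must be k x k")

    @property
    def k(self) -> int:
        return self.duration_ms.size


# ---------------------------------------------------------------------------
# Backfitting
# ---------------------------------------------------------------------------

def _backfit_array(data: np.ndarray, templates: TemplateSet, polarity: str,
                   srate: float, t0_offset_ms: float) -> LabelSequence:
    """Backfit one (n_channels, n_times) array of mean-referenced maps."""
    Y = np.asarray(data, dtype=float)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Yc, axis=0)
    ok = norms > 0
    corr = np.zeros((templates.k, Y.shape[1]))
    corr[:, ok] = (templates.maps @ Yc[:, ok]) / norms[ok]
    comp = np.abs(corr) if polarity == "unsigned" else corr
    labels = np.where(ok, comp.argmax(axis=0), UNASSIGNED)
    fit_r = np.where(ok, comp.max(axis=0), 0.0)
    return LabelSequence(labels, fit_r, srate, t0_offset_ms, corr=comp)


def backfit(epochs, templates: TemplateSet, polarity: str = "signed",
            window_ms: tuple | None = (0.0, 800.0)):
    """Assign every timepoint to its best-correlated template.

    Returns one :class:`LabelSequence` per epoch (a plain list), or a single
    sequence when a 2-D ``(n_channels, n_times)`` array is passed.
    Zero-variance timepoints are labeled ``-1`` with ``fit_r = 0``.
    """
    if isinstance(epochs, np.ndarray) and epochs.ndim == 2:
        return _backfit_array(epochs, templates, polarity, 1000.0, 0.0)
    if not isinstance(epochs, EpochSet):
        raise TypeError("backfit expects an EpochSet or a 2-D array")
    scalp = epochs.channels.scalp_indices
    sl = epochs.window_slice(window_ms) if window_ms is not None else slice(None)
    t0 = epochs.t0_offset_ms + (sl.start or 0) * 1000.0 / epochs.srate
    return [
        _backfit_array(epochs.data[e][scalp, :][:, sl], templates, polarity,
                       epochs.srate, t0)
        for e in range(epochs.n_epochs)
    ]


# ---------------------------------------------------------------------------
# Run-length utilities and smoothing
# ---------------------------------------------------------------------------

def label_runs(labels: np.ndarray) -> list:
    """Run-length encode a label vector into ``(label, start, stop)`` triples
    (half-open sample indices)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return [(int(labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def smooth_labels(seq: LabelSequence, min_duration_ms: float = 10.0) -> LabelSequence:
    """Remove interior runs shorter than ``min_duration_ms``.

    Each sample of a rejected run is re-assigned to the neighbouring run
    whose template correlates better at that sample (using the correlation
    matrix stored by :func:`backfit`; without it, samples fall to the left
    neighbour).  Runs abutting the window edges are exempt.  Iterates until
    no interior run is below threshold; the sample count never changes.
    """
    if min_duration_ms < 0:
        raise ValueError("min_duration must be non-negative")
    n = len(seq)
    if min_duration_ms * seq.srate / 1000.0 > n:
        raise ValueError("min_duration exceeds the analysis window")
    labels = seq.labels.copy()
    fit_r = seq.fit_r.copy()
    corr = seq.corr

    def short_interior_runs():
        runs = label_runs(labels)
        out = []
        for lab, a, b in runs:
            if a == 0 or b == n:
                continue
            if (b - a) * 1000.0 / seq.srate < min_duration_ms:
                out.append((lab, a, b))
        return out

    while True:
        bad = short_interior_runs()
        if not bad:
            break
        # shortest first (ties: earliest) keeps the result order-independent
        lab, a, b = min(bad, key=lambda r: (r[2] - r[1], r[1]))
        left, right = labels[a - 1], labels[b]
        for t in range(a, b):
            if corr is not None and left >= 0 and right >= 0:
                take_left = corr[left, t] >= corr[right, t]
            elif corr is not None and (left >= 0 or right >= 0):
                take_left = left >= 0
            else:
                take_left = True
            tgt = left if take_left else right
            labels[t] = tgt
            fit_r[t] = corr[tgt, t] if (corr is not None and tgt >= 0) else 0.0
    return LabelSequence(labels, fit_r, seq.srate, seq.t0_offset_ms, corr=corr)


def divide_substages(grand_avg, templates: TemplateSet, min_duration_ms: float = 10.0,
                     polarity: str = "signed",
                     window_ms: tuple = (0.0, 800.0)) -> list:
    """Divide a grand-average epoch into contiguous microstate sub-stages.

    ``grand_avg`` is an :class:`EpochSet` (its epochs are averaged) or a
    ``(n_channels, n_times)`` array.  Returns time-ordered
    :class:`SegmentRun` covering the analysis window.
    """
    if isinstance(grand_avg, EpochSet):
        avg = grand_avg.copy_with(data=grand_avg.data.mean(axis=0, keepdims=True),
                                  epoch_ids=("grand_average",))
        seq = backfit(avg, templates, polarity, window_ms)[0]
    else:
        seq = backfit(np.asarray(grand_avg), templates, polarity)
    seq = smooth_labels(seq, min_duration_ms)
    dt = 1000.0 / seq.srate
    return [SegmentRun(lab, seq.t0_offset_ms + a * dt, seq.t0_offset_ms + b * dt)
            for lab, a, b in label_runs(seq.labels)]


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

def _single_properties(seq: LabelSequence, k: int):
    runs = [(lab, a, b) for lab, a, b in label_runs(seq.labels) if lab != UNASSIGNED]
    assigned = int((seq.labels != UNASSIGNED).sum())
    if assigned == 0:
        raise ValueError("sequence has no assigned samples")
    dt_ms = 1000.0 / seq.srate
    duration = np.zeros(k)
    coverage = np.zeros(k)
    occurrence = np.zeros(k)
    absent = np.ones(k, dtype=bool)
    for s in range(k):
        lens = [b - a for lab, a, b in runs if lab == s]
        if not lens:
            continue
        absent[s] = False
        duration[s] = np.mean(lens) * dt_ms
        coverage[s] = sum(lens) / assigned
        occurrence[s] = len(lens) / (assigned * dt_ms / 1000.0)
    return duration, coverage, occurrence, absent, runs


def transition_matrix(seq, k: int):
    """K x K run-transition probabilities.

    Transitions are counted between successive distinct assigned runs
    (self-transitions are structurally absent, so the diagonal is zero);
    unassigned runs are dropped before counting.  Rows are normalized by
    their outgoing count; all-zero rows are flagged.  Returns
    ``(matrix, empty_row_flags)``.
    """
    if isinstance(seq, LabelSequence):
        run_labels = [lab for lab, _, _ in label_runs(seq.labels) if lab != UNASSIGNED]
    else:
        run_labels = [int(x) for x in seq if int(x) != UNASSIGNED]
    counts = np.zeros((k, k))
    for cur, nxt in zip(run_labels[:-1], run_labels[1:]):
        if cur != nxt:
            counts[cur, nxt] += 1
    out = counts.sum(axis=1)
    empty = out == 0
    mat = np.divide(counts, out[:, None], out=np.zeros_like(counts), where=~empty[:, None])
    return mat, empty


def compute_properties(seq, k: int, condition: str = "", band: str = "original") -> PropertySet:
    """Microstate properties of one sequence or a list of per-epoch sequences.

    Multi-epoch input averages duration/coverage/occurrence across epochs
    (per-trial values, as used for feature tables) and pools run-transition
    counts before normalizing.  Per single sequence the exact identity
    ``coverage = occurrence * duration / 1000`` holds state-wise.
    """
    seqs = seq if isinstance(seq, (list, tuple)) else [seq]
    if not seqs or any(len(s) == 0 for s in seqs):
        raise ValueError("empty label sequence")
    durs, covs, occs, absents = [], [], [], []
    counts = np.zeros((k, k))
    for s in seqs:
        d, c, o, ab, runs = _single_properties(s, k)
        durs.append(d)
        covs.append(c)
        occs.append(o)
        absents.append(ab)
        run_labels = [lab for lab, _, _ in runs]
        for cur, nxt in zip(run_labels[:-1], run_labels[1:]):
            if cur != nxt:
                counts[cur, nxt] += 1
    out = counts.sum(axis=1)
    empty = out == 0
    trans = np.divide(counts, out[:, None], out=np.zeros_like(counts), where=~empty[:, None])
    return PropertySet(
        np.mean(durs, axis=0), np.mean(covs, axis=0), np.mean(occs, axis=0),
        trans, np.all(absents, axis=0), empty,
        condition=condition, band=band, n_obs=len(seqs))


# ---------------------------------------------------------------------------
# Segment-table serialization
# ---------------------------------------------------------------------------

def save_segments(runs, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["state", "start_ms", "end_ms"])
        for r in runs:
            w.writerow([r.state, repr(float(r.start_ms)), repr(float(r.end_ms))])


def load_segments(path) -> list:
    rows = list(csv.reader(Path(path).open()))
    return [SegmentRun(int(s), float(a), float(b)) for s, a, b in rows[1:]]
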