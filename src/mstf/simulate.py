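"""Synthetic task-state EEG with planted microstate structure.

Each epoch spans -200..+800 ms at 1 kHz (configurable).  The post-stimulus
window is tiled by a semi-Markov state sequence: dwell times are gamma
distributed (shape 4 by default, giving refractory-like dwell regularity
rather than exponential churn) and successive states always differ.  During
a segment the scalp signal is the state's fixed zero-mean unit-norm
template scaled by a rectified-sinusoid amplitude envelope — this is what
creates the local GFP-peak structure that peak-map clustering exploits —
plus spatially white Gaussian noise.  The pre-stimulus baseline is pure
noise.  Every epoch is mean-referenced by construction, and the generator
is bitwise-deterministic for a fixed spec and seed.

Ground truth (per-sample states, true templates, per-epoch segment tables,
uncensored dwell draws) is returned alongside the data so the full
pipeline's recovery of K, templates and dwell statistics can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ChannelInfo, EpochSet, TemplateSet, normalize_map
from .segmentation import SegmentRun

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "make_templates",
    "simulate_epochs",
    "two_condition_dataset",
    "attended_spec",
    "unattended_spec",
]


@dataclass(frozen=True)
class SynthSpec:
    """Generator configuration.

    snr is the template-to-noise amplitude ratio at the topography level:
    the template map (unit spatial norm, scaled by ``amplitude_uv`` at an
    envelope antinode) has spatial L2 amplitude ``amplitude_uv``, and the
    per-channel noise standard deviation is chosen so the noise map's
    expected spatial L2 norm is ``amplitude_uv / snr``.
    """

    n_channels: int = 30
    srate: float = 1000.0
    window_ms: tuple = (-200.0, 800.0)
    k_true: int = 4
    dwell_mean_ms: float = 70.0
    dwell_shape: float = 4.0
    envelope_freq_hz: float = 20.0
    snr: float = 10.0
    amplitude_uv: float = 10.0
    seed: int = 0
    condition: str = ""
    max_abs_r: float = 0.5
    spatially_correlated_noise: bool = False

    def __post_init__(self):
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.snr <= 0 or self.dwell_mean_ms <= 0 or self.dwell_shape <= 0:
            raise ValueError("snr, dwell_mean_ms and dwell_shape must be positive")


@dataclass
class GroundTruth:
    """Planted structure behind one simulated EpochSet."""

    states: np.ndarray                  # (n_epochs, n_times), -1 pre-stimulus
    templates: TemplateSet
    dwell_mean_ms: float
    dwell_shape: float
    segments: list                      # per epoch: list of SegmentRun
    dwell_draws_ms: np.ndarray = field(default_factory=lambda: np.empty(0))

    def mean_segment_duration_ms(self) -> float:
        """Mean realized (window-censored) segment duration across epochs."""
        return float(np.mean([r.duration_ms for segs in self.segments for r in segs]))


def make_templates(k: int, n_channels: int, max_abs_r: float = 0.5,
                   seed=None, rng=None) -> TemplateSet:
    """Draw k zero-mean unit-norm maps with pairwise |Pearson r| <= max_abs_r.

    Uses rejection sampling (at most 10,000 draws).  ``max_abs_r = 0``
    switches to Gram-Schmidt inside the zero-mean subspace; since
    average-referenced maps span only n_channels - 1 dimensions, exact
    orthogonality supports at most ``n_channels - 1`` templates.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if k > n_channels:
        raise ValueError("cannot plant more templates than channels")
    if max_abs_r == 0:
        if k > n_channels - 1:
            raise ValueError("at most n_channels - 1 orthogonal zero-mean maps exist")
        maps = []
        while len(maps) < k:
            v = rng.standard_normal(n_channels)
            v = v - v.mean()
            for m in maps:
                v = v - (v @ m) * m
            nrm = np.linalg.norm(v)
            if nrm > 1e-8:
                maps.append(v / nrm)
        return TemplateSet(np.asarray(maps))
    maps = []
    for _ in range(10_000):
        v = normalize_map(rng.standard_normal(n_channels))
        if all(abs(v @ m) <= max_abs_r for m in maps):
            maps.append(v)
            if len(maps) == k:
                return TemplateSet(np.asarray(maps))
    raise RuntimeError(f"could not draw {k} maps with |r| <= {max_abs_r} in 10,000 tries")


def simulate_epochs(spec: SynthSpec, n_epochs: int, seed=None,
                    templates: TemplateSet | None = None):
    """Generate ``(EpochSet, GroundTruth)`` under ``spec``.

    ``seed`` overrides ``spec.seed``; templates may be supplied to share
    topographies across datasets.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if templates is None:
        templates = make_templates(spec.k_true, spec.n_channels, spec.max_abs_r, rng=rng)
    elif templates.k != spec.k_true:
        raise ValueError("supplied templates do not match k_true")
    lo, hi = spec.window_ms
    n_times = int(round((hi - lo) * spec.srate / 1000.0))
    i0 = int(round(-lo * spec.srate / 1000.0))       # sample index of t = 0
    dt = 1.0 / spec.srate
    # noise map E||n|| = sd * sqrt(n_ch); sd chosen so that ratio equals snr
    noise_sd = spec.amplitude_uv / (spec.snr * np.sqrt(spec.n_channels))
    mix = None
    if spec.spatially_correlated_noise:
        a = rng.standard_normal((spec.n_channels, spec.n_channels)) / np.sqrt(spec.n_channels)
        mix = np.eye(spec.n_channels) + 0.5 * a

    data = np.empty((n_epochs, spec.n_channels, n_times))
    states = np.full((n_epochs, n_times), -1, dtype=int)
    segments, draws = [], []
    for e in range(n_epochs):
        sig = np.zeros((spec.n_channels, n_times))
        segs = []
        t = i0
        state = int(rng.integers(spec.k_true))
        while t < n_times:
            dwell_ms = rng.gamma(spec.dwell_shape, spec.dwell_mean_ms / spec.dwell_shape)
            draws.append(dwell_ms)
            n = max(1, int(round(dwell_ms * spec.srate / 1000.0)))
            end = min(t + n, n_times)
            phase = rng.uniform(0, 2 * np.pi)
            tt = (np.arange(end - t)) * dt
            env = np.abs(np.sin(2 * np.pi * spec.envelope_freq_hz * tt + phase))
            sig[:, t:end] = spec.amplitude_uv * env * templates.maps[state][:, None]
            states[e, t:end] = state
            segs.append(SegmentRun(state, lo + t * 1000.0 / spec.srate,
                                   lo + end * 1000.0 / spec.srate))
            t = end
            if spec.k_true > 1:
                step = int(rng.integers(1, spec.k_true))
                state = (state + step) % spec.k_true
        noise = rng.normal(0.0, noise_sd, (spec.n_channels, n_times))
        if mix is not None:
            noise = mix @ noise
        ep = sig + noise
        data[e] = ep - ep.mean(axis=0, keepdims=True)   # mean reference
        segments.append(segs)

    channels = ChannelInfo([f"CH{i + 1:02d}" for i in range(spec.n_channels)])
    epochs = EpochSet(data, spec.srate, lo, channels, condition=spec.condition)
    gt = GroundTruth(states, templates, spec.dwell_mean_ms, spec.dwell_shape,
                     segments, np.asarray(draws))
    return epochs, gt


def attended_spec(seed: int = 0, **kw) -> SynthSpec:
    """Six quasi-stable states with shorter dwells (attended-like regime)."""
    kw.setdefault("condition", "attended")
    return SynthSpec(k_true=6, dwell_mean_ms=70.0, seed=seed, **kw)


def unattended_spec(seed: int = 0, **kw) -> SynthSpec:
    """Four states with longer dwells (unattended-like regime)."""
    kw.setdefault("condition", "unattended")
    return SynthSpec(k_true=4, dwell_mean_ms=85.0, seed=seed, **kw)


def two_condition_dataset(spec_a: SynthSpec | None = None,
                          spec_b: SynthSpec | None = None,
                          n_epochs_each: int = 100, seed: int = 0):
    """Two condition-tagged synthetic datasets with ground truth.

    Defaults emulate the attended (6 states, shorter dwell) vs unattended
    (4 states, longer dwell) task regimes.  Returns
    ``{condition: (EpochSet, GroundTruth)}``.
    """
    if spec_a is None:
        spec_a = attended_spec(seed=seed)
    else:
        spec_a = replace(spec_a, seed=seed)
    if spec_b is None:
        spec_b = unattended_spec(seed=seed + 1)
    else:
        spec_b = replace(spec_b, seed=seed + 1)
    out = {}
    for spec in (spec_a, spec_b):
        key = spec.condition or f"k{spec.k_true}"
        out[key] = simulate_epochs(spec, n_epochs_each)
    return out
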