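"""Hierarchical topographic clustering of GFP-peak maps.

Two bottom-up variants are provided:

``merge``
    Plain agglomeration: every peak map starts as its own cluster and the
    pair of clusters whose centroids are most similar (spatial Pearson r,
    or |r| in unsigned/polarity-ignoring mode) is merged at each step; the
    merged centroid is the normalized (polarity-aligned) mean of the member
    maps.  A solution is recorded at every K on the way down, so solutions
    at K and K+1 are nested (differ by exactly one merge).

``atomize_agglomerate``
    TAAHC: at each step the cluster with the lowest summed member-to-
    centroid similarity is dissolved and each freed map is re-assigned to
    the best remaining centroid.

Both are deterministic given input order; merge ties resolve to the lowest
``(i, j)`` cluster-index pair, atomize ties to the lowest cluster index.

:class:`MicrostateClustering` wraps peak extraction, agglomeration and
criterion-based K selection as a scikit-learn estimator: ``fit`` learns the
template ladder and the optimal K, ``predict`` backfits maps or epochs onto
the selected templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from . import criteria
from .core import EpochSet, TemplateSet, normalize_map
from .gfp import PeakMapSet, collect_peak_maps

__all__ = ["ClusterSolution", "agglomerate", "MicrostateClustering"]


@dataclass
class ClusterSolution:
    """One point of the agglomeration ladder: K templates + map assignment."""

    k: int
    templates: TemplateSet
    assignment: np.ndarray
    mean_within_r: float
    members: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.min(initial=0) < 0 or self.assignment.max(initial=0) >= self.k:
            raise ValueError("assignment indices out of [0, k)")
        if len(np.unique(self.assignment)) != self.k:
            raise ValueError("every cluster must be non-empty")


def _centroid(members: np.ndarray, polarity: str, reference: np.ndarray | None = None) -> np.ndarray:
    """Normalized mean of member maps; in unsigned mode members are first
    aligned in sign to ``reference`` (default: the first member)."""
    if polarity == "unsigned":
        ref = members[0] if reference is None else reference
        signs = np.sign(members @ ref)
        signs[signs == 0] = 1.0
        members = members * signs[:, None]
    return normalize_map(members.mean(axis=0))


def _similarity(a: np.ndarray, b: np.ndarray, polarity: str):
    s = a @ b.T if b.ndim > 1 else a @ b
    return np.abs(s) if polarity == "unsigned" else s


def _as_solution(maps, members_list, centroids, polarity, meta) -> ClusterSolution:
    # deterministic cluster order: by lowest member map index
    order = sorted(range(len(members_list)), key=lambda c: min(members_list[c]))
    assignment = np.empty(maps.shape[0], dtype=int)
    temp = np.empty((len(order), maps.shape[1]))
    within = np.empty(maps.shape[0])
    for rank, c in enumerate(order):
        idx = np.asarray(members_list[c])
        assignment[idx] = rank
        temp[rank] = centroids[c]
        within[idx] = _similarity(maps[idx], centroids[c], polarity)
    ts = TemplateSet(temp, meta=dict(meta, k=len(order)))
    return ClusterSolution(len(order), ts, assignment, float(within.mean()),
                           members=[sorted(members_list[c]) for c in order])


def agglomerate(maps, k_range=(2, 15), variant: str = "merge",
                polarity: str = "signed") -> list:
    """Cluster normalized maps over a K ladder; returns ascending-K solutions.

    Parameters
    ----------
    maps : PeakMapSet or ndarray (n_maps, n_channels)
        Zero-mean unit-norm topographies.
    k_range : (k_min, k_max)
    variant : {"merge", "atomize_agglomerate"}
    polarity : {"signed", "unsigned"}
    """
    if isinstance(maps, PeakMapSet):
        polarity = maps.polarity_mode
        X = maps.maps
    else:
        X = np.atleast_2d(np.asarray(maps, dtype=float))
    k_min, k_max = int(k_range[0]), int(k_range[1])
    n = X.shape[0]
    if not (2 <= k_min <= k_max):
        raise ValueError("need k_max >= k_min >= 2")
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the number of maps ({n})")
    if variant not in ("merge", "atomize_agglomerate"):
        raise ValueError(f"unknown variant {variant!r}")

    meta = {"variant": variant, "polarity": polarity,
            "k_min": k_min, "k_max": k_max, "n_maps": n}
    members = [[i] for i in range(n)]
    cents = X.copy()
    active = np.ones(n, dtype=bool)
    solutions = {}

    def record():
        live = np.flatnonzero(active)
        sol = _as_solution(X, [members[c] for c in live], cents[live], polarity, meta)
        solutions[sol.k] = sol

    if variant == "merge":
        sim = _similarity(cents, cents, polarity)
        sim[np.tril_indices(n)] = -np.inf       # keep i < j only
        n_active = n
        if k_min <= n_active <= k_max:
            record()
        while n_active > k_min:
            i, j = np.unravel_index(int(np.argmax(sim)), sim.shape)
            members[i] = members[i] + members[j]
            cents[i] = _centroid(X[np.asarray(members[i])], polarity, reference=cents[i])
            active[j] = False
            sim[j, :] = -np.inf
            sim[:, j] = -np.inf
            live = np.flatnonzero(active)
            s = _similarity(cents[live], cents[i], polarity)
            below, above = live < i, live > i
            sim[live[below], i] = s[below]
            sim[i, live[above]] = s[above]
            sim[i, i] = -np.inf
            n_active -= 1
            if k_min <= n_active <= k_max:
                record()
    else:
        n_active = n
        if k_min <= n_active <= k_max:
            record()
        while n_active > k_min:
            live = np.flatnonzero(active)
            quality = np.array(
                [float(_similarity(X[np.asarray(members[c])], cents[c], polarity).sum())
                 for c in live])
            worst = live[int(np.argmin(quality))]   # first min -> lowest index
            freed = members[worst]
            active[worst] = False
            remaining = np.flatnonzero(active)
            sims = _similarity(X[np.asarray(freed)], cents[remaining], polarity)
            targets = remaining[np.argmax(sims, axis=1)]
            changed = set()
            for m, c in zip(freed, targets):
                members[c].append(m)
                changed.add(c)
            for c in changed:
                cents[c] = _centroid(X[np.asarray(sorted(members[c]))], polarity,
                                     reference=cents[c])
            n_active -= 1
            if k_min <= n_active <= k_max:
                record()

    return [solutions[k] for k in sorted(solutions)]


class MicrostateClustering(ClusterMixin, BaseEstimator):
    """GFP-peak microstate clustering with criterion-based K selection.

    ``fit(X)`` accepts either an :class:`~mstf.core.EpochSet` (GFP-peak maps
    are extracted and pooled first) or a pre-built ``(n_maps, n_channels)``
    array of topographies.  A ladder of hierarchical solutions over
    ``k_range`` is built and the optimal K selected by ``select_method``.

    Parameters
    ----------
    k_range : (int, int), default (2, 15)
        Candidate cluster counts, covering the optima typically reported for
        task-state EEG (roughly 4-14).
    variant : {"merge", "atomize_agglomerate"}
    polarity : {"signed", "unsigned"}
        Signed spatial correlation (ERP convention, default) or
        polarity-ignoring |r|.
    select_method : {"kl_gev", "kl", "cv"}
    min_separation_ms : float
        Minimum GFP-peak spacing (suppresses jitter-duplicate maps).
    restrict_window_ms : (float, float)
        Analysis window for peak extraction, default 0-800 ms post-stimulus.
    max_maps : int or None
        Upper bound on maps fed to agglomeration; larger pools are
        subsampled (seeded) to keep the O(n^2) merge tractable.
    random_state : int or None

    Attributes
    ----------
    solutions_ : list of ClusterSolution (ascending K)
    report_ : criteria.SelectionReport
    k_ : int                  -- selected cluster count
    templates_ : TemplateSet  -- templates at ``k_``
    labels_ : ndarray         -- assignment of the clustered maps at ``k_``
    peak_maps_ : ndarray      -- the clustered (possibly subsampled) maps
    """

    def __init__(self, k_range=(2, 15), variant="merge", polarity="signed",
                 select_method="kl_gev", klgev_rule="after",
                 min_separation_ms=10.0, restrict_window_ms=(0.0, 800.0),
                 gfp_convention="rms", max_maps=1000, random_state=None):
        self.k_range = k_range
        self.variant = variant
        self.polarity = polarity
        self.select_method = select_method
        self.klgev_rule = klgev_rule
        self.min_separation_ms = min_separation_ms
        self.restrict_window_ms = restrict_window_ms
        self.gfp_convention = gfp_convention
        self.max_maps = max_maps
        self.random_state = random_state

    def _extract(self, X) -> np.ndarray:
        if isinstance(X, EpochSet):
            pms = collect_peak_maps(X, self.polarity, self.min_separation_ms,
                                    self.restrict_window_ms, self.gfp_convention)
            return pms.maps
        if isinstance(X, PeakMapSet):
            return X.maps
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.asarray([normalize_map(row) for row in X])

    def fit(self, X, y=None):
        maps = self._extract(X)
        if self.max_maps is not None and maps.shape[0] > self.max_maps:
            rng = np.random.default_rng(self.random_state)
            keep = np.sort(rng.choice(maps.shape[0], self.max_maps, replace=False))
            maps = maps[keep]
        self.peak_maps_ = maps
        self.solutions_ = agglomerate(maps, self.k_range, self.variant, self.polarity)
        self.report_ = criteria.select_k(self.solutions_, maps,
                                         methods=("kl_gev", "kl", "cv"),
                                         klgev_rule=self.klgev_rule)
        self.k_ = int(self.report_.selections[self.select_method]["k"])
        sol = next(s for s in self.solutions_ if s.k == self.k_)
        self.templates_ = sol.templates
        self.labels_ = sol.assignment
        return self

    def predict(self, X):
        """Backfit: assign maps (or every timepoint of an EpochSet's epochs)
        to the best-correlated selected template."""
        from .segmentation import backfit  # local import avoids a cycle
        if not hasattr(self, "templates_"):
            raise RuntimeError("fit the estimator before predicting")
        if isinstance(X, EpochSet):
            seqs = backfit(X, self.templates_, polarity=self.polarity,
                           window_ms=self.restrict_window_ms)
            return [s.labels for s in seqs]
        X = np.atleast_2d(np.asarray(X, dtype=float))
        maps = np.asarray([normalize_map(row) for row in X])
        corr = maps @ self.templates_.maps.T
        if self.polarity == "unsigned":
            corr = np.abs(corr)
        return corr.argmax(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
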