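"""Cluster-number selection criteria for microstate template sets.

Implements global explained variance (GEV), the KL_GEV successive-ratio
criterion built on it, the Krzanowski-Lai (KL) dispersion criterion, the
predictive-residual cross-validation (CV) criterion, and two generic
clustering scores (Calinski-Harabasz index and silhouette coefficient) used
to compare the criteria's selections.

KL_GEV reads the elbow of the GEV-vs-K curve: with ``diff_i = GEV_i -
GEV_{i+1}`` over ascending K, ``KL_GEV,i = |diff_i / diff_{i+1}|`` is large
exactly where the marginal GEV gain collapses after the next K, so the K
just after the maximizing ratio is taken as optimal (the literal "at the
ratio" reading is available via ``rule='at'``).  Ties in any argmax resolve
to the smallest K (parsimony).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np

from .core import TemplateSet

__all__ = [
    "CriterionTrace",
    "SelectionReport",
    "compute_gev",
    "kl_gev",
    "cv_criterion",
    "cv_split_criterion",
    "within_dispersion",
    "kl_criterion",
    "ch_index",
    "silhouette",
    "select_k",
]


# ---------------------------------------------------------------------------
# GEV
# ---------------------------------------------------------------------------

def compute_gev(data: np.ndarray, templates, labels: np.ndarray) -> float:
    """Global explained variance of a labeled template fit.

    ``GEV = 1 - sum_t ||y(t) - a(t) m_{L(t)}||^2 / sum_t ||y(t) - ybar||^2``
    with ``a(t) = <y(t), m_{L(t)}>`` the least-squares scaling for unit-norm
    templates and ``ybar`` the global mean map.  Timepoints labeled ``-1``
    (unassigned) contribute their full power to the residual.

    Parameters
    ----------
    data : ndarray (n_times, n_channels)
        Mean-referenced maps (rows).
    templates : TemplateSet or ndarray (k, n_channels)
    labels : ndarray (n_times,)
    """
    Y = np.atleast_2d(np.asarray(data, dtype=float))
    M = templates.maps if isinstance(templates, TemplateSet) else np.asarray(templates)
    labels = np.asarray(labels, dtype=int)
    if labels.size != Y.shape[0]:
        raise ValueError("labels must have one entry per timepoint")
    if labels.max(initial=-1) >= M.shape[0]:
        raise ValueError("label index out of template range")
    ybar = Y.mean(axis=0)
    total = float(((Y - ybar) ** 2).sum())
    if total == 0:
        raise ValueError("zero total variance: degenerate data")
    assigned = labels >= 0
    a = np.einsum("ij,ij->i", Y[assigned], M[labels[assigned]])
    resid = float((Y ** 2).sum() - (a ** 2).sum())
    return 1.0 - resid / total


# ---------------------------------------------------------------------------
# KL_GEV
# ---------------------------------------------------------------------------

@dataclass
class RatioSelection:
    """Outcome of a successive-ratio (elbow) criterion."""

    k_values: np.ndarray
    ratios: np.ndarray          # aligned to k_values; NaN where undefined
    selected_k: int
    notes: list = field(default_factory=list)


def kl_gev(gev_values, k_values=None, rule: str = "after") -> RatioSelection:
    """Select the optimal K from ascending-K GEV values.

    ``rule='after'`` (default) selects ``K_{i*+1}`` where ``i*`` maximizes
    the ratio: a large ``|diff_i / diff_{i+1}|`` means GEV gains collapse
    after ``K_{i+1}``.  ``rule='at'`` selects ``K_{i*}``.  Zero-denominator
    ratios are skipped with a note.
    """
    g = np.asarray(gev_values, dtype=float)
    if g.size < 3:
        raise ValueError("KL_GEV needs at least three GEV values")
    if k_values is None:
        k_values = np.arange(2, 2 + g.size)
    k_values = np.asarray(k_values, dtype=int)
    if k_values.size != g.size or np.any(np.diff(k_values) <= 0):
        raise ValueError("k_values must be ascending and match gev_values")
    diffs = g[:-1] - g[1:]                      # diff_i = GEV_i - GEV_{i+1}
    notes: list = []
    ratios = np.full(g.size, np.nan)
    for i in range(diffs.size - 1):
        if diffs[i + 1] == 0:
            notes.append(f"zero GEV increment after K={k_values[i + 1]}; ratio skipped")
            continue
        # ratio_i spans K_i -> K_{i+2}; stored at the K_{i+1} slot so the
        # k-aligned argmax directly yields the default selection
        ratios[i + 1] = abs(diffs[i] / diffs[i + 1])
    if np.all(np.isnan(ratios)):
        raise ValueError("all KL_GEV ratios undefined (flat GEV curve)")
    i_star = int(np.nanargmax(ratios))          # first max -> smallest K
    selected = k_values[i_star] if rule == "after" else k_values[i_star - 1]
    return RatioSelection(k_values, ratios, int(selected), notes)


# ---------------------------------------------------------------------------
# CV criterion
# ---------------------------------------------------------------------------

def cv_criterion(data: np.ndarray, templates, labels: np.ndarray) -> float:
    """Predictive-residual cross-validation criterion (lower is better).

    ``CV = sigma2 * ((N - 1) / (N - 1 - K))**2`` with ``sigma2`` the mean
    per-timepoint residual variance after least-squares template fitting and
    ``N`` the channel count.  Undefined (NaN) when ``K >= N - 1``.
    """
    Y = np.atleast_2d(np.asarray(data, dtype=float))
    M = templates.maps if isinstance(templates, TemplateSet) else np.asarray(templates)
    labels = np.asarray(labels, dtype=int)
    n_ch = Y.shape[1]
    k = M.shape[0]
    if k >= n_ch - 1:
        return float("nan")
    assigned = labels >= 0
    a = np.zeros(Y.shape[0])
    a[assigned] = np.einsum("ij,ij->i", Y[assigned], M[labels[assigned]])
    sigma2 = float(((Y ** 2).sum() - (a ** 2).sum()) / (Y.shape[0] * (n_ch - 1)))
    return sigma2 * ((n_ch - 1) / (n_ch - 1 - k)) ** 2


def cv_split_criterion(data: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Literal split-half train/validation variant of the CV criterion.

    Even-indexed maps act as training data: their assignments define
    per-cluster mean templates.  Odd-indexed maps are then fit to those
    templates by best correlation, and the mean held-out residual variance
    is returned (lower is better).
    """
    Y = np.atleast_2d(np.asarray(data, dtype=float))
    labels = np.asarray(labels, dtype=int)
    train, test = Y[0::2], Y[1::2]
    lab_train = labels[0::2]
    cents = []
    for c in range(k):
        members = train[lab_train == c]
        if len(members) == 0:
            continue
        m = members.mean(axis=0)
        m = m - m.mean()
        nrm = np.linalg.norm(m)
        if nrm > 0:
            cents.append(m / nrm)
    if not cents:
        return float("nan")
    C = np.asarray(cents)
    a = test @ C.T
    best = a[np.arange(len(test)), np.abs(a).argmax(axis=1)]
    resid = float((test ** 2).sum() - (best ** 2).sum())
    n_ch = Y.shape[1]
    return resid / (len(test) * (n_ch - 1))


# ---------------------------------------------------------------------------
# KL criterion
# ---------------------------------------------------------------------------

def within_dispersion(maps: np.ndarray, labels: np.ndarray) -> float:
    """Sum of squared Euclidean distances of maps to their cluster mean."""
    X = np.atleast_2d(np.asarray(maps, dtype=float))
    labels = np.asarray(labels, dtype=int)
    w = 0.0
    for c in np.unique(labels):
        mem = X[labels == c]
        w += float(((mem - mem.mean(axis=0)) ** 2).sum())
    return w


def kl_criterion(w_values, k_values, n_dims: int) -> RatioSelection:
    """Krzanowski-Lai criterion on within-cluster dispersions ``W_k``.

    ``DIFF(k) = (k-1)^{2/p} W_{k-1} - k^{2/p} W_k`` with ``p`` the map
    dimensionality; ``KL(k) = |DIFF(k) / DIFF(k+1)|`` and the maximizing K
    is selected.  Requires contiguous integer K values; edge positions are
    stored as NaN.
    """
    w = np.asarray(w_values, dtype=float)
    k_values = np.asarray(k_values, dtype=int)
    if w.size != k_values.size or np.any(np.diff(k_values) != 1):
        raise ValueError("KL needs W_k on a contiguous ascending K grid")
    if w.size < 3:
        raise ValueError("KL needs at least three W values")
    p = float(n_dims)
    diff = np.full(w.size, np.nan)
    for j in range(1, w.size):
        diff[j] = (k_values[j] - 1) ** (2 / p) * w[j - 1] - k_values[j] ** (2 / p) * w[j]
    notes: list = []
    ratios = np.full(w.size, np.nan)
    for j in range(1, w.size - 1):
        if diff[j + 1] == 0:
            notes.append(f"DIFF({k_values[j + 1]}) = 0; ratio skipped")
            continue
        ratios[j] = abs(diff[j] / diff[j + 1])
    if np.all(np.isnan(ratios)):
        raise ValueError("all KL ratios undefined")
    j_star = int(np.nanargmax(ratios))
    return RatioSelection(k_values, ratios, int(k_values[j_star]), notes)


# ---------------------------------------------------------------------------
# Generic clustering scores
# ---------------------------------------------------------------------------

def ch_index(maps: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz variance-ratio criterion ``[B/(k-1)] / [W/(n-k)]``."""
    X = np.atleast_2d(np.asarray(maps, dtype=float))
    labels = np.asarray(labels, dtype=int)
    clusters = np.unique(labels)
    n, k = X.shape[0], clusters.size
    if k < 2 or k >= n:
        return float("nan")
    grand = X.mean(axis=0)
    b = w = 0.0
    for c in clusters:
        mem = X[labels == c]
        cent = mem.mean(axis=0)
        b += len(mem) * float(((cent - grand) ** 2).sum())
        w += float(((mem - cent) ** 2).sum())
    if w == 0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def silhouette(maps: np.ndarray, labels: np.ndarray,
               distances: np.ndarray | None = None) -> float:
    """Mean silhouette coefficient over points (Euclidean distances).

    Points in singleton clusters score 0.  ``distances`` may supply a
    precomputed pairwise distance matrix to reuse across candidate Ks.
    """
    X = np.atleast_2d(np.asarray(maps, dtype=float))
    labels = np.asarray(labels, dtype=int)
    clusters = np.unique(labels)
    n, k = X.shape[0], clusters.size
    if k < 2 or k >= n:
        return float("nan")
    if distances is None:
        sq = (X ** 2).sum(axis=1)
        distances = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0))
    masks = {c: labels == c for c in clusters}
    sizes = {c: int(masks[c].sum()) for c in clusters}
    s = np.zeros(n)
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue
        a = distances[i, masks[c]].sum() / (sizes[c] - 1)
        b = min(distances[i, masks[o]].mean() for o in clusters if o != c)
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


# ---------------------------------------------------------------------------
# Joint selection report
# ---------------------------------------------------------------------------

@dataclass
class CriterionTrace:
    """Per-candidate-K values of every criterion (NaN where undefined)."""

    k_values: np.ndarray
    gev: np.ndarray
    cv: np.ndarray
    kl: np.ndarray
    kl_gev: np.ndarray
    diffs: np.ndarray           # diff_i = GEV_i - GEV_{i+1}, length m-1
    ch: np.ndarray
    sil: np.ndarray

    def to_dict(self) -> dict:
        return {f: np.asarray(getattr(self, f), dtype=float).tolist()
                for f in ("k_values", "gev", "cv", "kl", "kl_gev", "diffs", "ch", "sil")}

    @classmethod
    def from_dict(cls, d: dict) -> "CriterionTrace":
        arrays = {f: np.asarray(d[f]) for f in d}
        arrays["k_values"] = arrays["k_values"].astype(int)
        return cls(**arrays)


@dataclass
class SelectionReport:
    """Selected K per criterion, with CH/silhouette at each selection."""

    selections: dict            # method -> {"k", "ch", "silhouette"}
    trace: CriterionTrace
    notes: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {"selections": self.selections, "notes": self.notes,
                   "trace": self.trace.to_dict()}
        txt = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(txt)
        return txt

    @classmethod
    def from_json(cls, source) -> "SelectionReport":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (ValueError, TypeError):
                payload = json.loads(open(source).read())
        return cls(payload["selections"], CriterionTrace.from_dict(payload["trace"]),
                   payload["notes"])


def select_k(solutions, maps: np.ndarray, methods=("kl_gev", "kl", "cv"),
             klgev_rule: str = "after") -> SelectionReport:
    """Score a ladder of cluster solutions and select K per criterion.

    ``solutions`` is a list of objects with ``k``, ``templates`` (TemplateSet)
    and ``assignment`` attributes, on an ascending contiguous K grid;
    ``maps`` is the (n_maps, n_channels) substrate they cluster.  For each
    requested criterion the report carries the selected K together with the
    CH index and silhouette coefficient evaluated at that selection.
    """
    solutions = sorted(solutions, key=lambda s: s.k)
    if len(solutions) < 3:
        raise ValueError("need at least three candidate Ks")
    k_values = np.array([s.k for s in solutions], dtype=int)
    X = np.atleast_2d(np.asarray(maps, dtype=float))
    gev = np.array([compute_gev(X, s.templates, s.assignment) for s in solutions])
    cv = np.array([cv_criterion(X, s.templates, s.assignment) for s in solutions])
    w = np.array([within_dispersion(X, s.assignment) for s in solutions])

    notes: list = []
    kl_gev_ratios = np.full(k_values.size, np.nan)
    kl_ratios = np.full(k_values.size, np.nan)
    selections: dict = {}
    by_k = {s.k: s for s in solutions}

    if "kl_gev" in methods:
        res = kl_gev(gev, k_values, rule=klgev_rule)
        kl_gev_ratios = res.ratios
        notes += res.notes
        selections["kl_gev"] = {"k": res.selected_k}
    if "kl" in methods:
        res = kl_criterion(w, k_values, X.shape[1])
        kl_ratios = res.ratios
        notes += res.notes
        selections["kl"] = {"k": res.selected_k}
    if "cv" in methods:
        if np.all(np.isnan(cv)):
            raise ValueError("CV undefined for every K (too few channels)")
        selections["cv"] = {"k": int(k_values[int(np.nanargmin(cv))])}

    ch = np.full(k_values.size, np.nan)
    sil = np.full(k_values.size, np.nan)
    sq = (X ** 2).sum(axis=1)
    dist = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0))
    for method, sel in selections.items():
        s = by_k[sel["k"]]
        i = int(np.flatnonzero(k_values == s.k)[0])
        if np.isnan(ch[i]):
            ch[i] = ch_index(X, s.assignment)
            sil[i] = silhouette(X, s.assignment, distances=dist)
        sel["ch"] = float(ch[i])
        sel["silhouette"] = float(sil[i])

    trace = CriterionTrace(k_values, gev, cv, kl_ratios, kl_gev_ratios,
                           gev[:-1] - gev[1:], ch, sil)
    return SelectionReport(selections, trace, notes)
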