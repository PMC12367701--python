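"""End-to-end pipelines: simulate -> bands -> cluster -> backfit -> features.

These functions chain the package's stages the way a full experiment would:
per condition x band, GFP-peak maps are clustered and the optimal K chosen
by KL_GEV; per-epoch label sequences are then backfit, smoothed and reduced
to duration/coverage/occurrence/transition properties, which concatenate
across bands into the classification feature table.

By default each condition is described in its own microstate space (its own
templates and K) and feature columns are zero-padded to the largest K, with
absent-state flags — the multi-condition comparison design in which states
are matched across conditions and conditions may lack the higher-numbered
states.  A pooled mode (one template set fit on all conditions jointly) is
available instead.
"""

from __future__ import annotations

import numpy as np

from .cluster import MicrostateClustering
from .core import EpochSet, FeatureTable
from .features import ClassifierConfig, build_features, crossvalidate
from .preprocess import bandpass
from .segmentation import compute_properties, smooth_labels, backfit
from .simulate import two_condition_dataset

__all__ = ["analyze_condition", "condition_feature_table", "run_experiment"]


def analyze_condition(epochs: EpochSet, bands=("original",), seed=0,
                      **estimator_kw) -> dict:
    """Fit a :class:`MicrostateClustering` per band of one condition.

    Returns ``{band: fitted estimator}``; each estimator carries the
    selected K, templates and the full criterion-selection report.
    """
    out = {}
    for band in bands:
        ep = epochs if band == "original" else bandpass(epochs, band)
        est = MicrostateClustering(random_state=seed, **estimator_kw)
        out[band] = est.fit(ep)
    return out


def _pool(epochs_by_condition: dict) -> EpochSet:
    items = list(epochs_by_condition.values())
    data = np.concatenate([e.data for e in items], axis=0)
    ids = [f"{cond}:{eid}" for cond, e in epochs_by_condition.items()
           for eid in e.epoch_ids]
    return items[0].copy_with(data=data, epoch_ids=tuple(ids), condition="pooled")


def condition_feature_table(epochs_by_condition: dict, bands=("original",),
                            seed: int = 0, min_duration_ms: float = 10.0,
                            template_scope: str = "per_condition",
                            rows: str = "epoch", epochs_per_group: int = 10,
                            estimators_by_condition: dict | None = None,
                            **estimator_kw) -> FeatureTable:
    """Build the classification feature table for several conditions.

    Parameters
    ----------
    template_scope : {"per_condition", "pooled"}
        ``per_condition`` fits templates and K separately per condition and
        zero-pads features to the shared maximum K; ``pooled`` fits one
        template set on all conditions jointly.
    rows : {"epoch", "group"}
        One feature row per epoch (default), or one row per consecutive
        block of ``epochs_per_group`` epochs (emulating per-subject rows:
        duration/coverage/occurrence averaged, transition counts pooled).
    estimators_by_condition : optional ``{condition: {band: fitted estimator}}``
        Reuse previously fitted estimators instead of refitting.
    """
    conditions = list(epochs_by_condition)
    if estimators_by_condition is None:
        if template_scope == "pooled":
            shared = analyze_condition(_pool(epochs_by_condition), bands=bands,
                                       seed=seed, **estimator_kw)
            estimators_by_condition = {c: shared for c in conditions}
        elif template_scope == "per_condition":
            estimators_by_condition = {
                c: analyze_condition(epochs_by_condition[c], bands=bands,
                                     seed=seed, **estimator_kw)
                for c in conditions}
        else:
            raise ValueError("template_scope must be 'per_condition' or 'pooled'")

    observations, labels, groups = [], [], []
    for cond in conditions:
        ep = epochs_by_condition[cond]
        ests = estimators_by_condition[cond]
        seqs_by_band = {}
        for band, est in ests.items():
            bep = ep if band == "original" else bandpass(ep, band)
            seqs_by_band[band] = [
                smooth_labels(s, min_duration_ms)
                for s in backfit(bep, est.templates_, polarity=est.polarity,
                                 window_ms=est.restrict_window_ms)]
        if rows == "epoch":
            blocks = [[i] for i in range(ep.n_epochs)]
        elif rows == "group":
            blocks = [list(range(b, min(b + epochs_per_group, ep.n_epochs)))
                      for b in range(0, ep.n_epochs, epochs_per_group)]
        else:
            raise ValueError("rows must be 'epoch' or 'group'")
        for bi, block in enumerate(blocks):
            obs = {band: compute_properties([seqs_by_band[band][i] for i in block],
                                            ests[band].k_, condition=cond, band=band)
                   for band in ests}
            observations.append(obs)
            labels.append(cond)
            groups.append(f"{cond}:{bi // max(1, epochs_per_group) if rows == 'epoch' else bi}")
    return build_features(observations, labels, group_ids=groups,
                          bands=list(bands), pad_to_kmax=True)


def run_experiment(seed: int = 0, n_epochs: int = 60, bands=("original",),
                   models=("svm", "random_forest"), n_folds: int = 5,
                   grouping: str = "stratified", rows: str = "epoch",
                   **estimator_kw) -> dict:
    """Simulate the two-condition presets and run the full pipeline.

    Returns a JSON-ready report: per-condition selected K with CH/silhouette
    per criterion (the criterion-comparison structure) and per-model CV
    metrics.  Fully deterministic for a fixed seed.
    """
    data = two_condition_dataset(n_epochs_each=n_epochs, seed=seed)
    report: dict = {"seed": seed, "n_epochs": n_epochs, "bands": list(bands),
                    "conditions": {}}
    ests_by_cond = {}
    for cond, (epochs, gt) in data.items():
        ests = analyze_condition(epochs, bands=bands, seed=seed, **estimator_kw)
        ests_by_cond[cond] = ests
        report["conditions"][cond] = {
            "k_true": gt.templates.k,
            "bands": {band: {"selected": est.report_.selections, "k": est.k_}
                      for band, est in ests.items()},
        }
    ft = condition_feature_table({c: d[0] for c, d in data.items()},
                                 bands=bands, seed=seed, rows=rows,
                                 estimators_by_condition=ests_by_cond)
    report["classification"] = {}
    for model in models:
        cv = crossvalidate(ft, ClassifierConfig(model=model, seed=42),
                           n_folds=n_folds, grouping=grouping)
        report["classification"][model] = cv.mean
    return report
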