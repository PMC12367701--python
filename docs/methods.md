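# Methods

This note documents the models and estimation choices behind `mstf`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical conventions used throughout.

## Signal model and conventions

Epoched EEG is held as `(epoch, channel, time)` arrays in microvolts, with
stimulus onset at 0 ms and samples at `t0_offset + i·1000/srate`. The default
epoch spans −200…+800 ms at 1 kHz; the −200…0 ms interval is the baseline and
all microstate analysis is restricted to the 0–800 ms post-stimulus window.
EOG channels are carried through every container but excluded from GFP,
rejection thresholds, clustering and backfitting. Scalp maps ("topographies")
are normalized to zero mean across channels and unit L2 norm, which makes the
spatial Pearson correlation of two maps equal to their dot product — the
workhorse similarity of the whole pipeline.

## Preprocessing

* **Baseline**: per channel, the mean over −200…0 ms is subtracted.
* **Rejection**: epochs with any non-EOG sample exceeding ±100 µV are dropped
  (threshold configurable); a report reconciles input/rejected counts.
* **Reference**: instantaneous mean over non-EOG channels; baseline and
  referencing are linear and channel/time-separable, so they commute (a
  property the tests assert).
* **Bands**: delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz. These edges
  are the conventional boundaries compatible with an overall 0–30 Hz
  band-pass; they are configurable. Filtering is a 4th-order Butterworth run
  forward–backward (`sosfiltfilt`, reflective padding of one settling
  length), i.e. zero-phase: microstate segment boundaries must not be shifted
  by filter group delay, which rules out causal filtering here. ICA-based eye
  artifact removal is deliberately out of scope — it is a manual step in
  practice — so the pipeline expects pre-cleaned input.

## GFP and peak maps

GFP uses the root-mean-square (Lehmann–Skrandies) convention
`GFP(t) = sqrt((1/N) Σ (vᵢ − v̄)²)`; a sum-of-squares convention is available
(`convention="sumsq"`). The two are a monotone transform of each other at
fixed channel count, so peak locations — the only thing clustering consumes —
are identical under both. Peaks are strict local maxima
(`g[t−1] < g[t] ≥ g[t+1]`) with a minimum separation of 10 ms (larger peak
wins; suppresses jitter duplicates at 1 kHz), restricted to 0–800 ms.

## Hierarchical clustering

Two bottom-up variants over a candidate range K = 2…15 (covering the optima
typically reported for task-state EEG, ~4–14):

* **merge** (default): all peak maps start as singletons; the pair of
  clusters with the most similar centroids (signed r by default, |r| in
  polarity-ignoring mode) is merged; the centroid is the normalized
  (sign-aligned, in unsigned mode) mean of member maps. A solution is
  recorded at every K, so solutions at K and K+1 are nested. Ties go to the
  lowest index pair, making the procedure deterministic. A useful exact
  property: the mean member-to-centroid correlation is non-increasing as K
  decreases (‖Σa + Σb‖ ≤ ‖Σa‖ + ‖Σb‖), which the tests check.
* **atomize_agglomerate** (TAAHC): the cluster with the weakest summed
  member-to-centroid similarity is dissolved and its maps reassigned to the
  best remaining centroids.

Polarity: task/ERP analyses normally keep polarity, so `signed` is the
default; `unsigned` mode is fully polarity-invariant (tests flip random map
signs and require identical partitions).

Agglomeration from singletons is O(n²) in the number of peak maps; the
estimator therefore clusters at most `max_maps = 1000` maps, subsampled with
a seeded RNG when more are available (~3,000–6,000 peaks arise from 100
one-second epochs). One thousand maps is ample to estimate ≤15 centroids,
and the cap keeps a full fit around a second.

## Cluster-number criteria

* **GEV** of a labeled fit: `1 − Σₜ‖y(t) − a(t)m_{L(t)}‖² / Σₜ‖y(t) − ȳ‖²`,
  with `a(t) = ⟨y(t), m⟩` the least-squares scale for unit-norm templates.
  By default GEV is evaluated on the GFP-peak maps (the clustering
  substrate); full-timepoint evaluation is possible by backfitting first.
  The formula is implemented exactly as stated: for substrates whose time
  mean is not the zero map and templates that fit poorly, GEV can dip
  below 0; the pipeline's mean-referenced substrates keep it in [0, 1].
* **KL_GEV**: `diffᵢ = GEVᵢ − GEVᵢ₊₁`, `KL_GEVᵢ = |diffᵢ/diffᵢ₊₁|` over
  ascending K. A large ratio at position i means the GEV gain collapses
  after K_{i+1}, so the selected K is K_{i+1} (the diminishing-returns
  elbow); `rule="at"` gives the literal "K at the maximizing ratio"
  alternative. Zero-denominator positions are skipped with a note; argmax
  ties resolve to the smallest K (parsimony). The ratios are invariant to
  scaling all GEV increments by a constant.
* **KL**: `DIFF(k) = (k−1)^{2/p} W_{k−1} − k^{2/p} W_k` with p the map
  dimensionality and W the within-cluster sum of squared Euclidean distances
  to the (arithmetic-mean) centroid; `KL(k) = |DIFF(k)/DIFF(k+1)|`,
  maximized. W is a plain dispersion because no more specific compactness
  definition is standard.
* **CV**: the penalized predictive-residual criterion
  `CV = σ̂²((N−1)/(N−1−K))²` with σ̂² the mean per-timepoint residual
  variance and N the channel count (undefined for K ≥ N−1). A literal
  split-half train/validation variant (`cv_split_criterion`) is provided;
  the penalized form is the default because it is the form in routine
  microstate use and needs no data split.
* **CH index / silhouette** are computed natively from their definitions
  (`[B/(k−1)]/[W/(n−k)]`; mean of `(b−a)/max(a,b)` with singleton points
  scoring 0) and are cross-checked in the tests against scikit-learn's
  implementations to 1e-9. The selection report mirrors a
  criterion-comparison table: selected K per criterion plus CH and
  silhouette at each selection.

## Backfitting, smoothing, sub-stages, properties

Backfitting assigns each timepoint to the template with the highest spatial
Pearson correlation (|r| in unsigned mode), ties to the lowest template
index; zero-variance timepoints become "unassigned" (−1) with r = 0. The
smoother removes interior runs shorter than 10 ms (default), re-assigning
each sample to the neighbouring run whose template correlates better at that
sample, iterating shortest-run-first until stable; edge-abutting runs are
exempt and the sample count never changes. The label sequence carries the
full K×T correlation matrix from backfitting so the smoother can do this
exactly; without it (e.g. sequences loaded from CSV) samples fall
deterministically to the left neighbour.

Sub-stages are the contiguous runs of the smoothed grand-average sequence —
each run of one microstate class is read as one processing stage of the
0–800 ms response.

Per-state properties from a label sequence: mean run duration (ms), coverage
(fraction of assigned samples), occurrence (runs per second of assigned
time). Using assigned time as the occurrence denominator preserves the exact
per-sequence identity `coverage = occurrence × duration / 1000`, which the
tests assert on random sequences; when nothing is unassigned (the normal
case) it equals the plain window length. Transitions are counted between
successive distinct runs — not samples, whose matrices are dominated by the
diagonal — giving a structurally zero diagonal and rows normalized by
outgoing counts (all-zero rows flagged). Multi-epoch property sets average
duration/coverage/occurrence across epochs but pool transition counts before
normalizing, since per-epoch matrices rest on ~10 transitions each.

## Synthetic generator

`simulate_epochs` plants: k zero-mean unit-norm templates with pairwise
|r| ≤ 0.5 (rejection-sampled; exact orthogonality via Gram–Schmidt when
requested — note at most n_channels−1 orthogonal zero-mean maps exist); a
semi-Markov state sequence over 0–800 ms with gamma dwell times (shape 4 —
refractory-like regularity rather than exponential churn) and uniformly
random distinct successor states; per-segment rectified-sinusoid amplitude
envelopes (20 Hz, ~2 GFP peaks per 50 ms segment) that create the GFP-peak
structure the clustering exploits; and spatially white Gaussian noise (a
spatially correlated option exists for robustness checks). SNR is defined at
the topography level: the ratio of the template map's spatial L2 amplitude
at an envelope antinode to the noise map's expected spatial L2 norm. Epochs
are mean-referenced by construction and the generator is bitwise
deterministic per (spec, seed).

Default study conditions: 30 channels, 1 kHz, −200…800 ms, SNR 10,
100 epochs per condition; the two-condition presets plant 6 states with
70 ms mean dwell ("attended": more, shorter states) versus 4 states with
85 ms dwell ("unattended": fewer, longer states), matching the direction and
magnitude of task-state reports.

What the generator does **not** emulate: volume-conducted spatial noise
correlations (except by flag), 1/f spectral structure, ERP-locked latency
jitter across trials, eye artifacts, or between-subject topography
variability. Passing the recovery tests therefore shows the estimation
machinery is correct and well-calibrated under the stated noise model, not
that real recordings will reach the same accuracy.

## Feature tables and classification

One observation (an epoch by default, or a block of epochs emulating a
subject via `rows="group"`) yields, per band: duration/coverage/occurrence
per state followed by the off-diagonal transition probabilities; bands are
concatenated in a fixed column order. By default each condition is described
in its own microstate space (its own templates and K, per the
relabel-and-compare design) and columns are zero-padded to the largest K
with explicit absent-state flag columns; a pooled-template mode is
available. Trial-level rows with stratified folds are the default; grouped
CV (`by_group`) is provided because rows within one subject are correlated
and trial-level stratification can flatter accuracy.

Six reference classifiers with fixed, documented hyperparameters (SVM
rbf C=1 γ=1; random forest 100 trees; gradient boosting 100×depth-3; 5-NN;
logistic regression C=1/l2; LDA svd) run under k-fold CV with
standardization fit on each training fold only. There is no tuning loop —
the object of study is the feature set. One known hyperparameter pathology
is worth stating plainly: with γ = 1 on z-standardized feature vectors of
d ≳ 50 dimensions, squared distances are O(2d) and the RBF kernel matrix
degenerates toward the identity, so this SVM configuration predicts near
the majority class on per-epoch feature tables regardless of class
separability — the same tables are classified at ≥ 0.97 by the random
forest and logistic regression. The configuration is kept as documented
rather than silently re-tuned.

## Problem sizes and determinism

The test suite and acceptance script run the full pipeline at the study
conditions above; repeated-recovery checks use 25 seeded runs per planted K
(tests) and 10 per K (acceptance script), with template/dwell recovery
measured on a per-K subset. Every stage takes explicit seeds and is
reproducible bit-for-bit; `mstf run-all` executed twice with one seed
produces byte-identical reports.

## Known limitations

* EDF/BrainVision reading requires MNE and treats a continuous file as a
  single epoch; epoching from event lists is done by `epoch_and_baseline`.
* The CV criterion's split-half variant re-derives centroids from half the
  maps and is noticeably noisier than the penalized form on small substrates.
* Microstate syntax measures beyond first-order transitions (entropy,
  higher-order sequences) are out of scope, as are source-space
  interpretations of the template maps.
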