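# mstf — task-state EEG microstate analysis and time-frequency features

`mstf` is a toolkit for segmenting task-state (stimulus-locked) EEG into
**microstates** — brief (~50–100 ms) periods of quasi-stable scalp topography —
and turning their statistics into classification features. It targets the
analysis style used for audiovisual attention experiments: epoched multichannel
EEG under two or more task conditions, where the number of microstate classes
is itself condition-dependent and must be estimated from the data.

The pipeline:

1. **Preprocessing** — baseline correction (−200…0 ms), ±100 µV artifact
   rejection on non-EOG channels, average reference, zero-phase Butterworth
   band-pass into delta/theta/alpha/beta bands.
2. **GFP-peak extraction** — global field power
   `GFP(t) = sqrt( (1/N) Σᵢ (vᵢ(t) − v̄(t))² )`
   is the spatial standard deviation across electrodes; scalp maps at its
   local maxima are high-SNR, quasi-stable topographies and form the
   clustering substrate.
3. **Hierarchical topographic clustering** — bottom-up agglomeration of
   peak maps by spatial Pearson correlation (plain merge, or the
   atomize-and-agglomerate variant), recording a template set at every
   candidate K.
4. **Cluster-number selection with KL_GEV.** With GEV the global explained
   variance of a K-template fit,

   ```
   diffᵢ   = GEVᵢ − GEVᵢ₊₁
   KL_GEVᵢ = | diffᵢ / diffᵢ₊₁ |
   ```

   the ratio is maximal at the elbow where marginal GEV gains collapse; the
   K just past the maximizing ratio is selected. KL (Krzanowski–Lai on
   within-cluster dispersion) and the penalized-residual CV criterion are
   computed alongside, with the Calinski–Harabasz index and silhouette
   coefficient scoring each criterion's choice.
5. **Backfitting & sub-stages** — every timepoint is assigned to its
   best-correlated template; short runs are smoothed away; contiguous runs
   of one class in the grand average are the processing sub-stages.
6. **Properties & classification** — per state: mean duration (ms), coverage
   (fraction of time), occurrence (runs/s), and the run-transition matrix;
   concatenated across frequency bands these form the "time-frequency"
   feature vector, evaluated with six fixed classifiers under 5-fold CV.

Because task EEG of this kind is rarely shareable, the package ships a
first-class synthetic generator (`mstf.simulate`) that plants a semi-Markov
microstate sequence (gamma dwell times, rectified-sinusoid amplitude
envelopes, spatially white noise) with full ground truth, so the whole
pipeline can be validated end to end.

## Worked example

```python
import numpy as np
from mstf import MicrostateClustering, unattended_spec, simulate_epochs
from mstf import backfit, smooth_labels, compute_properties

# 100 synthetic epochs, 30 channels, 1 kHz, four planted states
epochs, truth = simulate_epochs(unattended_spec(seed=7), n_epochs=100)

est = MicrostateClustering(random_state=0).fit(epochs)
print("selected K:", est.k_)
print("per-criterion:", {m: s["k"] for m, s in est.report_.selections.items()})
match = np.abs(est.templates_.maps @ truth.templates.maps.T).max(axis=0)
print("template |r| vs planted:", match.round(3))

seqs = [smooth_labels(s) for s in backfit(epochs, est.templates_)]
props = compute_properties(seqs, est.k_)
print("mean duration (ms):", props.duration_ms.round(1))
print("coverage:", props.coverage.round(3))
print("occurrence (1/s):", props.occurrence.round(2))
```

prints

```
selected K: 4
per-criterion: {'kl_gev': 4, 'kl': 4, 'cv': 4}
template |r| vs planted: [1. 1. 1. 1.]
mean duration (ms): [79.6 80.1 84.7 77.9]
coverage: [0.255 0.239 0.264 0.242]
occurrence (1/s): [3.31 2.99 3.08 3.01]
```

All three criteria agree on the planted K = 4; the recovered templates are
numerically identical to the planted topographies (|r| ≈ 1), and the dwell
statistics sit near the generator's 85 ms mean with roughly uniform coverage
across the four states. `est.predict(new_epochs)` backfits the selected
templates onto further data.

The same pipeline is scriptable from a shell:

```bash
mstf simulate --preset two-condition --seed 7 --epochs 100 --out synth/
mstf cluster  --in synth/unattended --templates-out tpl.json --report sel.json
mstf backfit  --in synth/unattended --templates tpl.json --out labels/
mstf run-all  --seed 7 --epochs 60 --out report.json
```

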