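# dmama

Analytics for the **dynamic mean ankle moment arm (DMAMA)** measured with a
prosthesis-embedded pylon load cell, for researchers and engineers working on
semi-active lower-limb prostheses (e.g. variable-stiffness feet) who need a
single per-stride control target plus a locomotion-mode classifier that runs
on the same sensor.

## The metric

A 6-axis load cell mounted in the prosthetic pylon measures the force
`F = (Fx, Fy, Fz)` and moment `M` near the shank. After rotating the stream
into a shank-based frame (X anterior, Y proximal, Z right; sagittal plane
X–Y), the quasi-static sagittal joint moment at the ankle (or knee) is

```
M_joint = (r_joint→LC × F_sag)_z + M_z
```

with `r_joint→LC` the lever arm from the joint centre to the load-cell
origin and inertial terms neglected during stance. DMAMA for one stance
phase (heel strike HS to toe-off TO) is the impulse ratio

```
DMAMA = ∫[HS,TO] M_ankle dt  /  ‖ ∫[HS,TO] (Fx, Fy) dt ‖
```

— a length: the mean anterior moment arm of the ground-reaction impulse
about the ankle, reported in mm and as % of prosthetic foot length.
Integrals are trapezoidal on the measured (nonuniform, ~150 Hz) sample
times. A stiffer forefoot or an uphill slope moves DMAMA anteriorly, which
is what makes it usable as a closed-loop stiffness-control target.

The package implements, as composable estimator-style components:

- **`synthetic_gait`** (`dmama.synthetic`) — multi-subject gait-session
  generator with known ground truth: per-stride DMAMA targets drawn from a
  linear model (subject intercepts, stiffness slope, incline slope, negative
  stiffness×incline interaction), mode-specific stance waveforms, sampling
  jitter, sensor noise, transition strides.
- **`frame_calibration`** (`dmama.calibration`) — `FrameCalibrator`:
  rotation-vector (Rodrigues) averaging of calibration samples into the
  definitive sensor-to-shank rotation plus offset averaging.
- **`stride_pipeline`** (`dmama.strides`) — 8%-body-weight sagittal-force
  event detection with debouncing, stride segmentation, transition
  exclusion, 100 Hz resampling for the classifier path.
- **`dmama_metric`** (`dmama.metric`) — joint moments, per-stride DMAMA,
  moving-average smoothing for slow-adapting control.
- **`locomotion_classifier`** (`dmama.classify`) — 9 channels × 6 statistics
  = 54 features from a pre-toe-off window, greedy forward selection, window
  optimization (100–500 ms in 33 ms steps), per-(subject, stiffness) LDA
  with 10-fold cross-validation.
- **`sensitivity_analysis`** (`dmama.sensitivity`) — subject-independent
  fits with per-subject intercepts, per-subject regressions, cross-fit R²
  (may be negative), stiffness×incline interaction regression.
- **CLI** (`dmama.cli`) — `simulate`, `calibrate`, `segment`, `dmama`,
  `classify`, `sensitivity`, `interaction`, `run`.

## Worked example

```python
import json
from dmama import RunConfig, SessionConfig, run_pipeline

report = run_pipeline(RunConfig(session=SessionConfig(subjects=2, seed=42),
                                out_dir="demo_run", seed=42))
print(json.dumps(report["dmama"], indent=2))
for mode in ("down_ramp", "level", "up_ramp"):
    f = report["sensitivity"]["stiffness_by_mode"][mode]["subject_independent"]
    print(f"{mode:11s} slope {f['slope']:.3f} %FL/increment  "
          f"p {f['p_value']:.2e}  R2 {f['r_squared']:.3f}")
print("classifier accuracy:",
      report["classifier"]["overall_accuracy_pct"], "%")
```

prints (exactly, for this seed):

```
{
  "n_strides": 588,
  "n_included": 564,
  "mean_pct_foot": 15.087228049938313,
  "sd_pct_foot": 4.3590461684214965,
  "smoothed_tail_pct_foot": 18.895898381170586
}
down_ramp   slope 4.064 %FL/increment  p 3.66e-03  R2 0.967
level       slope 2.567 %FL/increment  p 3.43e-04  R2 0.996
up_ramp     slope 2.255 %FL/increment  p 2.54e-03  R2 0.984
classifier accuracy: 100.0 %
```

Reading it: two simulated subjects walked the five-mode circuit at three
stiffness settings (588 stances; transition strides excluded). The pooled
DMAMA-versus-stiffness slope is positive in all walking modes and largest
going downhill, and steeper slopes shrink it — the saturation captured by a
negative stiffness×incline interaction. The mode classifier, trained only
on load-cell-derived features, separates the five modes cleanly on these
synthetic waveforms.

The same run from the shell:

```bash
dmama run --seed 42 --out demo_run
dmama simulate --seed 7 --out session/     # stage-by-stage variant
dmama calibrate --samples session/subject00_calibration.csv \
      --foot-length 0.24 --body-weight 883 --out geom.json
dmama segment --session session/subject00_session.csv --geometry geom.json \
      --labels session/subject00_samples.csv --out strides.csv
dmama dmama --session session/subject00_session.csv --geometry geom.json \
      --strides strides.csv --out dmama.csv
dmama sensitivity --dmama dmama.csv --driver stiffness --out fits.json
```

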