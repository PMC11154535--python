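# cagewatch

Camera-only monitoring of a small animal (e.g. a hamster) in its home cage.
From top-view color video, `cagewatch` extracts **behavioral** features —
movement, body-shape change, direction change — and an **internal-state**
feature — a heart-rate proxy from green-channel micro-variation (video
photoplethysmography) — and flags non-routine states with a one-class SVM
trained on routine days. It is aimed at researchers and tool-builders who
want continuous, non-contact welfare monitoring without wearable sensors.

## Method

Per frame *t* of the analysis window:

1. **Segmentation.** Candidate masks come from a pluggable backend (default:
   HSV color thresholds + connected components; an adapter for external
   instance-segmentation detectors exists). The largest candidate is the
   animal region *B*; its ordered outer contour {xᵢ}, contour centroid
   **G**(t), eye position **F**(t) (largest eye-colored component in *B*'s
   bounding box), and area *N* are recorded.
2. **Behavioral features.**
   - movement m(t) = ‖**G**(t) − **G**(t−1)‖
   - body extent r(t) = ‖**G**(t) − **F**(t)‖, change r′(t) = r(t) − r(t−1)
   - direction θ(t): the PCA axis θ⁽ᵐ⁾ of the contour (eigenvector of the
     largest eigenvalue of the contour covariance), disambiguated and
     averaged with the centroid-to-eye angle θ⁽ᶜ⁾ = atan2(F_y−G_y, F_x−G_x);
     change θ′(t) wrapped to (−π, π].
3. **Cardiac feature.** Mean green value H(t) over a γ-pixel square around
   **G**(t), band-passed 4.76–7.14 Hz (285–428 beats/min) with a zero-phase
   2nd-order Butterworth filter; peaks by windowed local-maximum search;
   inter-peak intervals T give the rate series h(t) = t_H / T (t_H = 0.7 s).
4. **Anomaly detection.** Complete samples Z = (m, r, r′, θ′, h) are
   standardized and scored by a ν-parameterized one-class SVM with Gaussian
   kernel exp(−γ‖z−z′‖²); f(t) = 0 marks normal, 1 anomalous. (ν, γ) are
   chosen by 5-fold CV maximizing the held-out normal-classification rate on
   routine data. Alerts are debounced (3 consecutive anomalous samples).

Because no recordings ship with the package, a synthetic-scene generator
renders ground-truthed cage videos (moving, rotating, stretching elliptical
animal with eye spots, pulsating green channel, optional startle stimulus)
against which every stage is verified end to end.

## Worked example

Simulate a 30 s default scene (640×480, 60 fps) whose animal is startled at
20 s, then calibrate from frame 0. The rectangle coordinates below come from
the scene's `ground_truth.csv` (frame 0 centroid at (481, 356), eye at
(460, 349)); on real footage you would read them off the calibration image:

```sh
cagewatch simulate --out scratch/scene --seed 5 --stimulus-onset 20
cagewatch calibrate --image scratch/scene \
    --body-rect 478,353,484,359 --eye-rect 459,349,460,350 \
    --length-rect 431,306,531,406 \
    --body-pad 0.03,0.08,0.08 --eye-pad 0.08,0.15,0.12 \
    --out scratch/profile.yaml
cagewatch extract --video scratch/scene --profile scratch/profile.yaml \
    --out scratch/features.csv
```

The `extract` step prints the frame accounting:

```json
{"frames": 1800, "complete_samples": 1778, "incomplete": 22, "no_detection": 0}
```

— all 1800 frames had a detected animal; 22 lacked a complete feature
vector (differences are undefined at the sequence start and h(t) until the
second pulse peak), leaving 1778 samples. Train on the routine (pre-onset,
t < 1200) rows only, then score the whole recording:

```sh
cagewatch train --features scratch/features_pre.csv --out scratch/model.bin
cagewatch monitor --video scratch/scene --profile scratch/profile.yaml \
    --model scratch/model.bin --out scratch/run
```

```json
{"frames": 1800, "complete_samples": 1778, "incomplete": 22,
 "no_detection": 0, "anomaly_fraction": 0.3374578177727784,
 "n_alerts": 1, "alert_frames": [1202]}
```

The debounced alert fires at frame 1202 — 2 frames (33 ms) after the
stimulus began changing the simulated animal's movement, turning and pulse —
and about a third of all samples (the post-onset ones) score anomalous.
`cagewatch report` adds per-state feature statistics, time-series plots and
(when ground-truth labels exist) a confusion matrix; `cagewatch tune` runs
the cross-validated (ν, γ) grid search.

As a library: `cagewatch.synthetic.SyntheticScene`,
`cagewatch.pipeline.extract_features`, `train_model`, `score_features`,
`cagewatch.anomaly.select_params` / `baseline_compare` mirror the CLI.

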