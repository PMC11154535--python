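# Methods

## Problem and model

A single animal is filmed from above against a static cage background. Three
per-frame behavioral quantities and one internal-state quantity summarize
its state:

- **m(t)** (px/frame): Euclidean displacement of the body centroid between
  consecutive frames.
- **r(t), r′(t)** (px, px/frame): distance from the centroid **G** to the
  eye position **F** and its change. r grows when the body stretches,
  shrinks when the animal curls.
- **θ(t), θ′(t)** (rad, rad/frame): body direction and its change. The
  contour's first principal component gives an *axis* (defined mod π); the
  centroid→eye vector gives an *orientation* (mod 2π) that resolves which
  end is the head. The axis is flipped by 180° when that brings it closer
  to the eye direction, then the two are averaged circularly. Angles are in
  image coordinates (x-positive = 0 rad, y down); θ′ is wrapped to (−π, π].
- **h(t)**: heart-rate proxy. Blood-volume changes modulate skin color; the
  mean green value over a square patch around the centroid carries a weak
  periodic component at the pulse frequency. After bandpass filtering,
  inter-peak intervals T yield h = t_H / T, beats per t_H-second window.

A one-class SVM with Gaussian kernel learns the support of routine behavior
from complete samples Z = (m, r, r′, θ′, h) and labels new samples
normal (0) or anomalous (1).

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| passband (f_l, f_h) | 4.76, 7.14 | Hz | 285–428 beats/min, resting pulse band of a small rodent; configurable |
| filter | Butterworth, effective order 2, zero-phase | — | zero phase keeps peak times unshifted; causal variant behind a flag for live use |
| t_H | 0.7 | s | scaling of the rate channel; raw frequency is h / t_H |
| γ (region C side) | min(a_x, a_y)/2 | px | keeps the green patch inside the body for typical postures |
| α_th | 0.1 · a_x · a_y | px² | minimum credible body area; tolerant of partial occlusion |
| PCA eigenvalue-ratio gate | λ₁/λ₂ ≥ 1.2 | — | a curled (near-circular) body has no axis; below the gate θ falls back to the eye direction |
| ν grid | 10⁻⁴, 10⁻³, 10⁻² | — | endpoints as commonly practiced for near-clean training data; log-spaced because no step is canonical |
| kernel γ grid | 0.01…1 step 0.01 | — | standard dense sweep |
| alert debounce | 3 consecutive samples | — | suppresses single-frame flickers; raw f(t) always exported |

## Numerical choices

- **Peak picking ("mountain climbing").** A sample is a peak when it
  strictly exceeds every earlier sample and is ≥ every later sample within
  ⌊f_s/f_h⌋ − 1 samples on each side; ties go to the earliest index and
  endpoints are never peaks. The window enforces a minimum spacing of one
  period of the upper cutoff; the one-sample guard below the full period
  matters because a pulse at the upper cutoff has sampled peak spacings
  that alternate around f_s/f_h and sometimes quantize one sample short —
  a full-period window would suppress alternate beats and halve the
  recovered rate.
- **Rate series.** h(t) holds the most recent *completed* inter-peak
  interval (causal zero-order hold): defined from the second peak onward,
  changing only at peak times, NaN on masked frames. Gaps in the raw trace
  (no detection, area < α_th) are bridged by linear interpolation before
  filtering and re-masked after, so filter transients cannot fabricate
  beats; peaks inside masked spans are discarded.
- **One-class decision rule.** At ν ~ 10⁻⁴ the trained model places many
  training points exactly on the decision boundary; their decision values
  are zero up to solver tolerance and a strict sign rule would flag an
  arbitrary subset. A sample is therefore anomalous only when its decision
  value is below −10⁻⁶ (solver tolerance 10⁻⁸). The epsilon sits orders of
  magnitude above numerical noise and below any genuine outlier's margin.
- **Standardization.** The five features mix px, rad and beats; columns are
  standardized by training-set mean/sd before the shared Euclidean kernel
  (a no-standardization switch exists for strict replication). Constant
  features (sd = 0) are dropped with a warning.
- **Centroid.** Computed from the *contour* points (the position proxy used
  throughout); this weights the boundary, so it is not identical to the
  all-pixel centroid — a config switch (`use_mask_centroid`) selects the
  latter for comparison. Contours come from Moore border following on the
  hole-filled largest component (8-connectivity, outer boundary only).
- **Hue wraparound** is not modeled by the threshold type; calibration
  rejects rectangles whose hue spread exceeds half the hue scale instead of
  silently folding. The HSV scale of a profile is declared explicitly
  (`unit`, `opencv`, or `degrees`) because published threshold listings are
  ambiguous about theirs; printed min/max pairs are sorted on load.
- **Missingness.** A feature needing frame t−1 is missing at sequence
  starts and after any no-detection frame; missing features propagate to
  sample assembly, where only complete rows survive. Nothing is ever
  imputed. The identity frames = complete + incomplete + no-detection is
  enforced and reported on every run.

## Synthetic scenes: what they emulate, and what not

The generator renders an anti-aliased ellipse of a distinct HSV body color
with two dark eye spots near the head, on a static light background:
piecewise-constant speed (default 3 px/frame) with a turn rate resampled
every second (σ = 0.02 rad/frame) and wall reflection; a periodically
breathing major axis (±20%, 0.2 Hz); a green-channel sinusoid on body
pixels (default 5.5 Hz, 3 levels amplitude) standing in for the
photoplethysmographic signal — the default frequency is deliberately not an
integer divisor of the frame rate, since a pulse phase-locked to the frame
clock would yield frame-exact peak spacing and a degenerate constant rate
series no real animal produces; full-frame Gaussian sensor noise (σ = 2
levels); and an optional stimulus after which speed ×2.5, turn rate ×3 and
pulse frequency ×0.8 — the signature of a startled animal (more, faster
turning; the pulse proxy drifting out of its routine band). One eye spot is
rendered 25% larger so the largest-component rule resolves the same eye
every frame; otherwise ties would flip F between eyes and inject spurious
θ′ noise that real (asymmetric) animals do not produce.

Frames are rendered lazily and deterministically — frame t is a pure
function of (seed, t) — so long scenes never occupy memory and identical
seeds give byte-identical pixels.

Passing tests on these scenes show that the *pipeline machinery* recovers
known kinematics, pulse and state changes through rendering, segmentation,
filtering and classification. They do not show robustness to fur texture,
shadows, specular highlights, occlusion by cage furniture, lighting drift,
or genuine cardiac variability — the generator has none of these. The
published deployment of this class of system reports exactly such failure
modes (shadow-induced direction inversions, curled postures without an
axis); the gates above (eigenvalue ratio, α_th, debouncing) are the
corresponding mitigations, but their real-world effectiveness cannot be
established synthetically.

## Problem sizes used in tests and the acceptance script

Scenes are 256×192 or 320×240 px at 60 fps with a 20–26 px semi-major axis
— small frames chosen so the full suite and the acceptance script each run
in minutes on one CPU. Frame size is a free parameter of the study design
(features are resolution-covariant), so the choice affects runtime, not the
properties being verified: pulse recovery uses three 30 s scenes (4.8, 5.5,
7.0 Hz); stimulus detection uses five 32 s scenes with onset at 20 s;
the ν-property uses 10×400 Gaussian samples; the grid search uses a 3×10
(ν, γ) grid with 5 folds on 480 samples.

## Known limitations

- PCA orientation on *rasterized* contours carries an irreducible ~1–2°
  bias from direction-dependent boundary-pixel density (independent of
  resolution); sub-degree accuracy holds for continuous contour point sets.
- The eye-direction angle is exact only when the detected eye is a stable
  landmark; with two equal eye components the largest-component rule is
  arbitrary.
- h(t) inherits the frame clock: at 60 fps a 7 Hz pulse quantizes to 8/9
  frame intervals, bounding single-interval accuracy at ~6%; median-based
  estimates stay within 5%.
- The instance-segmentation backend is an adapter only; no detector weights
  ship with the package, and the color-threshold backend is the tested
  default.
- Live capture is out of scope; monitoring is offline or by tailing a
  growing frame directory.
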