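"""Ground-truthed synthetic cage scenes.

Renders a single elliptical "animal" of a distinct HSV body color with two
dark eye spots at the head end, moving over a static light background:

* trajectory: piecewise-constant speed and turn rate (resampled once per
  second), heading reflected at the walls so the body never leaves the frame;
* posture: the semi-major axis breathes periodically (stretch/curl);
* pulse: body pixels' green channel is modulated sinusoidally at a
  controlled frequency inside the cardiac passband, emulating the
  photoplethysmographic color change of blood flow (background pixels are
  not modulated);
* an optional stimulus event after which speed and turn rate are multiplied
  up and pulse frequency down — the behavioral signature of a startled
  animal;
* per-pixel Gaussian sensor noise over the whole frame.

Frames are rendered lazily and deterministically: frame t depends only on
(seed, t), so a 30 s scene never needs to be held in memory and identical
seeds give byte-identical frames.  Sub-pixel positions are anti-aliased so
centroid recovery can beat 1-px quantization.

The generator reports per-frame ground truth (centroid, orientation, axes,
eye position, pulse phase and instantaneous frequency, anomaly label) for
every accuracy check downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator, Optional, Tuple

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from .config import CalibrationProfile, ConfigError, CropSpec, HsvRange


@dataclass
class StimulusSpec:
    """Post-onset dynamics change: speed/turn up, pulse frequency down."""

    onset_s: float
    speed_mult: float = 2.5
    turn_mult: float = 3.0
    pulse_mult: float = 0.8      # < 1: heart rate tends to decrease


@dataclass
class SceneConfig:
    width: int = 640
    height: int = 480
    fps: float = 60.0
    duration_s: float = 30.0
    # colors, unit HSV
    body_hsv: Tuple[float, float, float] = (0.08, 0.55, 0.55)
    eye_hsv: Tuple[float, float, float] = (0.60, 0.35, 0.15)
    background_hsv: Tuple[float, float, float] = (0.12, 0.05, 0.85)
    # body geometry, px
    semi_major: float = 40.0
    semi_minor: float = 16.0
    stretch_amp: float = 0.2      # fractional breathing of the major axis
    stretch_freq: float = 0.2     # Hz
    # eyes (toward the head end of the major axis; kept well interior so the
    # eye spots never sever the head tip from the body mask)
    n_eyes: int = 2
    eye_offset_frac: float = 0.55   # of semi-major, along the axis
    eye_lateral_frac: float = 0.25  # of semi-minor, across the axis
    eye_radius_frac: float = 0.18   # of semi-minor
    # motion
    speed: float = 3.0            # px/frame
    turn_rate_mean: float = 0.0   # rad/frame, deterministic component
    turn_rate_sd: float = 0.02    # rad/frame, resampled per interval
    turn_interval_s: float = 1.0
    start_pos: Optional[Tuple[float, float]] = None
    start_heading: Optional[float] = None
    # pulse; default deliberately not an integer divisor of fps: a pulse
    # phase-locked to the frame clock would give frame-exact peak spacing
    # and a degenerate (constant) rate series no real animal produces
    pulse_freq: float = 5.5       # Hz, must lie inside (0, fps/2)
    pulse_amp: float = 3.0        # green levels (0..255 scale)
    # noise
    noise_sd: float = 2.0         # per-pixel Gaussian, levels
    stimulus: Optional[StimulusSpec] = None
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def validate(self) -> None:
        if not (0 < self.pulse_freq < self.fps / 2):
            raise ConfigError("pulse_freq must be in (0, fps/2)")
        if self.stimulus is not None:
            if not (0 < self.stimulus.onset_s < self.duration_s):
                raise ConfigError("stimulus onset must fall inside the scene")
            if not (0 < self.stimulus.pulse_mult * self.pulse_freq < self.fps / 2):
                raise ConfigError("post-stimulus pulse frequency outside (0, fps/2)")
        margin = self._margin()
        if 2 * margin >= min(self.width, self.height):
            raise ConfigError("ellipse (with stretch) does not fit in the frame")

    def _margin(self) -> float:
        return self.semi_major * (1.0 + self.stretch_amp) + 3.0

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneConfig":
        d = json.loads(Path(path).read_text())
        if d.get("stimulus") is not None:
            d["stimulus"] = StimulusSpec(**d["stimulus"])
        for k in ("body_hsv", "eye_hsv", "background_hsv", "start_pos"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def _hsv_to_rgb255(hsv: Tuple[float, float, float]) -> np.ndarray:
    return hsv2rgb(np.asarray(hsv, dtype=float).reshape(1, 1, 3)).reshape(3) * 255.0


class SyntheticScene:
    """Lazy, deterministic frame source plus aligned ground truth.

    Iterate for frames, or call :meth:`frame` for random access;
    :meth:`ground_truth` returns the per-frame truth table.
    """

    def __init__(self, config: SceneConfig):
        config.validate()
        self.config = config
        self._body_rgb = _hsv_to_rgb255(config.body_hsv)
        self._eye_rgb = _hsv_to_rgb255(config.eye_hsv)
        bg = _hsv_to_rgb255(config.background_hsv)
        self._bg_f = np.broadcast_to(
            bg.astype(np.float32), (config.height, config.width, 3)).copy()
        self._simulate_trajectory()

    # -- trajectory & ground truth ---------------------------------------
    def _simulate_trajectory(self) -> None:
        c = self.config
        n = c.n_frames
        rng = np.random.default_rng([c.seed, 0])
        margin = c._margin()
        onset_frame = (int(round(c.stimulus.onset_s * c.fps))
                       if c.stimulus is not None else n + 1)
        pos = np.empty((n, 2))
        heading = np.empty(n)
        a_t = np.empty(n)
        phase = np.empty(n)
        f0_t = np.empty(n)
        if c.start_pos is not None:
            x, y = float(c.start_pos[0]), float(c.start_pos[1])
        else:
            x = margin + rng.random() * (c.width - 2 * margin)
            y = margin + rng.random() * (c.height - 2 * margin)
        th = (float(c.start_heading) if c.start_heading is not None
              else rng.random() * 2 * math.pi)
        phi = rng.random() * 2 * math.pi
        turn_interval = max(1, int(round(c.turn_interval_s * c.fps)))
        turn = 0.0
        for t in range(n):
            post = t >= onset_frame
            speed = c.speed * (c.stimulus.speed_mult if post else 1.0)
            turn_sd = c.turn_rate_sd * (c.stimulus.turn_mult if post else 1.0)
            f0 = c.pulse_freq * (c.stimulus.pulse_mult if post else 1.0)
            if t % turn_interval == 0:
                turn = c.turn_rate_mean + rng.normal(0.0, turn_sd) \
                    if turn_sd > 0 else c.turn_rate_mean
            th += turn
            nx = x + speed * math.cos(th)
            ny = y + speed * math.sin(th)
            if nx < margin or nx > c.width - margin:
                th = math.pi - th          # reflect off a vertical wall
                nx = x + speed * math.cos(th)
            if ny < margin or ny > c.height - margin:
                th = -th                   # reflect off a horizontal wall
                ny = y + speed * math.sin(th)
            x = min(max(nx, margin), c.width - margin)
            y = min(max(ny, margin), c.height - margin)
            if not (margin - 1 <= x <= c.width - margin + 1
                    and margin - 1 <= y <= c.height - margin + 1):
                raise ConfigError(f"ellipse leaves the frame at frame {t}")
            pos[t] = (x, y)
            heading[t] = math.atan2(math.sin(th), math.cos(th))
            a_t[t] = c.semi_major * (
                1.0 + c.stretch_amp * math.sin(2 * math.pi * c.stretch_freq
                                               * t / c.fps))
            phase[t] = phi
            f0_t[t] = f0
            phi += 2 * math.pi * f0 / c.fps
        self._pos, self._heading, self._a, self._phase, self._f0 = (
            pos, heading, a_t, phase, f0_t)
        self._onset_frame = onset_frame

    def _eye_centers(self, t: int) -> list[tuple[np.ndarray, float]]:
        """[(center_xy, radius)] — first entry is the dominant (larger) eye."""
        c = self.config
        if c.n_eyes == 0:
            return []
        a, b = self._a[t], c.semi_minor
        th = self._heading[t]
        axis = np.array([math.cos(th), math.sin(th)])
        lateral = np.array([-math.sin(th), math.cos(th)])
        mid = self._pos[t] + c.eye_offset_frac * a * axis
        r = c.eye_radius_frac * b
        if c.n_eyes == 1:
            return [(mid, r)]
        off = c.eye_lateral_frac * b * lateral
        # dominant eye 25% larger so the largest-component rule is stable
        return [(mid + off, r * 1.25), (mid - off, r)]

    def ground_truth(self) -> pd.DataFrame:
        c = self.config
        n = c.n_frames
        rows = []
        for t in range(n):
            eyes = self._eye_centers(t)
            ex, ey = (eyes[0][0] if eyes else (math.nan, math.nan))
            r_true = (float(np.hypot(*(np.asarray([ex, ey]) - self._pos[t])))
                      if eyes else math.nan)
            rows.append({
                "t": t, "time_s": t / c.fps,
                "cx": self._pos[t, 0], "cy": self._pos[t, 1],
                "heading": self._heading[t], "a": self._a[t],
                "b": c.semi_minor, "eye_x": ex, "eye_y": ey,
                "r_true": r_true, "pulse_phase": self._phase[t],
                "f0": self._f0[t],
                "anomaly": int(t >= self._onset_frame)})
        return pd.DataFrame(rows)

    # -- rendering --------------------------------------------------------
    def _body_coverage(self, t: int, xx: np.ndarray, yy: np.ndarray
                       ) -> np.ndarray:
        c = self.config
        a, b = self._a[t], c.semi_minor
        th = self._heading[t]
        dx = xx - self._pos[t, 0]
        dy = yy - self._pos[t, 1]
        u = (dx * math.cos(th) + dy * math.sin(th)) / a
        v = (-dx * math.sin(th) + dy * math.cos(th)) / b
        f = np.sqrt(u * u + v * v)
        # ~1 px anti-aliased edge at the minor axis
        return np.clip(0.5 + (1.0 - f) * min(a, b), 0.0, 1.0)

    def frame(self, t: int) -> np.ndarray:
        """Render frame t as an RGB uint8 raster (deterministic in (seed, t))."""
        c = self.config
        if not (0 <= t < c.n_frames):
            raise IndexError(t)
        img = self._bg_f.copy()
        margin = int(math.ceil(c._margin())) + 2
        cx, cy = self._pos[t]
        x0 = max(0, int(cx) - margin); x1 = min(c.width, int(cx) + margin + 1)
        y0 = max(0, int(cy) - margin); y1 = min(c.height, int(cy) + margin + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        alpha = self._body_coverage(t, xx, yy)[..., None]
        body = self._body_rgb.copy()
        body[1] += c.pulse_amp * math.sin(self._phase[t])
        patch = img[y0:y1, x0:x1]
        patch[:] = alpha * body + (1.0 - alpha) * patch
        for center, radius in self._eye_centers(t):
            d = np.hypot(xx - center[0], yy - center[1])
            ae = np.clip(0.5 + (radius - d), 0.0, 1.0)[..., None]
            patch[:] = ae * self._eye_rgb + (1.0 - ae) * patch
        if c.noise_sd > 0:
            rng = np.random.default_rng([c.seed, 1, t])
            img += rng.standard_normal(img.shape, dtype=np.float32) * c.noise_sd
        return np.clip(img, 0.0, 255.0).astype(np.uint8)

    def gt_body_mask(self, t: int) -> np.ndarray:
        """Ground-truth body-colored pixels: ellipse coverage >= 0.5, minus
        the eye disks (eye pixels carry eye color, not body color)."""
        c = self.config
        yy, xx = np.mgrid[0:c.height, 0:c.width].astype(np.float64)
        mask = self._body_coverage(t, xx, yy) >= 0.5
        for center, radius in self._eye_centers(t):
            mask &= np.hypot(xx - center[0], yy - center[1]) > radius + 0.5
        return mask

    def __len__(self) -> int:
        return self.config.n_frames

    def __iter__(self) -> Iterator[np.ndarray]:
        for t in range(len(self)):
            yield self.frame(t)

    def write_pngs(self, out_dir: str | Path) -> Path:
        import imageio.v3 as iio
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        width = len(str(len(self) - 1))
        for t, fr in enumerate(self):
            iio.imwrite(out / f"frame_{t:0{width}d}.png", fr)
        self.ground_truth().to_csv(out / "ground_truth.csv", index=False)
        self.config.to_json(out / "scene.json")
        return out


def generate_scene(config: SceneConfig) -> tuple[SyntheticScene, pd.DataFrame]:
    """Build the scene and its ground-truth table."""
    scene = SyntheticScene(config)
    return scene, scene.ground_truth()


def stimulus_scenario(config: SceneConfig) -> tuple[SyntheticScene, pd.DataFrame]:
    """Scene with a stimulus event; defaults to onset at 60% of the duration
    with the standard multipliers when the config carries none."""
    if config.stimulus is None:
        from dataclasses import replace
        config = replace(config, stimulus=StimulusSpec(
            onset_s=0.6 * config.duration_s))
    return generate_scene(config)


def profile_from_scene(config: SceneConfig,
                       area_fraction: float = 0.1) -> CalibrationProfile:
    """Calibration profile matching a scene's colors and geometry.

    Pads are wide enough to absorb the pulse modulation, sensor noise up to
    sigma ~4 levels and anti-aliased edge blending, while still excluding
    the background and eye colors on at least one channel.
    """
    bh, bs, bv = config.body_hsv
    eh, es, ev = config.eye_hsv
    clip = lambda lo, hi: (max(0.0, lo), min(1.0, hi))
    body = HsvRange(*clip(bh - 0.05, bh + 0.05), *clip(bs - 0.20, bs + 0.20),
                    *clip(bv - 0.15, bv + 0.15))
    eye = HsvRange(*clip(eh - 0.12, eh + 0.12), *clip(es - 0.18, es + 0.18),
                   *clip(ev - 0.10, ev + 0.10))
    ax = 2.0 * config.semi_major * (1.0 + config.stretch_amp)
    ay = 2.0 * config.semi_minor
    crop = CropSpec(0, 0, config.width, config.height)
    return CalibrationProfile(body_range=body, eye_range=eye, ax=ax, ay=ay,
                              alpha_th=area_fraction * ax * ay, crop=crop,
                              fps=config.fps, hsv_scale="unit")
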