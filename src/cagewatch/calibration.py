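"""Calibration: color thresholds, body-length constants and the analysis crop.

A single calibration frame (e.g. the first video frame) plus three
user-specified rectangles drive everything downstream:

* a rectangle on the animal's body -> the body HSV range,
* a rectangle containing only an eye -> the eye HSV range,
* a rectangle enclosing the whole stretched animal -> body lengths
  (ax, ay) and the minimum-area gate alpha_th.

Interactive clicking is out of scope; rectangles arrive as coordinates.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .config import (HSV_SCALES, CalibrationProfile, ConfigError, CropSpec,
                     HsvRange, RectSpec)


def frame_to_hsv(image: np.ndarray) -> np.ndarray:
    """RGB raster (uint8 or float) -> HSV float array on the unit scale.

    Vectorized single-pass conversion (same definition as
    ``skimage.color.rgb2hsv``, against which it is unit-tested); kept local
    because it runs once per video frame and dominates per-frame cost.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ConfigError(f"expected HxWx3 color raster, got shape {img.shape}")
    if img.dtype == np.uint8:
        rgb = img[..., :3].astype(np.float32) * np.float32(1 / 255.0)
    else:
        rgb = np.clip(img[..., :3], 0.0, 1.0).astype(np.float32)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = np.max(rgb, axis=-1)
    mn = np.min(rgb, axis=-1)
    delta = mx - mn
    s = np.where(mx > 0, delta / np.where(mx > 0, mx, 1), 0.0)
    d = np.where(delta > 0, delta, 1)
    rmax = mx == r
    gmax = (mx == g) & ~rmax
    bmax = (mx == b) & ~rmax & ~gmax
    h = np.where(rmax, (g - b) / d, 0.0)
    h = np.where(gmax, 2.0 + (b - r) / d, h)
    h = np.where(bmax, 4.0 + (r - g) / d, h)
    h = (h / 6.0) % 1.0
    h[delta == 0] = 0.0
    return np.stack([h, s, mx], axis=-1)


def derive_hsv_range(image: np.ndarray, rect: RectSpec,
                     pad: float | Sequence[float] = 0.0,
                     scale: str = "unit") -> HsvRange:
    """Channel-wise (min - pad, max + pad) over the rectangle's pixels in HSV.

    ``pad`` is a scalar or per-channel (h, s, v) triple *on the target scale*;
    the result is clipped to the scale's representable range.  Exact min/max
    is used (not percentiles): the rectangle's color information *is* the
    definition of the animal's color.

    Rectangles whose hue spread exceeds half the hue scale are rejected:
    the range type does not model hue wraparound, and silently folding a
    red-ish region crossing hue 0 would corrupt the range.
    """
    hsv = frame_to_hsv(image)
    rect = rect.normalized()
    rect.validate_in(hsv.shape[:2])
    patch = hsv[rect.pa[1]:rect.pb[1], rect.pa[0]:rect.pb[0]]
    lo = patch.reshape(-1, 3).min(axis=0)
    hi = patch.reshape(-1, 3).max(axis=0)
    if hi[0] - lo[0] > 0.5:
        raise ConfigError(
            "hue spread exceeds half the hue scale (likely wraparound across "
            "hue 0); choose a rectangle with a tighter hue distribution")
    hs, ss, vs = HSV_SCALES.get(scale, (None,) * 3)
    if hs is None:
        raise ConfigError(f"unknown HSV scale {scale!r}")
    scales = np.array([hs, ss, vs])
    pad_arr = np.broadcast_to(np.asarray(pad, dtype=float), (3,))
    lo_s = np.clip(lo * scales - pad_arr, 0.0, scales)
    hi_s = np.clip(hi * scales + pad_arr, 0.0, scales)
    return HsvRange(lo_s[0], hi_s[0], lo_s[1], hi_s[1], lo_s[2], hi_s[2])


def derive_body_metrics(rect_l: RectSpec,
                        area_fraction: float = 0.1) -> Tuple[float, float, float]:
    """Body lengths and minimum-area gate from the whole-animal rectangle.

    ax, ay are the rectangle's width and height;
    alpha_th = area_fraction * ax * ay.  The fraction (default 0.1) makes the
    gate tolerant of partial occlusion while rejecting fragments.
    """
    rect_l = rect_l.normalized()
    if rect_l.is_empty():
        raise ConfigError(f"degenerate body-length rectangle {rect_l}")
    if not (0.0 < area_fraction <= 1.0):
        raise ConfigError(f"area_fraction must be in (0, 1], got {area_fraction}")
    ax, ay = float(rect_l.width), float(rect_l.height)
    return ax, ay, area_fraction * ax * ay


def crop_region_a(frame: np.ndarray, crop: CropSpec) -> np.ndarray:
    """Cut the analysis window A out of a full frame.

    Returns the rx x ry sub-raster with top-left at (mx, my); pixel intervals
    are half-open, so cropped coordinate (x, y) maps back to source
    coordinate (x + mx, y + my) exactly.
    """
    frame = np.asarray(frame)
    crop.validate_in(frame.shape[:2])
    return frame[crop.my:crop.my + crop.ry, crop.mx:crop.mx + crop.rx]


def calibrate(image: np.ndarray, body_rect: RectSpec, eye_rect: RectSpec,
              length_rect: RectSpec, crop: CropSpec, fps: float = 60.0,
              body_pad: float | Sequence[float] = 0.0,
              eye_pad: float | Sequence[float] = 0.0,
              area_fraction: float = 0.1,
              scale: str = "unit") -> CalibrationProfile:
    """Full calibration from one frame and three rectangles.

    Rectangle coordinates are given in *source-frame* coordinates; ranges are
    derived before cropping, matching a user who marks regions on the raw
    calibration image.
    """
    body_range = derive_hsv_range(image, body_rect, body_pad, scale)
    eye_range = derive_hsv_range(image, eye_rect, eye_pad, scale)
    ax, ay, alpha_th = derive_body_metrics(length_rect, area_fraction)
    crop.validate_in(np.asarray(image).shape[:2])
    return CalibrationProfile(body_range=body_range, eye_range=eye_range,
                              ax=ax, ay=ay, alpha_th=alpha_th, crop=crop,
                              fps=fps, hsv_scale=scale)
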