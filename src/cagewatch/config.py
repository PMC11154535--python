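"""Domain types and config (de)serialization.

All rectangles use a half-open pixel convention: corner ``pa`` is inclusive,
``pb`` exclusive, so a rectangle spanning columns 0..679 is written
``RectSpec((0, y0), (680, y1))`` and has width 680.  Coordinates are 0-based,
x rightward, y downward (image convention).

HSV values can live on different scales depending on the tool that produced
them; a profile therefore declares its scale explicitly.  Supported scales:

``unit``
    H, S, V all in [0, 1] (scikit-image convention).  Internal canonical form.
``opencv``
    H in [0, 180], S and V in [0, 255].
``degrees``
    H in [0, 360], S and V in [0, 100].
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Tuple

import yaml

HSV_SCALES: dict[str, Tuple[float, float, float]] = {
    "unit": (1.0, 1.0, 1.0),
    "opencv": (180.0, 255.0, 255.0),
    "degrees": (360.0, 100.0, 100.0),
}


class ConfigError(ValueError):
    """Invalid configuration or parameter value."""


@dataclass(frozen=True)
class RectSpec:
    """Axis-aligned rectangle given by two diagonal corners (half-open)."""

    pa: Tuple[int, int]
    pb: Tuple[int, int]

    def normalized(self) -> "RectSpec":
        """Return a copy with pa <= pb per axis (corners may be clicked in any order)."""
        xa, xb = sorted((self.pa[0], self.pb[0]))
        ya, yb = sorted((self.pa[1], self.pb[1]))
        return RectSpec((xa, ya), (xb, yb))

    @property
    def width(self) -> int:
        r = self.normalized()
        return r.pb[0] - r.pa[0]

    @property
    def height(self) -> int:
        r = self.normalized()
        return r.pb[1] - r.pa[1]

    def is_empty(self) -> bool:
        return self.width <= 0 or self.height <= 0

    def validate_in(self, shape: Tuple[int, int]) -> None:
        """Raise ConfigError unless the rectangle is non-empty and inside an
        image of (height, width) ``shape``."""
        r = self.normalized()
        if r.is_empty():
            raise ConfigError(f"empty rectangle {self}")
        h, w = shape[:2]
        if r.pa[0] < 0 or r.pa[1] < 0 or r.pb[0] > w or r.pb[1] > h:
            raise ConfigError(f"rectangle {r} exceeds image bounds {w}x{h}")

    def inflated(self, pad: int, shape: Tuple[int, int] | None = None) -> "RectSpec":
        r = self.normalized()
        xa, ya = r.pa[0] - pad, r.pa[1] - pad
        xb, yb = r.pb[0] + pad, r.pb[1] + pad
        if shape is not None:
            h, w = shape[:2]
            xa, ya = max(0, xa), max(0, ya)
            xb, yb = min(w, xb), min(h, yb)
        return RectSpec((xa, ya), (xb, yb))


@dataclass
class HsvRange:
    """Channel-wise HSV bounds on a declared scale (min <= max per channel).

    Hue wraparound (ranges crossing 0) is intentionally unsupported; see
    :func:`cagewatch.calibration.derive_hsv_range`.
    """

    h_min: float
    h_max: float
    s_min: float
    s_max: float
    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.h_min, self.h_max, "h"),
            (self.s_min, self.s_max, "s"),
            (self.v_min, self.v_max, "v"),
        ):
            if lo > hi:
                raise ConfigError(f"HsvRange: {name}_min={lo} > {name}_max={hi}")

    @classmethod
    def from_sorted(cls, h: Tuple[float, float], s: Tuple[float, float],
                    v: Tuple[float, float]) -> "HsvRange":
        """Build a range sorting each (a, b) pair; tolerates swapped listings."""
        h, s, v = sorted(h), sorted(s), sorted(v)
        return cls(h[0], h[1], s[0], s[1], v[0], v[1])

    def to_unit(self, scale: str) -> "HsvRange":
        """Convert bounds to the canonical unit scale."""
        try:
            hs, ss, vs = HSV_SCALES[scale]
        except KeyError:
            raise ConfigError(f"unknown HSV scale {scale!r}; one of {sorted(HSV_SCALES)}")
        return HsvRange(self.h_min / hs, self.h_max / hs,
                        self.s_min / ss, self.s_max / ss,
                        self.v_min / vs, self.v_max / vs)

    def as_tuple(self) -> Tuple[float, float, float, float, float, float]:
        return (self.h_min, self.h_max, self.s_min, self.s_max, self.v_min, self.v_max)


@dataclass
class CropSpec:
    """Analysis window A: top-left margin (mx, my), size rx x ry."""

    mx: int
    my: int
    rx: int
    ry: int

    def validate_in(self, shape: Tuple[int, int]) -> None:
        h, w = shape[:2]
        if self.mx < 0 or self.my < 0 or self.rx <= 0 or self.ry <= 0:
            raise ConfigError(f"invalid crop {self}")
        if self.mx + self.rx > w or self.my + self.ry > h:
            raise ConfigError(
                f"crop {self} exceeds frame bounds {w}x{h}")


@dataclass
class CalibrationProfile:
    """Everything the per-frame stages need: color thresholds, body-length
    constants, the minimum-area gate and the analysis crop."""

    body_range: HsvRange
    eye_range: HsvRange
    ax: float                      # body length along x, px
    ay: float                      # body length along y, px
    alpha_th: float                # minimum valid area, px^2
    crop: CropSpec
    fps: float = 60.0
    hsv_scale: str = "unit"
    use_mask_centroid: bool = False  # centroid from all mask pixels, not contour

    def __post_init__(self) -> None:
        if self.ax <= 0 or self.ay <= 0:
            raise ConfigError("body lengths ax, ay must be positive")
        if not (0 < self.alpha_th <= self.ax * self.ay):
            raise ConfigError("alpha_th must be in (0, ax*ay]")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.hsv_scale not in HSV_SCALES:
            raise ConfigError(f"unknown HSV scale {self.hsv_scale!r}")

    # -- flat key/value serialization -------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"hsv_scale": self.hsv_scale, "fps": self.fps,
                   "ax": self.ax, "ay": self.ay, "alpha_th": self.alpha_th,
                   "use_mask_centroid": self.use_mask_centroid}
        for prefix, rng in (("body", self.body_range), ("eye", self.eye_range)):
            for k, v in zip(("h_min", "h_max", "s_min", "s_max", "v_min", "v_max"),
                            rng.as_tuple()):
                d[f"{prefix}.{k}"] = float(v)
        for k in ("mx", "my", "rx", "ry"):
            d[f"crop.{k}"] = getattr(self.crop, k)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationProfile":
        def rng(prefix: str) -> HsvRange:
            g = lambda k: float(d[f"{prefix}.{k}"])
            # sort each printed pair: published threshold listings sometimes
            # swap min and max
            return HsvRange.from_sorted((g("h_min"), g("h_max")),
                                        (g("s_min"), g("s_max")),
                                        (g("v_min"), g("v_max")))
        crop = CropSpec(int(d["crop.mx"]), int(d["crop.my"]),
                        int(d["crop.rx"]), int(d["crop.ry"]))
        return cls(body_range=rng("body"), eye_range=rng("eye"),
                   ax=float(d["ax"]), ay=float(d["ay"]),
                   alpha_th=float(d["alpha_th"]), crop=crop,
                   fps=float(d.get("fps", 60.0)),
                   hsv_scale=str(d.get("hsv_scale", "unit")),
                   use_mask_centroid=bool(d.get("use_mask_centroid", False)))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2, sort_keys=True))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationProfile":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def config_hash(obj) -> str:
    """Stable short hash of a (nested) plain-data config, for model files."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    elif hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]
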