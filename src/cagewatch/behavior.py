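"""Per-frame behavioral features.

From the segmentation stream the package derives, per frame t:

* ``m(t)``   — movement: Euclidean displacement of the centroid G between
  consecutive frames (px/frame);
* ``r(t)``   — body extent: distance from centroid G to eye position F (px),
  large when the body is stretched, small when curled;
* ``r'(t)``  — extent change r(t) - r(t-1) (px/frame);
* ``theta(t)`` — body direction (rad, image coordinates, x-positive = 0 rad,
  y pointing down), combining the PCA axis of the contour with the
  centroid-to-eye vector;
* ``theta'(t)`` — direction change, wrapped to (-pi, pi] (rad/frame).

The PCA axis is orientation-free (defined mod pi); the centroid-to-eye
vector disambiguates which end is the head.  Features needing frame t-1 are
missing (NaN) at segment starts and after any no-detection frame; missing
values are propagated, never imputed.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .segmentation import SegmentationResult

TWO_PI = 2.0 * math.pi


def wrap_angle(a: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    w = -((-a + math.pi) % TWO_PI - math.pi)
    return w


def movement(g_t: Sequence[float], g_prev: Sequence[float]) -> float:
    """Centroid displacement between consecutive frames (px/frame)."""
    d = np.asarray(g_t, dtype=float) - np.asarray(g_prev, dtype=float)
    return float(np.hypot(d[0], d[1]))


def body_extent(g: Sequence[float], f: Sequence[float]) -> float:
    """Distance between centroid G and eye position F (px)."""
    d = np.asarray(g, dtype=float) - np.asarray(f, dtype=float)
    return float(np.hypot(d[0], d[1]))


def extent_change(r_t: float, r_prev: float) -> float:
    """r(t) - r(t-1): positive while stretching, negative while curling."""
    return float(r_t) - float(r_prev)


def pca_direction(contour: np.ndarray,
                  min_eig_ratio: float = 1.2) -> Optional[float]:
    """Axis angle of the contour's first principal component, in (-pi/2, pi/2].

    The contour coordinates are centered, the 2x2 covariance matrix formed,
    and the eigenvector of the largest eigenvalue taken.  When the eigenvalue
    ratio lambda1/lambda2 falls below ``min_eig_ratio`` the contour is nearly
    isotropic (a curled-up animal has no body axis) and None is returned.
    """
    pts = np.asarray(contour, dtype=np.float64)
    if pts.ndim != 2 or len(pts) < 2 or np.ptp(pts, axis=0).max() == 0:
        return None
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)          # ascending eigenvalues
    lam2, lam1 = float(evals[0]), float(evals[1])
    if lam1 <= 0 or (lam2 > 0 and lam1 / lam2 < min_eig_ratio):
        return None
    w1 = evecs[:, 1]
    if w1[0] == 0:
        return math.pi / 2
    theta = math.atan(w1[1] / w1[0])
    return theta if theta != -math.pi / 2 else math.pi / 2


def eye_direction(g: Sequence[float], f: Sequence[float],
                  strict: bool = False) -> Optional[float]:
    """Angle of the vector from centroid G toward eye F, in (-pi, pi].

    The default is the quadrant-aware two-argument form, so "direction"
    means centroid-toward-head and front/back are distinguishable.  With
    ``strict=True`` the quadrant-blind single-argument arctan of
    (Gy-Fy)/(Gx-Fx) is used instead (range (-pi/2, pi/2]); it cannot tell
    head from tail and is kept only for comparison.
    """
    gx, gy = float(g[0]), float(g[1])
    fx, fy = float(f[0]), float(f[1])
    if gx == fx and gy == fy:
        return None
    if strict:
        if gx == fx:
            return math.pi / 2
        return math.atan((gy - fy) / (gx - fx))
    return math.atan2(fy - gy, fx - gx)


def combined_direction(theta_m: Optional[float],
                       theta_c: Optional[float]) -> Optional[float]:
    """Fuse the PCA axis and the centroid-to-eye direction.

    The PCA axis is defined only mod pi; it is flipped by 180 degrees when
    that brings it closer to theta_c, then the two are averaged circularly
    (mapped within pi of each other before the arithmetic mean).  With the
    axis missing (isotropic contour) the eye direction alone is returned.
    """
    if theta_c is None:
        return None
    if theta_m is None:
        return wrap_angle(theta_c)
    flipped = wrap_angle(theta_m + math.pi)
    d_keep = abs(wrap_angle(theta_m - theta_c))
    d_flip = abs(wrap_angle(flipped - theta_c))
    tm = theta_m if d_keep <= d_flip else flipped
    return wrap_angle(theta_c + wrap_angle(tm - theta_c) / 2.0)


def direction_change(theta_t: float, theta_prev: float) -> float:
    """Wrapped angular difference theta(t) - theta(t-1) in (-pi, pi]."""
    return wrap_angle(float(theta_t) - float(theta_prev))


def compute_features(results: Sequence[SegmentationResult],
                     min_eig_ratio: float = 1.2,
                     strict_eye_angle: bool = False) -> pd.DataFrame:
    """Per-frame feature table from a segmentation stream.

    Columns: t, m, r, r_prime, theta, theta_prime (NaN where missing) plus
    valid_mask / valid_eye flags and the area.  Differences are formed only
    across consecutive frame indices with valid predecessors.
    """
    rows = []
    prev: dict = {"t": None, "g": None, "r": None, "theta": None}
    for res in results:
        t = res.frame_index
        m = r = r_prime = theta = theta_prime = math.nan
        g = res.centroid if res.valid_mask else None
        f = res.eye if (res.valid_mask and res.valid_eye) else None
        if g is not None:
            if prev["g"] is not None and prev["t"] == t - 1:
                m = movement(g, prev["g"])
            if f is not None:
                r = body_extent(g, f)
                if prev["r"] is not None and prev["t"] == t - 1 \
                        and not math.isnan(prev["r"]):
                    r_prime = extent_change(r, prev["r"])
                theta_c = eye_direction(g, f, strict=strict_eye_angle)
                theta_m = pca_direction(res.contour, min_eig_ratio) \
                    if res.contour is not None else None
                th = combined_direction(theta_m, theta_c)
                if th is not None:
                    theta = th
                    if prev["theta"] is not None and prev["t"] == t - 1 \
                            and not math.isnan(prev["theta"]):
                        theta_prime = direction_change(theta, prev["theta"])
        rows.append({"t": t, "m": m, "r": r, "r_prime": r_prime,
                     "theta": theta, "theta_prime": theta_prime,
                     "area": res.area, "valid_mask": res.valid_mask,
                     "valid_eye": res.valid_eye})
        prev = {"t": t, "g": g,
                "r": r if not math.isnan(r) else None,
                "theta": theta if not math.isnan(theta) else None}
    return pd.DataFrame(rows)
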