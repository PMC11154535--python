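"""Per-frame animal segmentation.

Each frame of the analysis window A is reduced to the animal region B (the
largest candidate mask), its ordered outer contour, the contour centroid
G(t), the eye position F(t) found by color inside B's bounding box, and the
mask area.  Backends propose candidate masks; the default ``color_threshold``
backend is fully self-contained (HSV in-range + connected components).  An
``instance_segmentation`` adapter accepts any external per-instance detector
(e.g. a pretrained network) but is never loaded unless explicitly configured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label

from .calibration import frame_to_hsv
from .config import CalibrationProfile, ConfigError, HsvRange, RectSpec


class NoDetection(Exception):
    """Raised by low-level ops when a mask/contour cannot be produced."""


@dataclass
class SegmentationResult:
    """Everything downstream feature stages need about one frame."""

    frame_index: int
    mask: Optional[np.ndarray]          # bool raster over region A, or None
    contour: Optional[np.ndarray]       # (I, 2) int array of (x, y), ordered
    centroid: Optional[np.ndarray]      # (Gx, Gy) float
    eye: Optional[np.ndarray]           # (Fx, Fy) float, or None
    area: int                           # pixel count of region B (0 if none)
    valid_mask: bool
    valid_eye: bool


# ---------------------------------------------------------------------------
# contour extraction: Moore border following
# ---------------------------------------------------------------------------

# 8-neighborhood in clockwise order starting from West, image coords (dy, dx)
_MOORE = np.array([(0, -1), (-1, -1), (-1, 0), (-1, 1),
                   (0, 1), (1, 1), (1, 0), (1, -1)], dtype=np.int64)


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Ordered outer boundary of the largest connected component.

    Moore border following (clockwise, 8-connectivity) on the hole-filled
    component.  Every returned point is a foreground pixel with at least one
    background 8-neighbor; points are returned once each, in traversal
    order, as an (I, 2) array of (x, y).

    Raises NoDetection on an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoDetection("empty mask")
    lab = label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    comp = lab == counts.argmax()
    comp = ndimage.binary_fill_holes(comp)
    padded = np.pad(comp, 1)

    ys, xs = np.nonzero(padded)
    start = (int(ys[0]), int(xs[0]))          # topmost, then leftmost
    offs = [tuple(o) for o in _MOORE]
    dir_index = {o: i for i, o in enumerate(offs)}
    # backtrack: the West neighbor of start is background by construction
    cur, back_dir = start, 0                  # back_dir: index of (b - cur)
    points = [start]
    first_move: tuple | None = None
    max_steps = 4 * int(comp.sum()) + 8
    for _ in range(max_steps):
        hit = None
        for k in range(1, 9):
            d = (back_dir + k) % 8
            ny, nx = cur[0] + offs[d][0], cur[1] + offs[d][1]
            if padded[ny, nx]:
                hit = (k, d, (ny, nx))
                break
        if hit is None:
            break                             # isolated single pixel
        k, d, nxt = hit
        if (cur, nxt) == first_move:
            break                             # closed the loop (Jacob's criterion)
        if first_move is None:
            first_move = (cur, nxt)
        # new backtrack = neighbor of OLD cur examined just before the hit
        bd = (back_dir + k - 1) % 8
        b = (cur[0] + offs[bd][0], cur[1] + offs[bd][1])
        points.append(nxt)
        cur = nxt
        back_dir = dir_index[(b[0] - cur[0], b[1] - cur[1])]

    # de-duplicate preserving first-visit order (thin parts are traversed twice)
    seen: set = set()
    ordered = []
    for p in points:
        if p not in seen:
            seen.add(p)
            ordered.append(p)
    pts = np.array(ordered, dtype=np.int64)
    # back to unpadded coords, as (x, y)
    return pts[:, ::-1] - 1


def centroid_of(contour: np.ndarray) -> np.ndarray:
    """Arithmetic mean of contour point coordinates (the position proxy G)."""
    contour = np.asarray(contour, dtype=np.float64)
    if contour.size == 0:
        raise NoDetection("empty contour")
    return contour.mean(axis=0)


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------

def _inrange_mask(hsv_unit: np.ndarray, rng: HsvRange, scale: str) -> np.ndarray:
    r = rng.to_unit(scale)
    h, s, v = hsv_unit[..., 0], hsv_unit[..., 1], hsv_unit[..., 2]
    return ((h >= r.h_min) & (h <= r.h_max) &
            (s >= r.s_min) & (s <= r.s_max) &
            (v >= r.v_min) & (v <= r.v_max))


class ColorThresholdBackend:
    """Candidate masks = connected components of the body-color in-range mask.

    Components below ``min_candidate_area`` pixels are discarded as noise
    specks before the largest-candidate rule is applied.
    """

    name = "color_threshold"

    def __init__(self, min_candidate_area: int = 20):
        self.min_candidate_area = min_candidate_area

    def propose(self, frame: np.ndarray, profile: CalibrationProfile,
                hsv: np.ndarray | None = None) -> list[np.ndarray]:
        if hsv is None:
            hsv = frame_to_hsv(frame)
        mask = _inrange_mask(hsv, profile.body_range, profile.hsv_scale)
        if not mask.any():
            return []
        lab = label(mask, connectivity=2)
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        ids = np.nonzero(counts >= self.min_candidate_area)[0]
        return [lab == i for i in ids]


class InstanceSegmentationBackend:
    """Adapter over an external per-instance detector.

    ``detector(frame) -> iterable of (mask, label)``; any instance whose label
    is in ``animal_labels`` counts as a candidate (generic detectors have no
    rodent class, so every animal-like instance is treated as a possible
    subject).  The package ships no detector weights; construction without a
    detector is a configuration error.
    """

    name = "instance_segmentation"

    def __init__(self, detector: Callable[[np.ndarray], Iterable] | None = None,
                 animal_labels: Sequence[str] = ("cat", "dog", "bear", "bird",
                                                 "sheep", "cow", "horse")):
        if detector is None:
            raise ConfigError(
                "instance_segmentation backend needs a detector callable; "
                "none is bundled — use the color_threshold backend or supply one")
        self.detector = detector
        self.animal_labels = set(animal_labels)

    def propose(self, frame: np.ndarray, profile: CalibrationProfile,
                hsv: np.ndarray | None = None) -> list[np.ndarray]:
        out = []
        for mask, lab_name in self.detector(frame):
            if lab_name in self.animal_labels:
                out.append(np.asarray(mask, dtype=bool))
        return out


BACKENDS: dict[str, Callable] = {
    "color_threshold": ColorThresholdBackend,
    "instance_segmentation": InstanceSegmentationBackend,
}


def get_backend(name_or_backend, **kwargs):
    if hasattr(name_or_backend, "propose"):
        return name_or_backend
    try:
        return BACKENDS[name_or_backend](**kwargs)
    except KeyError:
        raise ConfigError(f"unknown backend {name_or_backend!r}; "
                          f"registered: {sorted(BACKENDS)}")


# ---------------------------------------------------------------------------
# per-frame driver
# ---------------------------------------------------------------------------

def detect_eye(frame: np.ndarray, region_b_bbox: RectSpec, eye_range: HsvRange,
               scale: str = "unit",
               hsv: np.ndarray | None = None) -> Optional[np.ndarray]:
    """Centroid of the largest eye-colored component inside the bounding box.

    Returns (Fx, Fy) or None when no eye-colored pixel exists.  When both
    eyes resolve as separate components the larger one wins (a declared
    tie-break, not a biological claim).
    """
    if hsv is None:
        hsv = frame_to_hsv(frame)
    bbox = region_b_bbox.normalized()
    bbox.validate_in(hsv.shape[:2])
    sub = hsv[bbox.pa[1]:bbox.pb[1], bbox.pa[0]:bbox.pb[0]]
    mask = _inrange_mask(sub, eye_range, scale)
    if not mask.any():
        return None
    lab = label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    comp = lab == counts.argmax()
    ys, xs = np.nonzero(comp)
    return np.array([xs.mean() + bbox.pa[0], ys.mean() + bbox.pa[1]])


def segment_frame(frame: np.ndarray, profile: CalibrationProfile,
                  backend="color_threshold", frame_index: int = 0,
                  eye_bbox_pad: int = 2) -> SegmentationResult:
    """Segment one region-A frame into a SegmentationResult.

    The largest candidate mask (by pixel count) becomes region B.  When no
    candidate exists the result carries ``valid_mask=False`` and no features;
    masks are never interpolated across no-detection frames.  The area gate
    (alpha_th) is *not* applied here — area is reported and gated downstream.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ConfigError("empty frame")
    backend = get_backend(backend)
    hsv = frame_to_hsv(frame)
    candidates = backend.propose(frame, profile, hsv=hsv)
    if not candidates:
        return SegmentationResult(frame_index, None, None, None, None, 0,
                                  valid_mask=False, valid_eye=False)
    areas = [int(m.sum()) for m in candidates]
    mask = candidates[int(np.argmax(areas))]
    area = max(areas)
    contour = extract_contour(mask)
    if profile.use_mask_centroid:
        ys, xs = np.nonzero(mask)
        centroid = np.array([xs.mean(), ys.mean()])
    else:
        centroid = centroid_of(contour)
    ys, xs = np.nonzero(mask)
    bbox = RectSpec((int(xs.min()), int(ys.min())),
                    (int(xs.max()) + 1, int(ys.max()) + 1))
    # inflate by 2 px so a 1-px mask erosion cannot clip the eye spot
    bbox = bbox.inflated(eye_bbox_pad, frame.shape[:2])
    eye = detect_eye(frame, bbox, profile.eye_range, profile.hsv_scale, hsv=hsv)
    return SegmentationResult(frame_index, mask, contour, centroid, eye,
                              area, valid_mask=True, valid_eye=eye is not None)
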