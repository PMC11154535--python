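"""End-to-end orchestration: frames -> features -> decisions -> alerts.

The monitoring flow is a single pass over the frame stream:

1. crop each frame to the analysis window A (optional),
2. segment (region B, contour, centroid G, eye F, area),
3. read the green-channel patch around G for the cardiac trace,
4. derive behavioral features and the heart-rate series,
5. assemble complete samples, score with a trained one-class model,
6. debounce anomalous runs into alerts and write artifacts.

Every frame is accounted for:
``frames = complete samples + incomplete + no-detection`` holds exactly,
and the summary JSON reports the three terms.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import anomaly, behavior, cardiac
from .calibration import crop_region_a
from .config import CalibrationProfile, ConfigError
from .segmentation import SegmentationResult, get_backend, segment_frame


def extract_features(frames: Iterable[np.ndarray],
                     profile: CalibrationProfile,
                     backend="color_threshold",
                     gamma_px: Optional[int] = None,
                     fl: float = 4.76, fh: float = 7.14, t_h: float = 0.7,
                     min_eig_ratio: float = 1.2,
                     strict_eye_angle: bool = False,
                     apply_crop: bool = False,
                     ) -> tuple[pd.DataFrame, cardiac.CardiacTrace,
                                list[SegmentationResult]]:
    """Run segmentation + feature extraction over a frame stream.

    Returns the per-frame feature table (m, r, r', theta, theta', h and
    validity flags), the cardiac trace, and the raw segmentation results.
    ``gamma_px`` (side of the green-sampling square C) defaults to
    min(ax, ay)/2 so the patch stays inside the body for typical postures.
    """
    if gamma_px is None:
        gamma_px = max(2, int(min(profile.ax, profile.ay) // 2))
    backend = get_backend(backend)
    results: list[SegmentationResult] = []
    greens: list[float] = []
    for t, frame in enumerate(frames):
        if apply_crop:
            frame = crop_region_a(frame, profile.crop)
        res = segment_frame(frame, profile, backend, frame_index=t)
        results.append(res)
        if res.valid_mask and res.area >= profile.alpha_th:
            greens.append(cardiac.mean_green_patch(frame, res.centroid,
                                                   gamma_px))
        else:
            greens.append(math.nan)          # heartbeat information not extracted
    if not results:
        raise ConfigError("empty input: no frames read")
    feats = behavior.compute_features(results, min_eig_ratio=min_eig_ratio,
                                      strict_eye_angle=strict_eye_angle)
    params = cardiac.CardiacParams(gamma_px=gamma_px, fl=fl, fh=fh,
                                   fs=profile.fps, t_h=t_h)
    trace = cardiac.process_trace(np.asarray(greens), params)
    feats = feats.copy()
    feats["h"] = trace.rate
    return feats, trace, results


def accounting(features: pd.DataFrame) -> dict:
    """Frame accounting: every frame is a complete sample, incomplete, or a
    no-detection; the three terms sum exactly to the frame count."""
    n = len(features)
    no_detection = int((~features["valid_mask"]).sum())
    complete = int((~features[list(anomaly.FEATURES)].isna().any(axis=1)).sum())
    incomplete = n - no_detection - complete
    return {"frames": n, "complete_samples": complete,
            "incomplete": incomplete, "no_detection": no_detection}


def train_model(features: pd.DataFrame, nu: float = 0.0001,
                kernel_gamma: float = 0.25,
                standardize: bool = True) -> anomaly.OneClassModel:
    """Assemble training samples from routine-day features and fit."""
    sm = anomaly.assemble_samples(features, standardize=standardize)
    return anomaly.fit_one_class(sm, nu, kernel_gamma)


def score_features(model: anomaly.OneClassModel, features: pd.DataFrame
                   ) -> pd.DataFrame:
    """Decisions f(t) for every complete sample in a feature table."""
    sm = anomaly.assemble_samples(features, stats=(model.mean, model.sd),
                                  feature_names=model.feature_names,
                                  standardize=model.standardized)
    return anomaly.predict(model, sm)


def run_monitor(frames: Iterable[np.ndarray], profile: CalibrationProfile,
                model: anomaly.OneClassModel, out_dir: str | Path,
                debounce: int = 3, **extract_kwargs) -> dict:
    """Full monitoring pass; writes features/decisions/alerts/summary.

    Artifacts in ``out_dir``: features.csv, cardiac.csv, decisions.csv,
    alerts.csv (debounced onsets), summary.json.  Returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats, trace, _ = extract_features(frames, profile, **extract_kwargs)
    decisions = score_features(model, feats)
    alerts = anomaly.debounce_alerts(decisions, consecutive=debounce)
    feats.to_csv(out / "features.csv", index=False)
    trace.to_frame().to_csv(out / "cardiac.csv", index=False)
    decisions.to_csv(out / "decisions.csv", index=False)
    alerts.to_csv(out / "alerts.csv", index=False)
    summary = accounting(feats)
    summary["anomaly_fraction"] = (float(decisions["f"].mean())
                                   if len(decisions) else math.nan)
    summary["n_alerts"] = int(len(alerts))
    summary["alert_frames"] = [int(a) for a in alerts["alert_frame"]]
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_report(features: pd.DataFrame, decisions: pd.DataFrame,
               out_dir: str | Path,
               labels: Optional[pd.DataFrame] = None,
               seed: int = 0) -> dict:
    """Post-hoc report: per-state feature statistics, optional confusion
    matrices against ground-truth labels, and time-series plots.

    ``labels``, when given, is a frame (t, anomaly) aligned by frame index.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(decisions) and not set(decisions["t"]).issubset(set(features["t"])):
        raise ConfigError("decisions reference frames absent from features")
    report: dict = {}

    merged = features.merge(decisions, on="t", how="inner")
    stats = merged.groupby("f")[list(anomaly.FEATURES)].agg(["mean", "std"])
    stats.to_csv(out / "state_stats.csv")
    report["state_stats"] = {str(k): v for k, v in
                             stats.round(4).to_dict().items()} if len(stats) \
        else {}

    if labels is not None:
        lab = decisions.merge(labels, on="t", how="inner")
        if len(lab) != len(decisions):
            raise ConfigError("labels do not cover every decided frame")
        m = np.zeros((2, 2), dtype=int)
        for a, b in zip(lab["anomaly"], lab["f"]):
            m[int(a), int(b)] += 1
        report["confusion"] = m.tolist()
        (out / "confusion.csv").write_text(
            "true\\pred,f=0,f=1\nnormal,%d,%d\nnot normal,%d,%d\n"
            % (m[0, 0], m[0, 1], m[1, 0], m[1, 1]))

    _plot_features(merged, out / "features.png")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _plot_features(merged: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = list(anomaly.FEATURES)
    fig, axes = plt.subplots(len(cols) + 1, 1, figsize=(8, 10), sharex=True)
    for ax, col in zip(axes, cols):
        ax.plot(merged["t"], merged[col], lw=0.6)
        ax.set_ylabel(col)
    axes[-1].step(merged["t"], merged["f"], where="post", color="crimson")
    axes[-1].set_ylabel("f(t)")
    axes[-1].set_xlabel("frame")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
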