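"""Non-routine-state detection with a one-class SVM.

Per-frame features are assembled into complete sample vectors
Z = (m, r, r', theta', h); frames missing any of the five features are
excluded (never imputed).  Columns are standardized by training-set
mean/sd — the five features mix pixels, radians and beats, so a shared
Euclidean (Gaussian) kernel is only meaningful after standardization; a
``standardize=False`` switch exists for strict replication attempts.

The one-class SVM (Gaussian kernel exp(-gamma ||z - z'||^2)) learns the
support of routine behavior; nu in (0, 1) upper-bounds the fraction of
training samples treated as outliers (the nu-property).  Labels follow the
0 = normal / 1 = anomaly convention.  Hyperparameters (nu, gamma) are picked
by k-fold cross-validation maximizing the held-out normal-classification
rate on routine data, ties broken toward smaller nu then smaller gamma.

``baseline_compare`` fits the supervised baselines (two-class SVM, LDA,
MLP with two hidden layers of 20 units) for a confusion-matrix comparison
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, OneClassSVM

from .config import ConfigError, config_hash

FEATURES = ("m", "r", "r_prime", "theta_prime", "h")

MODEL_FORMAT_VERSION = 1


@dataclass
class SampleMatrix:
    """Complete, standardized feature vectors with their frame indices."""

    X: np.ndarray                    # (Q, n_features), standardized
    frame_index: np.ndarray          # (Q,)
    mean: np.ndarray                 # training-set per-feature mean (raw scale)
    sd: np.ndarray                   # training-set per-feature sd (raw scale)
    feature_names: tuple
    standardized: bool = True

    @property
    def n_samples(self) -> int:
        return len(self.X)


def assemble_samples(features: pd.DataFrame,
                     stats: Optional[tuple[np.ndarray, np.ndarray]] = None,
                     feature_names: Sequence[str] = FEATURES,
                     standardize: bool = True) -> SampleMatrix:
    """Keep frames where all features are present; standardize columns.

    ``stats=None`` fits mean/sd on the kept rows (training); evaluation
    matrices must pass the training stats so train and eval share one scale.
    A constant training feature (sd = 0) is dropped with a warning — it
    carries no information and would blow up the standardization.
    """
    missing = [f for f in feature_names if f not in features.columns]
    if missing:
        raise ConfigError(f"feature table lacks columns {missing}")
    sub = features[list(feature_names)]
    keep = ~sub.isna().any(axis=1)
    X = sub[keep].to_numpy(dtype=np.float64)
    idx = features["t"][keep].to_numpy() if "t" in features.columns \
        else np.nonzero(keep.to_numpy())[0]
    if len(X) == 0:
        raise ConfigError("no complete samples: every frame misses a feature")
    names = tuple(feature_names)
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        # "constant" up to float rounding of the mean
        zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
        if zero.any() and standardize:
            dropped = [n for n, z in zip(names, zero) if z]
            warnings.warn(f"dropping constant feature(s) {dropped} (sd = 0)")
            X = X[:, ~zero]
            mean, sd = mean[~zero], sd[~zero]
            names = tuple(n for n, z in zip(names, zero) if not z)
    else:
        mean, sd = stats
        if len(mean) != X.shape[1]:
            raise ConfigError("training stats do not match feature columns")
    if standardize:
        X = (X - mean) / sd
    return SampleMatrix(X=X, frame_index=np.asarray(idx), mean=mean, sd=sd,
                        feature_names=names, standardized=standardize)


@dataclass
class OneClassModel:
    """Trained one-class SVM plus the training standardization stats.

    ``boundary_tol``: a sample is anomalous when its decision value falls
    below -boundary_tol rather than below 0.  At small nu the solution
    places many training points exactly on the boundary; their decision
    values are zero up to solver tolerance, and the strict sign rule would
    flag an arbitrary half of them.  The epsilon (orders of magnitude above
    solver tolerance, orders below any real outlier's margin) removes that
    numerical jitter without affecting genuinely outlying samples.
    """

    nu: float
    kernel_gamma: float
    svm: OneClassSVM
    mean: np.ndarray
    sd: np.ndarray
    feature_names: tuple
    standardized: bool = True
    boundary_tol: float = 1e-6

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION,
                     "nu": self.nu, "kernel_gamma": self.kernel_gamma,
                     "svm": self.svm, "mean": self.mean, "sd": self.sd,
                     "feature_names": self.feature_names,
                     "standardized": self.standardized,
                     "boundary_tol": self.boundary_tol,
                     "config_hash": config_hash({
                         "nu": self.nu, "gamma": self.kernel_gamma,
                         "features": list(self.feature_names)})}, path)

    @classmethod
    def load(cls, path: str | Path) -> "OneClassModel":
        d = joblib.load(path)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ConfigError(f"unsupported model file version "
                              f"{d.get('format_version')}")
        return cls(nu=d["nu"], kernel_gamma=d["kernel_gamma"], svm=d["svm"],
                   mean=d["mean"], sd=d["sd"],
                   feature_names=tuple(d["feature_names"]),
                   standardized=d["standardized"],
                   boundary_tol=d.get("boundary_tol", 1e-6))


def fit_one_class(train: SampleMatrix, nu: float, kernel_gamma: float,
                  boundary_tol: float = 1e-6) -> OneClassModel:
    """Fit the nu-parameterized one-class SVM with a Gaussian kernel."""
    if not (0.0 < nu < 1.0):
        raise ConfigError(f"nu must be in (0, 1), got {nu}")
    if kernel_gamma <= 0:
        raise ConfigError(f"kernel_gamma must be positive, got {kernel_gamma}")
    if train.n_samples < 2:
        raise ConfigError("need at least 2 training samples")
    svm = OneClassSVM(kernel="rbf", nu=nu, gamma=kernel_gamma,
                      tol=min(1e-8, boundary_tol / 100))
    svm.fit(train.X)
    return OneClassModel(nu=nu, kernel_gamma=kernel_gamma, svm=svm,
                         mean=train.mean, sd=train.sd,
                         feature_names=train.feature_names,
                         standardized=train.standardized,
                         boundary_tol=boundary_tol)


def predict(model: OneClassModel, eval_matrix: SampleMatrix) -> pd.DataFrame:
    """Per-sample decisions f(t): 0 = normal, 1 = anomaly.

    Returns a frame (t, f) aligned with the evaluation matrix's rows;
    frames without a complete sample simply have no row (gaps are reported,
    never imputed).
    """
    if eval_matrix.X.shape[1] != len(model.feature_names):
        raise ConfigError("evaluation matrix column count does not match model")
    if len(eval_matrix.X) == 0:
        return pd.DataFrame({"t": [], "f": []})
    dv = model.svm.decision_function(eval_matrix.X)
    f = (dv < -model.boundary_tol).astype(int)
    return pd.DataFrame({"t": eval_matrix.frame_index, "f": f})


def training_anomaly_fraction(model: OneClassModel,
                              train: SampleMatrix) -> float:
    """Fraction of training samples the model flags (nu-property check)."""
    return float(predict(model, train)["f"].mean())


def select_params(train: SampleMatrix,
                  nu_grid: Sequence[float] = (0.0001, 0.001, 0.01),
                  gamma_grid: Sequence[float] = tuple(np.round(
                      np.arange(0.01, 1.001, 0.01), 2)),
                  k_folds: int = 5,
                  seed: int = 0) -> tuple[float, float, pd.DataFrame]:
    """Grid search (nu, gamma) by k-fold CV on routine-only data.

    Objective: mean over folds of the held-out fraction classified normal
    (routine data should be discriminated as normal).  Returns the
    maximizer, ties broken toward smaller nu then smaller gamma, plus the
    full fold report.
    """
    if k_folds < 2:
        raise ConfigError("k_folds must be >= 2")
    if not len(nu_grid) or not len(gamma_grid):
        raise ConfigError("empty parameter grid")
    if train.n_samples < k_folds:
        raise ConfigError("fewer samples than folds")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(train.X))
    rows = []
    best = None
    for nu in sorted(nu_grid):
        for gamma in sorted(gamma_grid):
            fold_rates = []
            for tr_idx, te_idx in splits:
                svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma, tol=1e-8)
                svm.fit(train.X[tr_idx])
                dv = svm.decision_function(train.X[te_idx])
                fold_rates.append(float((dv >= -1e-6).mean()))
            score = float(np.mean(fold_rates))
            rows.append({"nu": nu, "gamma": gamma,
                         "mean_normal_rate": score,
                         **{f"fold{i}": r for i, r in enumerate(fold_rates)}})
            if best is None or score > best[0]:
                best = (score, nu, gamma)
    report = pd.DataFrame(rows)
    return best[1], best[2], report


def debounce_alerts(decisions: pd.DataFrame, consecutive: int = 3
                    ) -> pd.DataFrame:
    """Alert onsets: runs of >= ``consecutive`` anomalous samples.

    Returns one row per alert with the run's first frame (onset) and the
    frame at which the debounce threshold was met (alert time).  Debouncing
    suppresses single-sample flickers; the raw f(t) stream is unaffected.
    """
    if consecutive < 1:
        raise ConfigError("consecutive must be >= 1")
    f = decisions["f"].to_numpy()
    t = decisions["t"].to_numpy()
    alerts = []
    run_start = None
    run_len = 0
    for i, fi in enumerate(f):
        if fi == 1:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len == consecutive:
                alerts.append({"onset_frame": int(t[run_start]),
                               "alert_frame": int(t[i])})
        else:
            run_len = 0
    return pd.DataFrame(alerts, columns=["onset_frame", "alert_frame"])


def baseline_compare(train_X: np.ndarray, train_y: np.ndarray,
                     eval_X: np.ndarray, eval_y: np.ndarray,
                     seed: int = 0,
                     ocsvm: Optional[OneClassModel] = None,
                     ocsvm_eval: Optional[SampleMatrix] = None,
                     mlp_max_iter: int = 500) -> dict[str, np.ndarray]:
    """Confusion matrices for the supervised baselines (and optionally the
    one-class model) on a labeled evaluation set.

    Rows are true classes (0 = normal, 1 = anomaly), columns predicted; row
    sums equal the true class counts.  The MLP uses two hidden layers of 20
    units (Adam, seeded); LDA and the Gaussian-kernel SVC use library
    defaults.
    """
    classes = np.unique(train_y)
    if len(classes) < 2:
        raise ConfigError("baseline comparison needs both classes in training")

    def confusion(y_true, y_pred) -> np.ndarray:
        m = np.zeros((2, 2), dtype=int)
        for a, b in zip(y_true, y_pred):
            m[int(a), int(b)] += 1
        return m

    out: dict[str, np.ndarray] = {}
    svc = SVC(kernel="rbf").fit(train_X, train_y)
    out["SVM"] = confusion(eval_y, svc.predict(eval_X))
    lda = LinearDiscriminantAnalysis().fit(train_X, train_y)
    out["LDA"] = confusion(eval_y, lda.predict(eval_X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")      # convergence warnings at small n
        mlp = MLPClassifier(hidden_layer_sizes=(20, 20), max_iter=mlp_max_iter,
                            random_state=seed).fit(train_X, train_y)
    out["MLP"] = confusion(eval_y, mlp.predict(eval_X))
    if ocsvm is not None and ocsvm_eval is not None:
        pred = predict(ocsvm, ocsvm_eval)["f"].to_numpy()
        out["OCSVM"] = confusion(eval_y, pred)
    return out


def comparison_table(matrices: dict[str, np.ndarray]) -> str:
    """Markdown rendering of the confusion-matrix comparison."""
    lines = ["| method | true \\ pred | f=0 | f=1 |",
             "|---|---|---|---|"]
    for name, m in matrices.items():
        lines.append(f"| {name} | normal | {m[0, 0]} | {m[0, 1]} |")
        lines.append(f"| {name} | not normal | {m[1, 0]} | {m[1, 1]} |")
    return "\n".join(lines)
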