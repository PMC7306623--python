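"""Sliding-window multivariate decoding of response type from epoch data.

Response-locked epochs spanning [-100, 300) ms are divided into 40
non-overlapping 10 ms windows (5 samples each at 500 Hz).  Per window, the
feature vector concatenates all scalp channels' samples (channel-major:
channel 0's 5 samples, then channel 1's, ...), giving 61 x 5 = 305 features
for the standard montage.  A linear soft-margin SVM (C = 1) is evaluated by
stratified 10-fold cross-validation repeated 10 times (100 train/test
analyses per window, averaged).  The empirical chance level comes from an
identical run in which training labels are shuffled independently for every
cross-validation step.

Class balance: the majority response type is randomly subsampled to the
minority count before decoding, and both classes must have >= 10 trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocessing import EpochSet
from .stats import bonferroni, t_independent, t_paired

__all__ = [
    "WindowGrid",
    "DecodingCurve",
    "build_features",
    "balance_classes",
    "train_linear_classifier",
    "cv_accuracy",
    "shuffled_null",
    "decode_subject",
    "group_analysis",
]

#: response categories collapsed into the "error" class for decoding
ERROR_CATEGORIES = ("detected_error", "undetected_error")
CORRECT_CATEGORIES = ("correct_go",)


@dataclass
class WindowGrid:
    """Non-overlapping sliding windows tiling the decoding epoch."""

    t_min: float = -100.0
    t_max: float = 300.0
    width: float = 10.0
    step: float = 10.0

    def __post_init__(self):
        if self.step != self.width:
            raise ValueError("windows must be non-overlapping (step == width)")
        span = self.t_max - self.t_min
        if abs(span / self.width - round(span / self.width)) > 1e-9:
            raise ValueError("window width must tile the epoch exactly")

    @property
    def n_windows(self) -> int:
        return int(round((self.t_max - self.t_min) / self.width))

    def samples_per_window(self, sampling_rate: float) -> int:
        spw = self.width * sampling_rate / 1000.0
        if abs(spw - round(spw)) > 1e-9:
            raise ValueError("window width must be an integer number of samples")
        return int(round(spw))

    def window_times(self) -> np.ndarray:
        """Start time (ms) of each window."""
        return self.t_min + self.width * np.arange(self.n_windows)


@dataclass
class DecodingCurve:
    """Per-subject decoding result: one accuracy per window, real and shuffled."""

    subject_id: str
    window_start_ms: np.ndarray
    accuracy: np.ndarray
    shuffled_accuracy: np.ndarray
    n_per_class: int
    config: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_id,
                             "window_start_ms": self.window_start_ms,
                             "accuracy": self.accuracy,
                             "shuffled_accuracy": self.shuffled_accuracy})


def build_features(ep: EpochSet, grid: WindowGrid, window_index: int,
                   epoch_indices: np.ndarray | None = None) -> np.ndarray:
    """Trials x features matrix for one analysis window (channel-major)."""
    if not 0 <= window_index < grid.n_windows:
        raise ValueError(f"window_index {window_index} out of range "
                         f"[0, {grid.n_windows})")
    if abs(ep.times[0] - grid.t_min) > 1e-9 or \
            len(ep.times) != grid.n_windows * grid.samples_per_window(ep.sampling_rate):
        raise ValueError("epoch time axis does not match the window grid")
    spw = grid.samples_per_window(ep.sampling_rate)
    s0 = window_index * spw
    scalp = ep.scalp_picks
    idx = np.arange(ep.data.shape[0]) if epoch_indices is None else np.asarray(epoch_indices)
    seg = ep.data[idx][:, scalp, s0:s0 + spw]
    return seg.reshape(len(idx), len(scalp) * spw)


def balance_classes(labels: np.ndarray, seed: int,
                    min_per_class: int = 10) -> np.ndarray:
    """Subsample the majority class to the minority count (order-preserving)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if counts.min() < min_per_class:
        raise ValueError(f"class {classes[np.argmin(counts)]!r} has "
                         f"{counts.min()} trials, below the minimum of {min_per_class}")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    n_min = counts.min()
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) > n_min:
            idx = np.sort(rng.choice(idx, size=n_min, replace=False))
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def train_linear_classifier(X: np.ndarray, y: np.ndarray,
                            C: float = 1.0) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVM; returns (weights, bias). Deterministic.

    The solver tolerance is tightened well below libsvm's default so the
    returned hyperplane is reproducible to optimization precision.
    """
    clf = SVC(kernel="linear", C=C, tol=1e-8)
    clf.fit(np.asarray(X, dtype=float), np.asarray(y))
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def _fold_seeds(seed: int, repeats: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(repeats) % (2 ** 31)


def _cv(X: np.ndarray, y: np.ndarray, folds: int, repeats: int, seed: int,
        C: float, shuffle_labels: bool) -> float:
    """Mean accuracy over folds x repeats; optionally with a shuffled-label
    null (training labels permuted independently per cross-validation step)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"smallest class ({counts.min()}) < folds ({folds}); "
                         "reduce folds explicitly if intended")
    accs = []
    for rep_seed in _fold_seeds(seed, repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rep_seed))
        rng = np.random.default_rng(int(rep_seed) + 1)
        for train, test in skf.split(X, y):
            y_train = y[train]
            if shuffle_labels:
                y_train = y_train[rng.permutation(len(y_train))]
            if len(np.unique(y_train)) < 2:
                accs.append(np.mean(y[test] == y_train[0]))
                continue
            clf = SVC(kernel="linear", C=C)
            clf.fit(X[train], y_train)
            accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    return float(np.mean(accs))


def cv_accuracy(X: np.ndarray, y: np.ndarray, folds: int = 10,
                repeats: int = 10, seed: int = 0, C: float = 1.0) -> float:
    """Repeated stratified k-fold CV accuracy (folds x repeats analyses)."""
    return _cv(X, y, folds, repeats, seed, C, shuffle_labels=False)


def shuffled_null(X: np.ndarray, y: np.ndarray, folds: int = 10,
                  repeats: int = 10, seed: int = 0, C: float = 1.0) -> float:
    """Empirical chance level: same CV, training labels shuffled per step."""
    return _cv(X, y, folds, repeats, seed, C, shuffle_labels=True)


def decode_subject(ep: EpochSet, subject_id: str = "", grid: WindowGrid | None = None,
                   folds: int = 10, repeats: int = 10, seed: int = 0,
                   C: float = 1.0, min_per_class: int = 10) -> DecodingCurve:
    """Full sliding-window decode of errors vs correct responses.

    Detected and undetected errors are collapsed into one class; classes are
    balanced by seeded subsampling; each window yields a real and a
    shuffled-label accuracy.  Deterministic for a fixed seed.
    """
    grid = grid or WindowGrid()
    lab = np.asarray(["error" if l in ERROR_CATEGORIES else
                      "correct" if l in CORRECT_CATEGORIES else "other"
                      for l in ep.labels])
    usable = np.flatnonzero(ep.kept & (lab != "other"))
    ss = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
    kept_rel = balance_classes(lab[usable], int(ss[0]), min_per_class)
    idx = usable[kept_rel]
    y = lab[idx]

    real = np.empty(grid.n_windows)
    null = np.empty(grid.n_windows)
    for w in range(grid.n_windows):
        Xw = build_features(ep, grid, w, epoch_indices=idx)
        real[w] = cv_accuracy(Xw, y, folds, repeats, int(ss[1]) + w, C)
        null[w] = shuffled_null(Xw, y, folds, repeats, int(ss[2]) + w, C)
    return DecodingCurve(subject_id, grid.window_times(), real, null,
                         int((y == "error").sum()),
                         config={"folds": folds, "repeats": repeats, "C": C,
                                 "seed": seed, "csd": ep.csd_applied})


def group_analysis(curves_a: list[DecodingCurve], curves_b: list[DecodingCurve],
                   family_alpha: float = 0.05,
                   names: tuple[str, str] = ("patient", "control")) -> pd.DataFrame:
    """Per-window statistics table for two groups of decoding curves.

    Per window: paired t (real vs shuffled) within each group, and an
    independent t between groups on the real accuracies; significance is
    flagged at the Bonferroni-adjusted alpha family_alpha / n_windows.
    """
    if len(curves_a) < 2 or len(curves_b) < 2:
        raise ValueError("need >= 2 subjects per group")
    grids = [tuple(c.window_start_ms) for c in curves_a + curves_b]
    if len(set(grids)) != 1:
        raise ValueError("window grids differ between subjects")
    wa = np.stack([c.accuracy for c in curves_a])
    wb = np.stack([c.accuracy for c in curves_b])
    sa = np.stack([c.shuffled_accuracy for c in curves_a])
    sb = np.stack([c.shuffled_accuracy for c in curves_b])
    n_windows = wa.shape[1]
    alpha = bonferroni(family_alpha, n_windows)

    width = (curves_a[0].window_start_ms[1] - curves_a[0].window_start_ms[0]
             if n_windows > 1 else 10.0)
    rows = []
    for w in range(n_windows):
        ra = t_paired(wa[:, w], sa[:, w])
        rb = t_paired(wb[:, w], sb[:, w])
        rg = t_independent(wa[:, w], wb[:, w])
        rows.append({
            "window_start_ms": curves_a[0].window_start_ms[w],
            "window_end_ms": curves_a[0].window_start_ms[w] + width,
            f"t_vs_null_{names[0]}": ra.t, f"p_vs_null_{names[0]}": ra.p,
            f"sig_vs_null_{names[0]}": ra.p < alpha,
            f"t_vs_null_{names[1]}": rb.t, f"p_vs_null_{names[1]}": rb.p,
            f"sig_vs_null_{names[1]}": rb.p < alpha,
            "t_between": rg.t, "p_between": rg.p, "sig_between": rg.p < alpha,
        })
    out = pd.DataFrame(rows)
    out.attrs["alpha_adjusted"] = alpha
    return out
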