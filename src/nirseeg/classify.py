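"""Per-window sparse linear classification of mental-task pairs.

For every non-overlapping 1 s window an independent binary classifier is
trained: an L1-penalized linear SVM whose hyperparameter ``C`` (default 2.0)
is divided by the number of training examples, so regularization pressure is
constant across problem sizes (effective C = 0.023 when all 96 epochs of a
balanced pair survive a 10-fold split).  Evaluation uses a 10x10 stratified
cross-validation: per split, each feature is Z-normalized with the training
fold's mean/sd, the held-out fold is scored with Cohen's kappa, and the 100
estimates per window summarize decoding strength; a final model refit on all
data provides the feature weights used for importance ranking.

Cohen's kappa corrects agreement for chance; on a perfectly balanced
two-class problem kappa = 2*accuracy - 1, so kappa 0/0.4/1 correspond to
50/70/100% accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC
import warnings

from ._seeding import child_seed
from .exceptions import ConfigurationError
from .features import WindowedFeatureMatrix

__all__ = [
    "CVScheme",
    "TrainingParams",
    "SparseLinearModel",
    "WindowedCVResult",
    "PeakSummary",
    "cohens_kappa",
    "confusion_2x2",
    "kappa_to_accuracy",
    "delta_kappa_to_accuracy_points",
    "effective_c",
    "train_sparse_linear",
    "run_windowed_cv",
    "peak_summary",
    "delta_kappa_at_window",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified k-fold evaluation (default 10 x 10 = 100 estimates)."""

    n_repeats: int = 10
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.n_folds < 2:
            raise ConfigurationError("need n_repeats >= 1 and n_folds >= 2")

    @property
    def n_estimates(self) -> int:
        return self.n_repeats * self.n_folds


@dataclass(frozen=True)
class TrainingParams:
    """L1-SVM dialect: C scaled by training-set size, squared-hinge loss
    (liblinear's L1-penalized formulation), near-unpenalized intercept."""

    c_base: float = 2.0
    tol: float = 1e-4
    max_iter: int = 5000
    weight_threshold: float = 1e-8  # |w| above this counts as selected

    def __post_init__(self) -> None:
        if self.c_base <= 0:
            raise ConfigurationError("c_base must be positive")


def effective_c(params: TrainingParams, n_train: int) -> float:
    """C divided by the number of training examples (2.0/86 ~ 0.023 for a
    10-fold split of 96 epochs)."""
    if n_train < 1:
        raise ConfigurationError("n_train must be positive")
    return params.c_base / n_train


def confusion_2x2(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Counts [[TP, FN], [FP, TN]] for +1/-1 labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return np.array(
        [
            [np.sum((y_true == 1) & (y_pred == 1)), np.sum((y_true == 1) & (y_pred == -1))],
            [np.sum((y_true == -1) & (y_pred == 1)), np.sum((y_true == -1) & (y_pred == -1))],
        ]
    )


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``confusion`` is a 2x2 count table; p_o is the observed agreement
    (trace / N) and p_e the agreement expected from the marginals.  A
    degenerate table with p_e = 1 (all mass in one cell row/column pattern)
    is defined as kappa = 0.
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2):
        raise ConfigurationError("confusion must be 2x2")
    if np.any(c < 0):
        raise ConfigurationError("confusion counts must be non-negative")
    n = c.sum()
    if n <= 0:
        raise ConfigurationError("confusion table is empty")
    p_o = np.trace(c) / n
    p_e = float(c.sum(axis=1) @ c.sum(axis=0)) / n**2
    if np.isclose(p_e, 1.0):
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_to_accuracy(kappa: float) -> float:
    """Balanced two-class accuracy (percent) equivalent to a kappa value."""
    if not -1.0 <= kappa <= 1.0:
        raise ConfigurationError("kappa must lie in [-1, 1]")
    return 50.0 * (1.0 + kappa)


def delta_kappa_to_accuracy_points(delta_kappa: float) -> float:
    """Balanced-class accuracy change (percentage points) for a kappa change."""
    if not -2.0 <= delta_kappa <= 2.0:
        raise ConfigurationError("a kappa difference must lie in [-2, 2]")
    return 50.0 * delta_kappa


@dataclass
class SparseLinearModel:
    """A trained L1-sparse linear decision rule with its normalization."""

    weights: np.ndarray        # in Z-normalized feature space
    bias: float
    mean: np.ndarray
    sd: np.ndarray
    majority_label: int
    weight_threshold: float = 1e-8
    converged: bool = True

    @property
    def selected(self) -> np.ndarray:
        return np.abs(self.weights) > self.weight_threshold

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        z = (np.asarray(X, dtype=float) - self.mean) / self.sd
        return z @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.n_selected == 0:
            return np.full(len(X), self.majority_label, dtype=int)
        scores = self.decision_function(X)
        pred = np.where(scores >= 0, 1, -1)
        return pred


def train_sparse_linear(
    X: np.ndarray, y: np.ndarray, params: TrainingParams | None = None
) -> SparseLinearModel:
    """Fit the L1-penalized linear SVM on Z-normalized features.

    Normalization statistics come from the given (training) data only.  The
    effective C is ``c_base / n_examples``.  With every weight at zero the
    model predicts the majority training class.
    """
    params = params or TrainingParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ConfigurationError("features must be finite")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ConfigurationError("training labels must contain exactly two classes")
    if not np.array_equal(np.sort(classes), [-1, 1]):
        raise ConfigurationError("labels must be +/-1")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (X - mean) / sd

    clf = LinearSVC(
        penalty="l1",
        loss="squared_hinge",
        dual=False,
        C=effective_c(params, len(y)),
        tol=params.tol,
        max_iter=params.max_iter,
        intercept_scaling=100.0,
        fit_intercept=True,
        random_state=0,  # liblinear's internal shuffle; fixed for reproducibility
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(z, y.astype(int))
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not converged:
        log.debug("liblinear did not converge within %d iterations", params.max_iter)

    pos, neg = int(np.sum(y == 1)), int(np.sum(y == -1))
    majority = 1 if pos >= neg else -1
    return SparseLinearModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        mean=mean,
        sd=sd,
        majority_label=majority,
        weight_threshold=params.weight_threshold,
        converged=converged,
    )


@dataclass
class WindowedCVResult:
    """Per-window CV performance plus the all-data refit models."""

    pair: tuple[str, str]
    perf: pd.DataFrame            # window_start_s, mean_kappa, sd_kappa, n_selected, n_estimates
    kappas: np.ndarray            # (n_windows, n_estimates)
    final_weights: np.ndarray     # (n_windows, n_features), Z-space weights of the refits
    window_starts: np.ndarray
    meta: pd.DataFrame


def run_windowed_cv(
    features: WindowedFeatureMatrix,
    pair: tuple[str, str],
    scheme: CVScheme | None = None,
    params: TrainingParams | None = None,
    *,
    windows: np.ndarray | None = None,
) -> WindowedCVResult:
    """Repeated stratified CV of one task pair, independently per window.

    ``pair[0]`` maps to +1 and ``pair[1]`` to -1.  Folds with a single
    training class are skipped with a warning; fewer than half the expected
    estimates for a window is an error.  Per split, normalization is fitted
    on the training partition only (inside :func:`train_sparse_linear`).
    """
    scheme = scheme or CVScheme()
    params = params or TrainingParams()
    sub = features.select_pair(pair)
    y = np.where(sub.labels.astype(str) == pair[0], 1, -1)
    if np.sum(y == 1) < 2 or np.sum(y == -1) < 2:
        raise ConfigurationError(f"need >= 2 epochs per class for pair {pair}")

    if windows is None:
        window_idx = np.arange(sub.n_windows)
    else:
        window_idx = np.array([sub.window_index(w) for w in windows])
    starts = sub.window_starts[window_idx]

    rows = []
    all_kappas = np.full((len(window_idx), scheme.n_estimates), np.nan)
    final_weights = np.zeros((len(window_idx), sub.n_features))

    for out_i, wi in enumerate(window_idx):
        X = sub.values[:, wi, :]
        est, n_sel = [], []
        for rep in range(scheme.n_repeats):
            skf = StratifiedKFold(
                n_splits=scheme.n_folds,
                shuffle=True,
                random_state=child_seed(scheme.seed, "cv", int(wi), rep),
            )
            for train, test in skf.split(X, y):
                if len(np.unique(y[train])) < 2:
                    log.warning("window %s: single-class training fold skipped", starts[out_i])
                    continue
                model = train_sparse_linear(X[train], y[train], params)
                kappa = cohens_kappa(confusion_2x2(y[test], model.predict(X[test])))
                est.append(kappa)
                n_sel.append(model.n_selected)
        if len(est) < scheme.n_estimates / 2:
            raise ConfigurationError(
                f"window {starts[out_i]} s: only {len(est)} valid CV estimates"
            )
        all_kappas[out_i, : len(est)] = est
        final = train_sparse_linear(X, y, params)
        final_weights[out_i] = final.weights
        rows.append(
            {
                "window_start_s": starts[out_i],
                "mean_kappa": float(np.mean(est)),
                "sd_kappa": float(np.std(est, ddof=1)),
                "n_selected": float(np.mean(n_sel)),
                "n_estimates": len(est),
            }
        )
    perf = pd.DataFrame(rows)
    return WindowedCVResult(pair, perf, all_kappas, final_weights, starts, sub.meta.copy())


@dataclass(frozen=True)
class PeakSummary:
    """Highest window-mean kappa across task execution and when it occurs."""

    peak_kappa: float
    peak_time_s: float


def peak_summary(
    perf: pd.DataFrame, task_range: tuple[float, float] = (0.0, 15.0)
) -> PeakSummary:
    """Peak = max window-mean kappa over windows starting within the task
    (0..14 s); ties break to the earliest window.  Pre-task and post-task
    windows are excluded."""
    mask = (perf["window_start_s"] >= task_range[0]) & (perf["window_start_s"] < task_range[1])
    task = perf[mask].sort_values("window_start_s")
    expected = int(round(task_range[1] - task_range[0]))
    if len(task) != expected:
        raise ConfigurationError(
            f"expected {expected} task windows in [{task_range[0]}, {task_range[1]}), "
            f"got {len(task)}"
        )
    best = task["mean_kappa"].to_numpy().argmax()  # argmax takes the first maximum
    return PeakSummary(
        float(task["mean_kappa"].iloc[best]), float(task["window_start_s"].iloc[best])
    )


def delta_kappa_at_window(
    perf_fused: pd.DataFrame, perf_eeg: pd.DataFrame, window_start_s: float
) -> float:
    """Fusion gain: mean kappa(fused) - mean kappa(EEG) at a given window
    (typically the NIRS peak window w*)."""
    out = []
    for perf in (perf_fused, perf_eeg):
        row = perf[np.isclose(perf["window_start_s"], window_start_s)]
        if len(row) != 1:
            raise ConfigurationError(f"window {window_start_s} s absent from performance table")
        out.append(float(row["mean_kappa"].iloc[0]))
    return out[0] - out[1]
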