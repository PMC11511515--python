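"""Accuracy metrics and the adjusting-parameter sweep harness.

Labeling is evaluated per window: every slide position of the predicted
track is compared with the ground-truth label covering the majority of that
window, with the unclassified class (0) participating as a first-class
label.  The summary statistics are the confusion matrix, overall accuracy
and Cohen's kappa.  Predicted quality scores are evaluated against coach
scores by RMSE, the R^2 and slope of an ordinary least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .labeling import ResponseTrack
from .skeleton import LabelTrack


@dataclass
class EvalResult:
    matrix: pd.DataFrame  # rows = truth, columns = predicted
    overall_accuracy: float
    kappa: float
    n_windows: int


def window_truth_labels(
    truth: LabelTrack, windows: list[tuple[float, float]]
) -> np.ndarray:
    """Majority-overlap ground-truth label per window (0 = background)."""
    return np.array([truth.majority_label(t1, t2) for t1, t2 in windows], dtype=int)


def confusion_and_kappa(
    predicted: ResponseTrack | np.ndarray,
    truth: LabelTrack | np.ndarray,
    class_ids: list[int] | None = None,
) -> EvalResult:
    """Window-level confusion matrix, overall accuracy and Cohen's kappa.

    ``predicted`` may be a ResponseTrack (compared on its own window grid
    against a ground-truth LabelTrack) or a plain label array paired with a
    truth label array.  Class 0 is always included.
    """
    if isinstance(predicted, ResponseTrack):
        if not isinstance(truth, LabelTrack):
            raise TypeError("a ResponseTrack must be paired with a LabelTrack")
        windows = predicted.window_bounds()
        if not windows:
            raise ValueError("empty prediction track")
        lo, hi = windows[0][0], windows[-1][1]
        t_lo, t_hi = truth.span
        if truth.segments and (t_hi <= lo or t_lo >= hi):
            raise ValueError("prediction and truth tracks cover disjoint spans")
        y_pred = predicted.final_labels()
        y_true = window_truth_labels(truth, windows)
        if class_ids is None:
            class_ids = predicted.class_ids
    else:
        y_pred = np.asarray(predicted, dtype=int)
        y_true = np.asarray(truth, dtype=int)
        if y_pred.shape != y_true.shape:
            raise ValueError("label arrays must be aligned")
    labels = sorted(set([0]) | set(class_ids or []) | set(y_true) | set(y_pred))
    M = confusion_matrix(y_true, y_pred, labels=labels)
    oa = float(np.trace(M) / M.sum())
    kappa = (
        1.0
        if np.array_equal(y_true, y_pred)
        else float(cohen_kappa_score(y_true, y_pred, labels=labels))
    )
    matrix = pd.DataFrame(M, index=labels, columns=labels)
    matrix.index.name = "truth"
    matrix.columns.name = "predicted"
    return EvalResult(matrix, oa, kappa, len(y_true))


@dataclass
class ScoreRegression:
    rmse: float
    r2: float  # NaN when truth is constant (flagged)
    slope: float
    intercept: float
    n: int
    constant_truth: bool = False


def score_regression(
    predicted: np.ndarray, truth: np.ndarray
) -> ScoreRegression:
    """RMSE of predicted - truth plus OLS fit of predicted on truth."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape or predicted.size < 2:
        raise ValueError("need >= 2 paired scores")
    rmse = float(np.sqrt(np.mean((predicted - truth) ** 2)))
    if np.all(truth == truth[0]):
        return ScoreRegression(rmse, float("nan"), float("nan"), float("nan"),
                               predicted.size, constant_truth=True)
    fit = stats.linregress(truth, predicted)
    return ScoreRegression(
        rmse, float(fit.rvalue**2), float(fit.slope), float(fit.intercept), predicted.size
    )


# ---------------------------------------------------------------------------
# parameter sweep


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian grid of adjusting parameters (window length, rate, n_D)."""

    delta_ts: tuple[float, ...] = (5.0, 7.0, 10.0, 15.0, 20.0)
    rates: tuple[float, ...] = (30.0, 10.0, 6.0, 4.3)
    n_ds: tuple[int, ...] = (2, 4, 8, 12, 20)

    def cells(self) -> list[tuple[float, float, int]]:
        """All (delta_t, rate, n_D) cells; delta_t outermost, n_D innermost."""
        return list(product(self.delta_ts, self.rates, self.n_ds))

    def __len__(self) -> int:
        return len(self.delta_ts) * len(self.rates) * len(self.n_ds)


def run_sweep(
    grid: SweepGrid,
    train_items,
    test_items=None,
    base_config=None,
) -> pd.DataFrame:
    """Train and evaluate once per grid cell; one row per cell, grid order.

    ``train_items``/``test_items`` are dataset items (sequence + labels);
    evaluation defaults to relabeling the training items.  Deterministic
    given the items and config.
    """
    from .config import PipelineConfig
    from .labeling import label_sequence
    from .pipeline import train

    base = base_config if base_config is not None else PipelineConfig()
    test_items = test_items if test_items is not None else train_items
    rows = []
    for delta_t, rate, n_d in grid.cells():
        cfg = base.model_copy(
            update={"delta_t": delta_t, "fps": rate, "n_d": n_d}
        )
        model = train(train_items, cfg)
        preds, truths = [], []
        for item in test_items:
            track = label_sequence(model, item.sequence)
            preds.append(track.final_labels())
            truths.append(window_truth_labels(item.labels, track.window_bounds()))
        res = confusion_and_kappa(
            np.concatenate(preds), np.concatenate(truths), class_ids=model.class_ids
        )
        rows.append(
            {
                "delta_t": delta_t,
                "rate": rate,
                "n_d": n_d,
                "overall_accuracy": res.overall_accuracy,
                "kappa": res.kappa,
                "n_windows": res.n_windows,
            }
        )
    return pd.DataFrame(rows)
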