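"""Detection/classification scoring and feature-target correlation analysis.

Accuracy and error rate share one denominator — the total number of
evaluated windows — so they sum to exactly 1 in every report:

    accuracy = (TP + TN) / (TP + FP + TN + FN)
    error    = (FN + FP) / (TP + FP + TN + FN)
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred, positive=None):
    """2x2 confusion counts for the given positive class.

    With ``positive=None`` and more than two classes, returns a dict of
    one-vs-rest :class:`ConfusionCounts` per class plus a ``"micro"`` entry
    aggregating them.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"label sequences differ in length: {len(y_true)} vs {len(y_pred)}")
    if positive is not None:
        t = y_true == positive
        p = y_pred == positive
        return ConfusionCounts(
            tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)))
    classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    if len(classes) == 2:
        return confusion(y_true, y_pred, positive=classes[0])
    per = {c: confusion(y_true, y_pred, positive=c) for c in classes}
    per["micro"] = ConfusionCounts(
        tp=sum(c.tp for c in per.values()), tn=sum(c.tn for c in per.values()),
        fp=sum(c.fp for c in per.values()), fn=sum(c.fn for c in per.values()))
    return per


def accuracy_and_error(counts: ConfusionCounts) -> tuple[float, float]:
    """(accuracy, error rate); they sum to 1 by construction."""
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    acc = (counts.tp + counts.tn) / counts.total
    err = (counts.fn + counts.fp) / counts.total
    return acc, err


@dataclass
class CorrelationTable:
    """Pearson correlations among features and against a binary target."""

    feature_feature: np.ndarray
    feature_target: np.ndarray
    feature_names: list[str]
    excluded: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.feature_feature, index=self.feature_names,
                          columns=self.feature_names)
        df["target"] = self.feature_target
        return df

    def plot_heatmap(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        full = np.column_stack([self.feature_feature, self.feature_target])
        im = ax.imshow(full, vmin=-1, vmax=1, cmap="coolwarm")
        ax.set_xticks(range(len(self.feature_names) + 1),
                      self.feature_names + ["target"], rotation=90)
        ax.set_yticks(range(len(self.feature_names)), self.feature_names)
        ax.figure.colorbar(im, ax=ax)
        return ax


def correlation_analysis(features, target) -> CorrelationTable:
    """Pearson correlation of each feature with the others and with the
    (binary) target class.  Constant feature columns are excluded (NaN in
    the table); a constant target is an error."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if y.dtype.kind in "OUSb":  # tokens -> indicator of the non-noise class
        y = (y != "noise").astype(float)
    else:
        y = y.astype(float)
    if np.std(y) == 0:
        raise ValueError("target class is constant")
    sd = X.std(axis=0)
    excluded = [int(i) for i in np.flatnonzero(sd == 0)]
    F = X.shape[1]
    ff = np.full((F, F), np.nan)
    ft = np.full(F, np.nan)
    ok = np.flatnonzero(sd > 0)
    if ok.size:
        sub = np.corrcoef(X[:, ok], rowvar=False)
        ff[np.ix_(ok, ok)] = np.atleast_2d(sub)
        for i in ok:
            ft[i] = np.corrcoef(X[:, i], y)[0, 1]
    names = [f"F{i + 1}" for i in range(F)]
    return CorrelationTable(feature_feature=ff, feature_target=ft,
                            feature_names=names, excluded=excluded)


@dataclass
class DetectionReport:
    """Per-seed accuracies/errors with Table-style mean/high/low summaries."""

    method: str
    per_run: list[dict]  # each: {seed, accuracy, error_rate, tp, tn, fp, fn}

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r["accuracy"] for r in self.per_run])

    @property
    def error_rates(self) -> np.ndarray:
        return np.array([r["error_rate"] for r in self.per_run])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_error(self) -> float:
        return float(self.error_rates.mean())

    def to_frame(self) -> pd.DataFrame:
        """Mean/Highest/Lowest accuracy and error-rate summary (percent)."""
        acc, err = self.accuracies * 100, self.error_rates * 100
        return pd.DataFrame(
            {
                "Accuracy Mean": [acc.mean()], "Accuracy Highest": [acc.max()],
                "Accuracy Lowest": [acc.min()], "Error Mean": [err.mean()],
                "Error Highest": [err.max()], "Error Lowest": [err.min()],
            },
            index=[self.method],
        )

    def summary(self) -> str:
        df = self.to_frame().round(2)
        return f"{len(self.per_run)}-trial report\n{df.to_string()}"


def multi_run_summary(fit_fn, seeds, method: str = "mse") -> DetectionReport:
    """Run ``fit_fn(seed)`` (returning an object with .accuracy, .error_rate
    and .counts) per seed and aggregate the per-trial scores."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    runs = []
    for seed in seeds:
        res = fit_fn(seed)
        runs.append({
            "seed": int(seed), "accuracy": float(res.accuracy),
            "error_rate": float(res.error_rate),
            "tp": res.counts.tp, "tn": res.counts.tn,
            "fp": res.counts.fp, "fn": res.counts.fn,
        })
    return DetectionReport(method=method, per_run=runs)
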