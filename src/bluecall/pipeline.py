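"""The end-to-end detector: features -> mixture-based feature reduction ->
mixture classification, wrapped as a statsmodels-style Model/Results pair.

Workflow per fit (one "trial"):

1. split the labelled windows 70/30, stratified by class, with the trial
   seed;
2. z-score features using training statistics;
3. on the training rows, fit a mixture whose component count is chosen by
   BIC, rank features by |MPP| and keep the top zeta columns;
4. refit the mixture (same K) on the reduced training matrix and map each
   component to the majority class of its members;
5. classify the test rows by the maximum-likelihood rule and score the
   binary call-vs-noise decision.

Trials vary only the split and the EM seed; the feature matrix is extracted
once per dataset.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gmm
from .baselines import dmd_features, pca_features, wavelet_segment_features
from .entropy import mse_matrix
from .evaluate import ConfusionCounts, DetectionReport, accuracy_and_error, confusion, multi_run_summary
from .preprocess import NOISE_LABEL, SegmentSet
from .synth import Benchmark, stratified_split

METHODS = ("mse", "pca", "dmd", "wf")

#: Default retained feature count per extraction method.
DEFAULT_ZETA = {"mse": 4, "pca": 7, "dmd": 5, "wf": 3}


def extract_features(segs, method: str = "mse", m: int = 2, r_coef: float = 0.2,
                     tau_max: int = 12, norm_mode: str = "paper") -> np.ndarray:
    """Per-window feature matrix for the chosen method.

    ``mse`` uses the log-transformed entropy profile; ``pca``/``dmd`` project
    the raw window matrix; ``wf`` uses the wavelet (E, F, H) averages.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    X = segs.segments if isinstance(segs, SegmentSet) else np.asarray(segs, float)
    if method == "mse":
        return mse_matrix(segs, m=m, r_coef=r_coef, tau_max=tau_max,
                          norm_mode=norm_mode).log_values
    if method == "pca":
        n = min(tau_max, X.shape[0] - 1, X.shape[1])
        return pca_features(X, n).projected
    if method == "dmd":
        return dmd_features(segs, n_features=tau_max)
    return wavelet_segment_features(segs)


class CallDetector:
    """Mixture-model call detector over a labelled feature matrix.

    Parameters
    ----------
    features : (s x F) array
        One feature row per analysis window (see :func:`extract_features`).
    labels : sequence of str
        Per-window class tokens; ``"noise"`` marks non-call windows.
    method : str
        Feature-extraction tag, used for reporting and the zeta default.
    zeta : int, optional
        Retained feature count after MPP ranking (method default if omitted).
    k_range : iterable of int
        Candidate mixture sizes for BIC selection.
    task : {"detection", "classification"}
        Detection scores the binary call-vs-noise decision; classification
        keeps the full call-type labels.
    """

    def __init__(self, features, labels, method: str = "mse",
                 zeta: int | None = None, k_range=range(1, 9),
                 test_size: float = 0.3, task: str = "detection",
                 n_init: int = 5, max_iter: int = 500, tol: float = 1e-6,
                 reg_covar: float = 1e-6):
        self.features = np.asarray(features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (windows x features)")
        if len(labels) != self.features.shape[0]:
            raise ValueError("labels must align with feature rows")
        if task not in ("detection", "classification"):
            raise ValueError(f"unknown task {task!r}")
        self.labels = [str(l) for l in labels]
        if task == "detection":
            self.labels = [NOISE_LABEL if l == NOISE_LABEL else "call"
                           for l in self.labels]
        self.method = method
        self.zeta = zeta if zeta is not None else min(
            DEFAULT_ZETA.get(method, 4), self.features.shape[1])
        self.k_range = list(k_range)
        self.test_size = test_size
        self.task = task
        self._fit_kwargs = dict(n_init=n_init, max_iter=max_iter, tol=tol,
                                reg_covar=reg_covar)

    @classmethod
    def from_benchmark(cls, bench: Benchmark, method: str = "mse",
                       **kwargs) -> "CallDetector":
        segs = SegmentSet(segments=bench.segments, window_s=bench.window_s,
                          rate=bench.rate, labels=bench.labels)
        feat_kw = {k: kwargs.pop(k) for k in ("m", "r_coef", "tau_max", "norm_mode")
                   if k in kwargs}
        feats = extract_features(segs, method=method, **feat_kw)
        return cls(feats, bench.labels, method=method, **kwargs)

    @classmethod
    def from_segments(cls, segs: SegmentSet, method: str = "mse", **kwargs
                      ) -> "CallDetector":
        if segs.labels is None:
            raise ValueError("segments carry no labels; annotate them first")
        feat_kw = {k: kwargs.pop(k) for k in ("m", "r_coef", "tau_max", "norm_mode")
                   if k in kwargs}
        feats = extract_features(segs, method=method, **feat_kw)
        return cls(feats, segs.labels, method=method, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "CallDetectorResults":
        """Run one seeded trial of the reduce-refit-classify workflow."""
        rng = np.random.default_rng(seed)
        train_idx, test_idx = stratified_split(self.labels, self.test_size, rng)
        X = self.features
        mu = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd

        K = gmm.select_k(Z[train_idx], self.k_range, seed=seed,
                         **self._fit_kwargs)
        reduction_fit = gmm.GaussianMixtureModel(Z[train_idx]).fit(
            K, seed=seed, **self._fit_kwargs)
        ranking = gmm.rank_features(reduction_fit, Z[train_idx],
                                    standardize=False)
        zeta = min(self.zeta, len(ranking.feature_order))
        psi_train = gmm.reduce(Z[train_idx], ranking, zeta)
        psi_test = gmm.reduce(Z[test_idx], ranking, zeta)

        final = gmm.GaussianMixtureModel(psi_train.values).fit(
            K, seed=seed + 1, **self._fit_kwargs)
        train_components = final.map_cluster(psi_train.values)
        final.class_map = gmm.map_components_to_classes(
            train_components, [self.labels[i] for i in train_idx],
            n_components=final.n_components)
        y_pred = final.ml_classify(psi_test.values)
        y_true = [self.labels[i] for i in test_idx]
        counts = self._score(y_true, y_pred)
        acc, err = accuracy_and_error(counts)
        return CallDetectorResults(
            detector=self, seed=seed, n_components=K, zeta=zeta,
            ranking=ranking, selected_features=psi_train.selected_features,
            mixture=final, train_idx=train_idx, test_idx=test_idx,
            y_true=y_true, y_pred=list(y_pred), counts=counts,
            accuracy=acc, error_rate=err)

    def _score(self, y_true, y_pred) -> ConfusionCounts:
        if self.task == "detection":
            return confusion(y_true, y_pred, positive="call")
        per = confusion(y_true, y_pred)
        return per["micro"] if isinstance(per, dict) else per

    def fit_multi(self, seeds) -> DetectionReport:
        """One trial per seed; aggregated Table-style report."""
        return multi_run_summary(self.fit, seeds, method=self.method)


@dataclass
class CallDetectorResults:
    """One trial's fitted pipeline state and test-set scores."""

    detector: CallDetector
    seed: int
    n_components: int
    zeta: int
    ranking: gmm.FeatureRanking
    selected_features: np.ndarray
    mixture: gmm.GaussianMixtureResults
    train_idx: np.ndarray
    test_idx: np.ndarray
    y_true: list[str]
    y_pred: list[str]
    counts: ConfusionCounts
    accuracy: float
    error_rate: float
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        c = self.counts
        lines = [
            f"{self.detector.method.upper()}-GMM {self.detector.task} trial "
            f"(seed {self.seed})",
            "=" * 52,
            f"windows train/test:  {len(self.train_idx)}/{len(self.test_idx)}",
            f"mixture components:  {self.n_components} (BIC-selected)",
            f"features kept:       {self.zeta} of "
            f"{self.detector.features.shape[1]} "
            f"(columns {self.selected_features.tolist()})",
            f"TP/TN/FP/FN:         {c.tp}/{c.tn}/{c.fp}/{c.fn}",
            f"accuracy:            {self.accuracy:.4f}",
            f"error rate:          {self.error_rate:.4f}",
        ]
        return "\n".join(lines)
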