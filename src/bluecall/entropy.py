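"""Multiscale sample entropy (MSE) feature extraction.

Sample entropy (SampEn) of a series is -ln of the conditional probability
that two length-m templates lying within a Chebyshev tolerance r of each
other still lie within r when extended to length m+1.  Multiscale sample
entropy evaluates SampEn on coarse-grained copies of the series at scale
factors 1..tau_max, where coarse-graining at scale tau replaces consecutive
non-overlapping blocks of tau samples by their mean.  Regular, strongly
tonal call windows have low entropy at the scales that resolve the call's
period; broadband noise windows stay irregular, which is what makes the
entropy profile a discriminative feature vector.

Two normalisation conventions for the match probabilities are provided:

``"paper"``
    the published normalisers T_m = m(M)/2 and T_{m+1} = (m+1)(M-1)/2 with
    M = floor(L/tau) - m + 1 (these are not pair counts, so the
    "probabilities" may exceed 1; entropy differences are unaffected by the
    shared constant only when m is fixed);
``"standard"``
    the classical SampEn pair-count normalisers M(M-1)/2 and
    (M-1)(M-2)/2, under which a constant series has entropy exactly 0.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import SegmentSet

NORM_MODES = ("paper", "standard")

#: Row-block size for the chunked pairwise-distance computation; bounds peak
#: memory at ~block * n * 8 bytes per scale.
_BLOCK = 128


@dataclass(frozen=True)
class CoarseGrainedSeries:
    """A segment averaged over non-overlapping blocks of length tau."""

    values: np.ndarray
    tau: int
    segment_index: int = 0

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MatchCounts:
    """Template-match counts and probabilities for one series and tolerance.

    C_m counts unordered pairs of m-dimensional embedding vectors within the
    Chebyshev tolerance; C_m1 the same among the (m+1)-dimensional vectors.
    T_m / T_m1 are the normalisers of the active norm mode.
    """

    C_m: int
    C_m1: int
    T_m: float
    T_m1: float
    P_m: float
    P_m1: float
    r_abs: float
    m: int
    norm_mode: str


def coarse_grain(segment, tau: int, segment_index: int = 0) -> CoarseGrainedSeries:
    """Average consecutive non-overlapping blocks of length tau.

    Output value j is the mean of samples (j-1)*tau+1 .. j*tau (1-based);
    the partial trailing block is dropped, so the output has floor(L/tau)
    points.  tau=1 returns the segment unchanged.
    """
    x = np.asarray(segment, dtype=float).ravel()
    if tau < 1 or int(tau) != tau:
        raise ValueError(f"tau must be a positive integer, got {tau}")
    if len(x) < tau:
        raise ValueError(f"series of length {len(x)} too short for tau={tau}")
    tau = int(tau)
    n = len(x) // tau
    values = x[: n * tau].reshape(n, tau).mean(axis=1)
    return CoarseGrainedSeries(values=values, tau=tau, segment_index=segment_index)


def embed(series, m: int) -> np.ndarray:
    """All length-m templates of the series with unit stride: an (M x m) array,
    M = len - m + 1."""
    x = _as_values(series)
    if m < 1:
        raise ValueError(f"embedding dimension must be >= 1, got {m}")
    if len(x) < m + 1:
        raise ValueError(
            f"series of length {len(x)} too short to embed at m={m} "
            "(need at least m+1 points)"
        )
    return sliding_window_view(x, m)


def chebyshev(u, v) -> float:
    """Chebyshev (max-coordinate) distance between two equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.max(np.abs(u - v))) if u.size else 0.0


def _as_values(series) -> np.ndarray:
    if isinstance(series, CoarseGrainedSeries):
        return series.values
    return np.asarray(series, dtype=float).ravel()


def _count_similar_pairs(emb: np.ndarray, r_abs: float) -> int:
    """Number of unordered template pairs with Chebyshev distance <= r_abs.

    Chunked over rows so the n^2 distance matrix never materialises whole.
    """
    M, m = emb.shape
    total = 0
    for i0 in range(0, M - 1, _BLOCK):
        i1 = min(i0 + _BLOCK, M - 1)
        tail = emb[i0 + 1:]  # candidate js for rows i0..i1-1
        d = np.abs(np.subtract.outer(emb[i0:i1, 0], tail[:, 0]))
        for dim in range(1, m):
            np.maximum(d, np.abs(np.subtract.outer(emb[i0:i1, dim], tail[:, dim])), out=d)
        hits = d <= r_abs
        # keep only j > i: column c corresponds to j = i0 + 1 + c, row b to i = i0 + b
        rows = np.arange(i0, i1)[:, None]
        cols = np.arange(i0 + 1, M)[None, :]
        total += int(np.count_nonzero(hits & (cols > rows)))
    return total


def count_matches(series, m: int, r_abs: float, norm_mode: str = "paper") -> MatchCounts:
    """Count Chebyshev template matches at dimensions m and m+1.

    Returns the pair counts together with the probabilistic parameters
    P_m = C_m / T_m and P_{m+1} = C_{m+1} / T_{m+1} under the requested
    normalisation mode.
    """
    if norm_mode not in NORM_MODES:
        raise ValueError(f"norm_mode must be one of {NORM_MODES}, got {norm_mode!r}")
    if r_abs <= 0:
        raise ValueError(f"tolerance r_abs must be positive, got {r_abs}")
    x = _as_values(series)
    n = len(x)
    M = n - m + 1  # number of m-dimensional templates
    if M < 2 or n - m < 2:
        raise ValueError(
            f"series of length {n} yields too few templates at m={m} for pair counting"
        )
    C_m = _count_similar_pairs(embed(x, m), r_abs)
    C_m1 = _count_similar_pairs(sliding_window_view(x, m + 1), r_abs)
    if norm_mode == "paper":
        T_m = m * M / 2.0
        T_m1 = (m + 1) * (M - 1) / 2.0
    else:
        T_m = M * (M - 1) / 2.0
        T_m1 = (M - 1) * (M - 2) / 2.0
    return MatchCounts(
        C_m=C_m, C_m1=C_m1, T_m=T_m, T_m1=T_m1,
        P_m=C_m / T_m, P_m1=C_m1 / T_m1,
        r_abs=r_abs, m=m, norm_mode=norm_mode,
    )


def sample_entropy(series, m: int = 2, r_abs: float | None = None,
                   norm_mode: str = "paper", r_coef: float = 0.2) -> float:
    """SampEn = -ln(P_{m+1} / P_m) of one series.

    ``r_abs`` is the absolute Chebyshev tolerance; if omitted it is set to
    ``r_coef`` times the series standard deviation.  When either match count
    is zero the entropy is undefined and NaN is returned (callers impute it;
    see :func:`mse_matrix`).
    """
    x = _as_values(series)
    if r_abs is None:
        sd = float(np.std(x))
        if sd == 0:
            return math.nan if norm_mode == "paper" else 0.0
        r_abs = r_coef * sd
    counts = count_matches(x, m, r_abs, norm_mode)
    if counts.C_m == 0 or counts.C_m1 == 0:
        return math.nan
    return float(-np.log(counts.P_m1 / counts.P_m))


@dataclass
class MSEFeatureMatrix:
    """Per-window entropy profile: entry (k, eta) is SampEn of window k
    coarse-grained at scale eta (columns are scales 1..tau_max).

    ``log_values`` is ln(1 + values), the transform applied before mixture
    modelling to symmetrise the feature distributions.
    """

    values: np.ndarray
    m: int
    r_coef: float
    tau_max: int
    norm_mode: str
    window_s: float | None = None
    rate: float | None = None
    labels: list[str] | None = None
    n_imputed: int = 0
    log_values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.log_values = np.log1p(self.values)

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path, sidecar: bool = True) -> None:
        """Write the matrix as TSV (row = window, columns SE_1..SE_tau) plus a
        JSON metadata sidecar."""
        cols = [f"SE_{eta}" for eta in range(1, self.tau_max + 1)]
        df = pd.DataFrame(self.values, columns=cols)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t", index=False)
        if sidecar:
            meta = {
                "method": "mse", "m": self.m, "r_coef": self.r_coef,
                "tau_max": self.tau_max, "norm_mode": self.norm_mode,
                "window_s": self.window_s, "rate": self.rate,
                "n_imputed": self.n_imputed,
            }
            with open(str(path) + ".meta.json", "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_tsv(cls, path) -> "MSEFeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = df.pop("label").tolist() if "label" in df.columns else None
        try:
            with open(str(path) + ".meta.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"m": 2, "r_coef": 0.2, "tau_max": df.shape[1],
                    "norm_mode": "paper", "window_s": None, "rate": None,
                    "n_imputed": 0}
        return cls(values=df.to_numpy(), m=meta["m"], r_coef=meta["r_coef"],
                   tau_max=meta["tau_max"], norm_mode=meta["norm_mode"],
                   window_s=meta.get("window_s"), rate=meta.get("rate"),
                   labels=labels, n_imputed=meta.get("n_imputed", 0))

    def plot(self, ax=None):
        """Mean entropy-versus-scale profile per label (or overall)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scales = np.arange(1, self.tau_max + 1)
        if self.labels is not None:
            for lab in sorted(set(self.labels)):
                rows = [i for i, l in enumerate(self.labels) if l == lab]
                ax.plot(scales, self.values[rows].mean(axis=0), marker="o", label=lab)
            ax.legend()
        else:
            ax.plot(scales, self.values.mean(axis=0), marker="o")
        ax.set_xlabel("scale factor")
        ax.set_ylabel("sample entropy")
        return ax


def _impute_nonfinite(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace non-finite entries by the column maximum of finite entries.

    Undefined entropy means no template matches were found, i.e. maximal
    irregularity at that scale, so the column's largest observed entropy is
    the faithful stand-in.  A column with no finite entries falls back to
    the global finite maximum (0 if none exists).
    """
    out = values.copy()
    bad = ~np.isfinite(out)
    n_bad = int(bad.sum())
    if n_bad == 0:
        return out, 0
    finite_all = out[np.isfinite(out)]
    global_max = float(finite_all.max()) if finite_all.size else 0.0
    for col in range(out.shape[1]):
        mask = bad[:, col]
        if not mask.any():
            continue
        finite = out[~mask, col]
        fill = float(finite.max()) if finite.size else global_max
        out[mask, col] = fill
    return out, n_bad


def mse_matrix(segs, m: int = 2, r_coef: float = 0.2, tau_max: int = 12,
               norm_mode: str = "paper") -> MSEFeatureMatrix:
    """Multiscale sample entropy feature matrix of a segment set.

    For each window F_k the tolerance is fixed at ``r_coef`` times the
    standard deviation of the unaggregated (scale-1) window and reused at
    every scale, so entropies are comparable across scales.  Entry (k, eta)
    is the SampEn of the scale-eta coarse-grained window; undefined entries
    (zero matches) are imputed by the column maximum of finite entries.
    """
    if isinstance(segs, SegmentSet):
        rows = segs.segments
        window_s, rate, labels = segs.window_s, segs.rate, segs.labels
    else:
        rows = np.asarray(segs, dtype=float)
        window_s = rate = None
        labels = None
    if rows.ndim != 2:
        raise ValueError("expected a 2-D segment matrix")
    L = rows.shape[1]
    if L // tau_max < m + 2:
        raise ValueError(
            f"window length {L} leaves floor(L/tau_max)={L // tau_max} points at "
            f"scale {tau_max}; need at least m+2={m + 2}"
        )
    values = np.empty((rows.shape[0], tau_max))
    for k, row in enumerate(rows):
        sd = float(np.std(row))
        if sd == 0:
            values[k, :] = np.nan
            continue
        r_abs = r_coef * sd
        for eta in range(1, tau_max + 1):
            cg = coarse_grain(row, eta, segment_index=k)
            values[k, eta - 1] = sample_entropy(cg, m=m, r_abs=r_abs,
                                                norm_mode=norm_mode)
    values, n_imputed = _impute_nonfinite(values)
    return MSEFeatureMatrix(values=values, m=m, r_coef=r_coef, tau_max=tau_max,
                            norm_mode=norm_mode, window_s=window_s, rate=rate,
                            labels=labels, n_imputed=n_imputed)
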