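"""Comparison feature extractors: PCA, dynamic mode decomposition, and
continuous-wavelet spectral features.

All three produce one feature row per analysis window from the same
segment matrix the entropy features are built from, so every method feeds
the identical mixture-model back-end and the comparison isolates the
feature extraction step.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import uniform_filter1d
from sklearn.decomposition import PCA

from .preprocess import SegmentSet

_WAVELET = "cmor1.5-1.0"  # complex Morlet: analytic, good tonal localisation


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------
@dataclass
class PCAResult:
    components: np.ndarray       # (n_components x d) orthonormal loadings
    explained_variance: np.ndarray
    projected: np.ndarray        # (s x n_components) scores
    mean: np.ndarray


def pca_features(X, n_components: int) -> PCAResult:
    """Mean-centred SVD projection onto the leading principal components."""
    X = np.asarray(X, dtype=float)
    s, d = X.shape
    if s < 2:
        raise ValueError("need at least 2 observations for PCA")
    if not 1 <= n_components <= min(s, d):
        raise ValueError(
            f"n_components must be in [1, {min(s, d)}], got {n_components}")
    p = PCA(n_components=n_components, svd_solver="full")
    scores = p.fit_transform(X)
    return PCAResult(components=p.components_,
                     explained_variance=p.explained_variance_,
                     projected=scores, mean=p.mean_)


# ---------------------------------------------------------------------------
# DMD
# ---------------------------------------------------------------------------
@dataclass
class DMDResult:
    """Eigenpairs of the best-fit linear one-step operator A = X2 V S^-1 U*."""

    eigenvalues: np.ndarray   # complex, length = rank
    modes: np.ndarray         # (d x rank), columns are spatial modes phi
    amplitudes: np.ndarray    # b = pinv(Phi) x0
    rank: int
    singular_values: np.ndarray


def dmd(X, rank: int | None = None, rank_tol: float = 1e-10) -> DMDResult:
    """Dynamic mode decomposition of a (d x T) snapshot matrix.

    Columns of X are successive states.  The SVD of the first T-1 snapshots
    is truncated to ``rank`` (default: all singular values above
    ``rank_tol`` times the largest); the reduced operator's eigenpairs give
    the DMD eigenvalues and the modes phi = X1 V S^-1 w.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("snapshot matrix must be 2-D with at least 2 columns")
    if not np.any(X):
        raise ValueError("zero snapshot matrix")
    X1, X2 = X[:, :-1], X[:, 1:]
    U, S, Vh = np.linalg.svd(X1, full_matrices=False)
    if rank is None:
        rank = max(int(np.sum(S > rank_tol * S[0])), 1)
    if not 1 <= rank <= min(X.shape[0], X.shape[1] - 1):
        raise ValueError(f"rank must be in [1, {min(X.shape[0], X.shape[1] - 1)}]")
    U, S, Vh = U[:, :rank], S[:rank], Vh[:rank]
    V = Vh.conj().T
    atilde = U.conj().T @ X2 @ V / S
    eigvals, W = np.linalg.eig(atilde)
    modes = X1 @ V @ (W / S[:, None])
    amplitudes = np.linalg.pinv(modes) @ X[:, 0]
    return DMDResult(eigenvalues=eigvals, modes=modes, amplitudes=amplitudes,
                     rank=rank, singular_values=S)


def dmd_features(segs, n_features: int = 12) -> np.ndarray:
    """Per-window DMD features: projection magnitudes onto the leading modes.

    Windows are treated as snapshots (columns) of one matrix; each window's
    feature vector is |pinv(Phi) F_k|, its coefficient magnitudes in the
    retained mode basis.
    """
    X = segs.segments if isinstance(segs, SegmentSet) else np.asarray(segs, float)
    snaps = X.T  # (L x s): columns are windows in temporal order
    rank = min(n_features, snaps.shape[0], snaps.shape[1] - 1)
    res = dmd(snaps, rank=rank)
    coeffs = np.linalg.pinv(res.modes) @ snaps  # (rank x s)
    return np.abs(coeffs).T


# ---------------------------------------------------------------------------
# Wavelet features
# ---------------------------------------------------------------------------
@dataclass
class WaveletFeatureMatrix:
    """Time-resolved wavelet features: per-frame (E, F, H) triples.

    E is the z-scored total smoothed in-band energy, F the spectral
    centroid (Hz) and H the base-2 entropy of the normalised energy
    distribution across scales.  Frames with zero energy carry NaN
    sentinels for F and H.
    """

    rows: np.ndarray            # (T x 3): columns E, F, H
    scales: np.ndarray
    frequencies: np.ndarray     # Hz, one per scale
    smoothing_n: int
    energy: np.ndarray          # (n_scales x T) smoothed energy


def default_scales(rate: float, f_lo: float = 10.0, f_hi: float = 120.0,
                   n_scales: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced CWT scales mapping to f_lo..f_hi Hz (clipped below Nyquist)."""
    f_hi = min(f_hi, 0.45 * rate)
    freqs = np.geomspace(f_lo, f_hi, n_scales)
    scales = pywt.frequency2scale(_WAVELET, freqs / rate)
    return scales, freqs


def energy_centroid(energy: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Energy-weighted mean frequency per frame; NaN where energy is zero."""
    tot = energy.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cent = (freqs[:, None] * energy).sum(axis=0) / tot
    cent[tot == 0] = np.nan
    return cent


def energy_entropy(energy: np.ndarray) -> np.ndarray:
    """Base-2 Shannon entropy of the per-frame energy distribution over scales.

    Bounded by log2(n_scales); exactly 0 when all energy sits at one scale;
    NaN for zero-energy frames.
    """
    tot = energy.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = energy / tot
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    H = -plogp.sum(axis=0)
    H[tot == 0] = np.nan
    return H


def wavelet_features(x, rate: float, scales=None, freqs=None,
                     smoothing_n: int | None = None) -> WaveletFeatureMatrix:
    """CWT-based (E, F, H) features of one waveform.

    The squared CWT magnitude is smoothed along time with a moving average
    of ``smoothing_n`` frames (default: half a second) before the centroid
    and entropy are formed; the energy column is z-scored across frames.
    """
    x = np.asarray(x, dtype=float).ravel()
    if scales is None or freqs is None:
        scales, freqs = default_scales(rate)
    scales = np.asarray(scales, dtype=float)
    if scales.size == 0:
        raise ValueError("scales must be non-empty")
    if smoothing_n is None:
        smoothing_n = max(int(0.5 * rate), 1)
    if len(x) <= smoothing_n:
        raise ValueError(
            f"signal length {len(x)} must exceed smoothing span {smoothing_n}")
    coef, _ = pywt.cwt(x, scales, _WAVELET, sampling_period=1.0 / rate)
    energy = np.abs(coef) ** 2
    energy = uniform_filter1d(energy, size=smoothing_n, axis=1, mode="nearest")
    E_tot = energy.sum(axis=0)
    sd = E_tot.std()
    E = (E_tot - E_tot.mean()) / sd if sd > 0 else np.zeros_like(E_tot)
    F = energy_centroid(energy, freqs)
    H = energy_entropy(energy)
    rows = np.column_stack([E, F, H])
    return WaveletFeatureMatrix(rows=rows, scales=scales, frequencies=freqs,
                                smoothing_n=smoothing_n, energy=energy)


def wavelet_segment_features(segs, scales=None, freqs=None,
                             smoothing_n: int | None = None) -> np.ndarray:
    """One (E, F, H) row per window: frame-averages of the time-resolved
    features (NaN frames ignored)."""
    if isinstance(segs, SegmentSet):
        X, rate = segs.segments, segs.rate
    else:
        raise ValueError("wavelet_segment_features needs a SegmentSet (for rate)")
    out = np.empty((X.shape[0], 3))
    for k, row in enumerate(X):
        wf = wavelet_features(row, rate, scales=scales, freqs=freqs,
                              smoothing_n=smoothing_n)
        out[k] = np.nanmean(wf.rows, axis=0)
    return out
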