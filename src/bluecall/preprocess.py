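"""Audio preprocessing for low-frequency whale-call recordings.

The detection pipeline sees a mono waveform ``x(t)``, bandpass-filters it to
the 15-30 Hz band where Antarctic blue-whale song lives (``y(t)``), rescales
it by its maximum absolute value (``z(t)``), and cuts it into fixed-length,
non-overlapping analysis windows.  Annotations (selection-table style: begin
and end time in seconds, low/high frequency in Hz, call label) ride along on
the recording and are used to label windows.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

log = logging.getLogger(__name__)

#: Label used for windows with no (or tied) annotation overlap.
NOISE_LABEL = "noise"

ANNOTATION_COLUMNS = ["begin_s", "end_s", "low_hz", "high_hz", "label"]


@dataclass(frozen=True)
class Annotation:
    """A single call annotation: time span, frequency bounds and label."""

    t_begin: float
    t_end: float
    f_low: float
    f_high: float
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.t_begin < self.t_end):
            raise ValueError(
                f"annotation times must satisfy 0 <= begin < end, "
                f"got [{self.t_begin}, {self.t_end}]"
            )
        if math.isfinite(self.f_low) and math.isfinite(self.f_high):
            if not self.f_low < self.f_high:
                raise ValueError(
                    f"annotation frequencies must satisfy low < high, "
                    f"got [{self.f_low}, {self.f_high}]"
                )


@dataclass
class AcousticRecording:
    """A mono waveform with its sample rate and optional annotations.

    ``samples`` are dimensionless amplitudes; successive preprocessing stages
    (filtering, normalisation) return new recordings rather than mutating.
    """

    samples: np.ndarray
    rate: float
    annotations: list[Annotation] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class FilterSpec:
    """A bandpass design: passband edges, order and sample rate.

    The realized filter is a Butterworth bandpass (maximally flat passband),
    stored in second-order sections.  Applied forward-backward the response
    is zero phase, preserving call timing.
    """

    f_low: float = 15.0
    f_high: float = 30.0
    order: int = 4
    rate: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high < self.rate / 2):
            raise ValueError(
                f"band edges must satisfy 0 < f_low < f_high < rate/2, got "
                f"({self.f_low}, {self.f_high}) at rate {self.rate}"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        self.sos = signal.butter(
            self.order, [self.f_low, self.f_high], btype="bandpass",
            fs=self.rate, output="sos",
        )

    def magnitude_response(self, freqs) -> np.ndarray:
        """Single-pass magnitude response |H(f)| at the given frequencies (Hz)."""
        _, h = signal.sosfreqz(self.sos, worN=np.atleast_1d(freqs), fs=self.rate)
        return np.abs(h)


@dataclass
class SegmentSet:
    """s non-overlapping fixed-length windows cut from a recording.

    Rows of ``segments`` are the windows F_k in temporal order; ``labels`` is
    the optional per-window class token derived from annotations.
    """

    segments: np.ndarray
    window_s: float
    rate: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        if self.segments.ndim != 2:
            raise ValueError("segments must be a 2-D (s x L) array")
        if self.labels is not None and len(self.labels) != self.segments.shape[0]:
            raise ValueError("labels length must match the number of windows")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def segment_length(self) -> int:
        return self.segments.shape[1]

    def start_times(self) -> np.ndarray:
        return np.arange(self.n_segments) * self.window_s

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.segments)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t", index=False)


def read_wav(path) -> AcousticRecording:
    """Read a WAV file into an :class:`AcousticRecording`.

    Integer PCM is rescaled to [-1, 1) by the type's full scale; float data
    is taken as-is.  Multi-channel audio keeps channel 0 with a warning.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # corrupt header, empty file, ...
        raise IOError(f"could not read WAV file {path!s}: {exc}") from exc
    if data.size == 0:
        raise IOError(f"WAV file {path!s} contains no samples")
    if data.ndim > 1:
        log.warning("%s has %d channels; keeping channel 0", path, data.shape[1])
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min < 0:  # signed PCM: divide by |min| so full scale hits -1/+~1
            data = data.astype(float) / float(-info.min)
        else:  # unsigned 8-bit
            half = (info.max + 1) / 2
            data = (data.astype(float) - half) / half
    else:
        data = data.astype(float)
    return AcousticRecording(samples=data, rate=float(rate), source_id=str(path))


def write_wav(path, rec: AcousticRecording) -> None:
    """Write a recording as 32-bit float WAV."""
    wavfile.write(path, int(rec.rate), rec.samples.astype(np.float32))


def read_annotations(path) -> list[Annotation]:
    """Read a selection-table-like CSV with header begin_s,end_s,low_hz,high_hz,label."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path!s} lacks columns {missing}")
    return [
        Annotation(row.begin_s, row.end_s, row.low_hz, row.high_hz, str(row.label))
        for row in df.itertuples()
    ]


def write_annotations(path, annotations: list[Annotation]) -> None:
    pd.DataFrame(
        [(a.t_begin, a.t_end, a.f_low, a.f_high, a.label) for a in annotations],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(path, index=False)


def bandpass(rec: AcousticRecording, spec: FilterSpec | None = None) -> AcousticRecording:
    """Zero-phase Butterworth bandpass; default 15-30 Hz, fourth order.

    The filter is applied forward-backward (``sosfiltfilt``) so call onsets
    are not delayed; length is preserved.
    """
    if spec is None:
        spec = FilterSpec(rate=rec.rate)
    if spec.rate != rec.rate:
        raise ValueError(
            f"filter designed for rate {spec.rate}, recording has rate {rec.rate}"
        )
    # sosfiltfilt needs more than its padding length of samples to settle
    padlen = 3 * (2 * spec.sos.shape[0] + 1 - min((spec.sos[:, 2] == 0).sum(),
                                                  (spec.sos[:, 5] == 0).sum()))
    if len(rec) <= max(padlen, 3 * spec.order):
        raise ValueError(
            f"recording too short ({len(rec)} samples) for the filter warm-up"
        )
    y = signal.sosfiltfilt(spec.sos, rec.samples)
    return replace(rec, samples=y)


def normalize(rec: AcousticRecording) -> AcousticRecording:
    """Divide the waveform by its maximum absolute value so max |z| = 1."""
    peak = np.max(np.abs(rec.samples))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero signal")
    return replace(rec, samples=rec.samples / peak)


def decimate(rec: AcousticRecording, factor: int) -> AcousticRecording:
    """Integer decimation with an anti-alias FIR filter (zero phase).

    Used after bandpass filtering: the 15-30 Hz analysis band needs far less
    than 1 kHz, and the entropy step scales quadratically with window length.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"decimation factor must be a positive integer, got {factor}")
    if factor == 1:
        return rec
    y = signal.decimate(rec.samples, int(factor), ftype="fir", zero_phase=True)
    return replace(rec, samples=y, rate=rec.rate / factor)


def _window_label(annotations: list[Annotation], t0: float, t1: float) -> str:
    """Label of the annotation class with the largest temporal overlap.

    No overlap, or a tie between classes, yields the noise label.
    """
    overlap: dict[str, float] = {}
    for a in annotations:
        o = min(t1, a.t_end) - max(t0, a.t_begin)
        if o > 0:
            overlap[a.label] = overlap.get(a.label, 0.0) + o
    if not overlap:
        return NOISE_LABEL
    best = max(overlap.values())
    winners = [lab for lab, o in overlap.items() if o == best]
    return winners[0] if len(winners) == 1 else NOISE_LABEL


def segment(rec: AcousticRecording, window_s: float) -> SegmentSet:
    """Cut the recording into floor(duration/window) non-overlapping windows.

    Windows are half-open [k*W, (k+1)*W); the trailing remainder is
    discarded.  If the recording carries annotations each window receives
    the majority-overlap label (ties and empty windows -> ``"noise"``).
    """
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    L = int(math.floor(window_s * rec.rate))
    s = len(rec) // L
    if s < 1:
        raise ValueError(
            f"recording ({rec.duration_s:.1f} s) shorter than one {window_s} s window"
        )
    rows = rec.samples[: s * L].reshape(s, L)
    labels = None
    if rec.annotations:
        labels = [
            _window_label(rec.annotations, k * window_s, (k + 1) * window_s)
            for k in range(s)
        ]
    return SegmentSet(segments=rows, window_s=window_s, rate=rec.rate, labels=labels)


def dft_bin_spacing(rate: float, n_dft: int) -> float:
    """Frequency grid spacing (Hz) of an n-point DFT at the given sample rate."""
    if n_dft < 1:
        raise ValueError("n_dft must be >= 1")
    return rate / n_dft
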