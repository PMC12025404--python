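"""Synthetic blue-whale call scenes.

Antarctic blue-whale song is built from stereotyped Z calls: a 25-27 Hz
tonal part lasting 8-12 s (Bm-Ant-A), a ~2 s downsweep from about 27 Hz to
20 Hz (Bm-Ant-B), and a final 8-12 s tonal gliding from 20 Hz to about
18 Hz (Bm-Ant-Z), 18-26 s in total.  Non-song D calls are short (1-4 s)
variable downsweeps spanning 22-106 Hz.  The generator renders these as
linear-FM chirps with raised-cosine onset/offset tapers — the simplest
waveform consistent with the calls' verbal description — mixes them onto
seeded white or pink noise at a controlled in-band (15-30 Hz) SNR, and
writes the same WAV + selection-table CSV formats the preprocessing module
reads, so synthetic and real recordings are interchangeable.

It does not model ocean propagation, multipath, or transient interference
(icebergs, airguns): scenes are calls plus stationary coloured noise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import (
    AcousticRecording,
    Annotation,
    FilterSpec,
    NOISE_LABEL,
    bandpass,
    decimate,
    normalize,
)

log = logging.getLogger(__name__)

CALL_TYPES = ("BmAntA", "BmAntB", "BmAntZ", "BmD")

#: Analysis band (Hz) in which scene SNR is defined — the band the detector sees.
BAND = (15.0, 30.0)

#: Duration (s) of the raised-cosine onset/offset ramps.
_TAPER_S = 0.5

#: Frequency/duration envelopes per call type: (f_start range, f_end range,
#: duration range).  Z-type calls are handled piecewise in synth_call.
_ENVELOPES = {
    "BmAntA": ((25.0, 27.0), None, (8.0, 12.0)),   # tonal
    "BmD": ((60.0, 106.0), (22.0, 40.0), (1.0, 4.0)),
}


@dataclass(frozen=True)
class CallSpec:
    """One call to synthesize: type, frequency span, duration, amplitude."""

    call_type: str
    f_start: float
    f_end: float
    duration_s: float
    amplitude: float = 1.0
    #: Durations of the three Z-call parts (tonal, downsweep, tonal); only
    #: used by the composite BmAntB / BmAntZ types.
    part_durations: tuple[float, float, float] = (10.0, 2.0, 10.0)

    def __post_init__(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call type {self.call_type!r}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")

    @classmethod
    def draw(cls, call_type: str, rng: np.random.Generator,
             amplitude: float = 1.0) -> "CallSpec":
        """Draw a call with parameters uniform within the type's envelope."""
        if call_type in ("BmAntZ", "BmAntB"):
            d1 = rng.uniform(8.0, 12.0)
            d3 = rng.uniform(8.0, 12.0)
            parts = (d1, 2.0, d3)
            if call_type == "BmAntZ":
                dur, f_end = d1 + 2.0 + d3, 18.0
            else:
                dur, f_end = d1 + 2.0, 20.0
            return cls(call_type=call_type, f_start=rng.uniform(25.0, 27.0),
                       f_end=f_end, duration_s=dur, amplitude=amplitude,
                       part_durations=parts)
        f_start_rng, f_end_rng, dur_rng = _ENVELOPES[call_type]
        f_start = rng.uniform(*f_start_rng)
        f_end = f_start if f_end_rng is None else rng.uniform(*f_end_rng)
        return cls(call_type=call_type, f_start=f_start, f_end=f_end,
                   duration_s=rng.uniform(*dur_rng), amplitude=amplitude)

    @property
    def f_low(self) -> float:
        return min(self.f_start, self.f_end, 18.0 if self.call_type in
                   ("BmAntZ",) else self.f_end)

    @property
    def f_high(self) -> float:
        return max(self.f_start, self.f_end)


@dataclass(frozen=True)
class SceneSpec:
    """A recording to synthesize: duration, rate, placed calls, noise, SNR."""

    duration_s: float
    rate: float = 1000.0
    calls: tuple = ()  # sequence of (onset_s, CallSpec)
    noise_kind: str = "white"
    snr_db: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_kind not in ("white", "pink"):
            raise ValueError(f"noise_kind must be 'white' or 'pink', got {self.noise_kind!r}")
        for onset, call in self.calls:
            if onset < 0 or onset + call.duration_s > self.duration_s + 1e-9:
                raise ValueError(
                    f"call at onset {onset:.2f}s (duration {call.duration_s:.2f}s) "
                    f"does not fit in a {self.duration_s:.2f}s scene"
                )
            if call.f_high >= self.rate / 2:
                raise ValueError(
                    f"call reaches {call.f_high} Hz, above Nyquist for rate {self.rate}"
                )


def _taper(n: int, rate: float) -> np.ndarray:
    """Raised-cosine onset/offset ramps of up to 0.5 s each."""
    ramp = min(int(_TAPER_S * rate), n // 2)
    w = np.ones(n)
    if ramp > 0:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        w[:ramp] = edge
        w[-ramp:] = edge[::-1]
    return w


def _chirp(f0: float, f1: float, duration_s: float, rate: float,
           amplitude: float, phase0: float = 0.0) -> np.ndarray:
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    phase = 2 * np.pi * (f0 * t + (f1 - f0) / (2 * duration_s) * t ** 2) + phase0
    return amplitude * np.cos(phase) * _taper(n, rate)


def synth_call(spec: CallSpec, rate: float) -> np.ndarray:
    """Render one call as a linear-FM chirp (piecewise for Z-type calls)."""
    if spec.f_high >= rate / 2:
        raise ValueError(
            f"call frequency {spec.f_high} Hz is at or above Nyquist ({rate / 2} Hz)"
        )
    if spec.call_type == "BmAntA" or spec.call_type == "BmD":
        return _chirp(spec.f_start, spec.f_end, spec.duration_s, rate, spec.amplitude)
    # Z-call pieces: tonal around f_start, 2-s downsweep to 20 Hz, tonal to 18 Hz
    d1, d2, d3 = spec.part_durations
    parts = [_chirp(spec.f_start, spec.f_start, d1, rate, spec.amplitude),
             _chirp(27.0, 20.0, d2, rate, spec.amplitude)]
    if spec.call_type == "BmAntZ":
        parts.append(_chirp(20.0, 18.0, d3, rate, spec.amplitude))
    return np.concatenate(parts)


def band_power(x: np.ndarray, rate: float, band: tuple[float, float] = BAND) -> float:
    """Mean power of x inside the band, by periodogram integration."""
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2 / n ** 2
    if n % 2 == 0:
        spec[1:-1] *= 2
    else:
        spec[1:] *= 2
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(spec[mask].sum())


def _noise(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    w = rng.standard_normal(n)
    if kind == "white":
        return w
    # pink: shape the spectrum by 1/sqrt(f)
    spec = np.fft.rfft(w)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    y = np.fft.irfft(spec * scale, n)
    return y / np.std(y)


_ANNOT_BANDS = {  # nominal low/high frequency bounds per call type
    "BmAntA": (25.0, 27.0),
    "BmAntB": (20.0, 27.0),
    "BmAntZ": (18.0, 27.0),
    "BmD": (22.0, 106.0),
}


def synth_scene(spec: SceneSpec, return_components: bool = False):
    """Render a scene: calls summed onto seeded noise at the target in-band SNR.

    The noise is rescaled so the 15-30 Hz power ratio between the summed
    call waveform and the noise equals ``snr_db`` exactly (by the
    periodogram measure of :func:`band_power`).  Scenes without calls are
    pure unit-variance noise.  Annotations carry exact onsets/offsets.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate))
    noise = _noise(spec.noise_kind, n, rng)
    sig = np.zeros(n)
    annotations: list[Annotation] = []
    last_end = -np.inf
    for onset, call in sorted(spec.calls, key=lambda c: c[0]):
        if onset < last_end:
            log.warning("overlapping calls at %.2f s", onset)
        wave = synth_call(call, spec.rate)
        i0 = int(round(onset * spec.rate))
        sig[i0:i0 + len(wave)] += wave[: n - i0]
        t_end = onset + len(wave) / spec.rate
        lo, hi = _ANNOT_BANDS[call.call_type]
        annotations.append(Annotation(onset, t_end, lo, hi, call.call_type))
        last_end = t_end
    if annotations:
        p_sig = band_power(sig, spec.rate)
        p_noise = band_power(noise, spec.rate)
        noise = noise * np.sqrt(p_sig / (p_noise * 10 ** (spec.snr_db / 10)))
    rec = AcousticRecording(samples=sig + noise, rate=spec.rate,
                            annotations=annotations,
                            source_id=f"synth-seed{spec.seed}")
    if return_components:
        return rec, sig, noise
    return rec


@dataclass
class Benchmark:
    """A labelled synthetic dataset ready for the pipeline.

    One analysis window per scene; ``segments`` is the preprocessed
    (bandpassed, decimated, normalised) window matrix, ``labels`` the
    per-window call-type tokens, and ``train_idx`` / ``test_idx`` a
    stratified 70/30 split.
    """

    segments: np.ndarray
    labels: list[str]
    train_idx: np.ndarray
    test_idx: np.ndarray
    rate: float
    window_s: float
    snr_db: float
    seed: int
    scene_seeds: list[int] = field(default_factory=list)

    @property
    def binary_labels(self) -> list[str]:
        """Collapse call types to 'call' vs 'noise' for detection."""
        return [NOISE_LABEL if l == NOISE_LABEL else "call" for l in self.labels]


DEFAULT_BALANCE = {NOISE_LABEL: 0.5, "BmAntA": 0.2, "BmAntZ": 0.15, "BmD": 0.15}


def stratified_split(labels, test_size: float, rng: np.random.Generator):
    """Seeded stratified split preserving class proportions to within one item.

    Per-class test counts follow the largest-remainder rule so the overall
    test fraction is met exactly (e.g. 100 windows at 0.3 -> 70/30) while
    every class keeps at least one window on each side.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    sizes = {}
    for lab in classes:
        sizes[lab] = int(np.sum(labels == lab))
        if sizes[lab] < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 instances")
    target_total = int(round(test_size * len(labels)))
    quota = {lab: test_size * n for lab, n in sizes.items()}
    n_test = {lab: min(max(int(np.floor(q)), 1), sizes[lab] - 1)
              for lab, q in quota.items()}
    remainders = sorted(classes, key=lambda l: quota[l] - np.floor(quota[l]),
                        reverse=True)
    for lab in remainders:
        if sum(n_test.values()) >= target_total:
            break
        if n_test[lab] < sizes[lab] - 1:
            n_test[lab] += 1
    train_idx, test_idx = [], []
    for lab in classes:
        idx = rng.permutation(np.flatnonzero(labels == lab))
        test_idx.extend(idx[: n_test[lab]])
        train_idx.extend(idx[n_test[lab]:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def make_benchmark(n_scenes: int = 100, class_balance: dict | None = None,
                   snr_db: float = 10.0, seed: int = 0, rate: float = 1000.0,
                   window_s: float = 26.0, noise_kind: str = "white",
                   decimation: int = 10, test_size: float = 0.3) -> Benchmark:
    """Generate a labelled single-window-per-scene benchmark.

    Each scene is one ``window_s``-second recording holding either pure
    noise or a single call of the drawn type, centred in the window (long Z
    calls are clipped to fit).  Scenes are preprocessed exactly as real
    recordings would be — 15-30 Hz bandpass, integer decimation, max-abs
    normalisation — and the resulting windows are split 70/30 stratified by
    class.
    """
    if n_scenes < 10:
        raise ValueError("need at least 10 scenes for a meaningful benchmark")
    balance = dict(class_balance or DEFAULT_BALANCE)
    total = sum(balance.values())
    classes = sorted(balance)
    counts = {c: int(round(n_scenes * balance[c] / total)) for c in classes}
    # fix rounding drift on the largest class
    drift = n_scenes - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for c in classes:
        labels.extend([c] * counts[c])
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    fspec = FilterSpec(rate=rate)
    rows, scene_seeds = [], []
    for lab in labels:
        scene_seed = int(rng.integers(0, 2 ** 31 - 1))
        scene_seeds.append(scene_seed)
        calls = ()
        if lab != NOISE_LABEL:
            call = CallSpec.draw(lab, np.random.default_rng(scene_seed + 1))
            if call.duration_s > window_s:
                raise ValueError(
                    f"{lab} call of {call.duration_s:.1f}s does not fit a "
                    f"{window_s}s window; enlarge window_s"
                )
            onset = (window_s - call.duration_s) / 2
            calls = ((max(onset, 0.0), call),)
        scene = SceneSpec(duration_s=window_s, rate=rate, calls=calls,
                          noise_kind=noise_kind, snr_db=snr_db, seed=scene_seed)
        rec = synth_scene(scene)
        rec = normalize(decimate(bandpass(rec, fspec), decimation))
        L = int(window_s * rec.rate)
        rows.append(rec.samples[:L])
    segments = np.vstack(rows)
    train_idx, test_idx = stratified_split(labels, test_size, rng)
    return Benchmark(segments=segments, labels=labels, train_idx=train_idx,
                     test_idx=test_idx, rate=rate / decimation,
                     window_s=window_s, snr_db=snr_db, seed=seed,
                     scene_seeds=scene_seeds)
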