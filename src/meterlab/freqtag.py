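"""The shared frequency-tagging engine.

Stimulus-locked responses concentrate in narrow spectral peaks at frequencies
tied to the 5-Hz event rate, sitting on broadband background noise.  The same
machinery is applied to stimulus envelopes, cochlear-model output, EEG, and
tapping-sensor signals: cut seven 14.4-s segments with 50% overlap, average
across trials in the time domain, FFT, subtract the local noise floor
(average of the second neighboring bin on each side), extract amplitudes at
the target-frequency set, and z-score them across that set.  The mean z over
the meter-related subset {1.25, 2.5, 5} Hz measures how much the meter
frequencies stand out — a gain-free, scale-invariant prominence measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SEGMENT_WINDOW = 14.4   # s
SEGMENT_HOP = 7.2       # s (50% overlap)
N_SEGMENTS = 7
CORE_DURATION = 57.6    # s
EVENT_RATE = 5.0        # Hz
METER_FREQUENCIES = (1.25, 2.5, 5.0)
DEFAULT_CYCLES = (12, 16)

ORIGINS = ("eeg", "tapping", "periphery", "envelope")


def window_samples(rate: float) -> int:
    return int(round(SEGMENT_WINDOW * rate))


def segment_starts(rate: float) -> list[int]:
    return [int(round(k * SEGMENT_HOP * rate)) for k in range(N_SEGMENTS)]


def required_samples(rate: float) -> int:
    """Samples needed to cut all seven segments."""
    return segment_starts(rate)[-1] + window_samples(rate)


@dataclass(frozen=True)
class SegmentedSignal:
    """Seven half-overlapping segments of a (channels × samples) signal."""

    segments: np.ndarray  # (7, channels, window_samples)
    rate: float
    origin: str = "eeg"

    def __post_init__(self) -> None:
        if self.segments.ndim != 3 or self.segments.shape[0] != N_SEGMENTS:
            raise ValueError(f"expected (7, channels, samples), got {self.segments.shape}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")


def segment_signal(
    x: np.ndarray, rate: float, core_start_offset: float = 0.0, origin: str = "eeg"
) -> SegmentedSignal:
    """Cut the 57.6-s core into 7 segments of 14.4 s with 7.2-s hop.

    ``core_start_offset`` drops the leading padding region (0.4 s for padded
    trials).  A 1-D input is treated as a single channel.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    first = int(round(core_start_offset * rate))
    need = required_samples(rate)
    avail = x.shape[1] - first
    if avail < need:
        raise ValueError(
            f"signal too short: need {need / rate:.3f} s after offset "
            f"{core_start_offset} s, have {max(avail, 0) / rate:.3f} s"
        )
    n = window_samples(rate)
    segs = np.stack(
        [x[:, first + s : first + s + n] for s in segment_starts(rate)]
    )
    return SegmentedSignal(segs, float(rate), origin)


def average_trials(trials: Sequence[SegmentedSignal]) -> SegmentedSignal:
    """Element-wise mean across trials (time-domain averaging).

    Phase-locked components survive; activity not time-locked to the stimulus
    cancels roughly as 1/sqrt(n_trials).
    """
    if len(trials) == 0:
        raise ValueError("no trials to average")
    first = trials[0]
    for t in trials[1:]:
        if t.segments.shape != first.segments.shape or t.rate != first.rate:
            raise ValueError("trials differ in shape or rate")
    return replace(first, segments=np.mean([t.segments for t in trials], axis=0))


@dataclass(frozen=True)
class MagnitudeSpectrum:
    """Per-channel FFT magnitudes of one segment; bins 0..Nyquist."""

    amplitudes: np.ndarray  # (channels, bins) or (bins,)
    resolution: float       # Hz per bin
    noise_subtracted: bool = False

    @property
    def n_bins(self) -> int:
        return self.amplitudes.shape[-1]


def magnitude_spectrum(segment: np.ndarray, rate: float) -> MagnitudeSpectrum:
    """Rectangular-window FFT magnitude per channel, no zero padding."""
    segment = np.asarray(segment, dtype=float)
    n = segment.shape[-1]
    amps = np.abs(np.fft.rfft(segment, axis=-1)) / n
    return MagnitudeSpectrum(amplitudes=amps, resolution=rate / n)


def subtract_noise(spec: MagnitudeSpectrum) -> MagnitudeSpectrum:
    """Subtract, at each bin, the mean amplitude of the 2nd neighbor either side.

    Boundary bins with only one second-neighbor available use that single
    neighbor.  The operation is linear and leaves an isolated peak intact
    while zeroing any locally flat background; output values may be negative.
    """
    if spec.noise_subtracted:
        raise ValueError("spectrum is already noise-subtracted")
    a = spec.amplitudes
    nb = a.shape[-1]
    out = np.empty_like(a)
    for k in range(nb):
        neighbors = []
        if k - 2 >= 0:
            neighbors.append(a[..., k - 2])
        if k + 2 < nb:
            neighbors.append(a[..., k + 2])
        if neighbors:
            out[..., k] = a[..., k] - np.mean(neighbors, axis=0)
        else:
            out[..., k] = a[..., k]
    return MagnitudeSpectrum(out, spec.resolution, noise_subtracted=True)


def average_channels(spec: MagnitudeSpectrum) -> MagnitudeSpectrum:
    """Mean spectrum across channels (after any per-channel noise subtraction)."""
    a = np.atleast_2d(spec.amplitudes)
    return replace(spec, amplitudes=a.mean(axis=0))


@dataclass(frozen=True)
class TargetFrequencySet:
    """The analysis frequencies and how each is read off the spectrum.

    Built from the harmonics of 12-event (5/12 Hz) and 16-event (5/16 Hz)
    cycles up to the 5-Hz event rate.  A frequency landing exactly on a bin
    (to tolerance) is read there; otherwise the maximum of the two closest
    bins is taken.
    """

    frequencies: tuple[float, ...]
    resolution: float
    meter_subset: tuple[float, ...] = METER_FREQUENCIES
    exact_tol: float = 1e-9
    exact_bin: tuple[bool, ...] = field(init=False)

    def __post_init__(self) -> None:
        freqs = tuple(sorted(self.frequencies))
        if len(set(freqs)) != len(freqs):
            raise ValueError("duplicate target frequencies")
        missing = [f for f in self.meter_subset if not _member(f, freqs)]
        if missing:
            raise ValueError(f"meter frequencies {missing} not in the target set")
        object.__setattr__(self, "frequencies", freqs)
        exact = tuple(
            abs(f / self.resolution - round(f / self.resolution)) < self.exact_tol
            for f in freqs
        )
        object.__setattr__(self, "exact_bin", exact)

    @property
    def meter_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, f in enumerate(self.frequencies) if _member(f, self.meter_subset)
        )


def _member(f: float, fs: Sequence[float], tol: float = 1e-9) -> bool:
    return any(abs(f - g) < tol for g in fs)


def build_target_frequencies(
    resolution: float,
    event_rate: float = EVENT_RATE,
    cycles: Sequence[int] = DEFAULT_CYCLES,
    max_freq: float | None = None,
    frequencies: Sequence[float] | None = None,
) -> TargetFrequencySet:
    """Union of cycle-harmonic frequencies up to the event rate, deduplicated.

    With the default cycles (12, 16) the set has 24 members, 16 of which are
    exact-bin at resolution 1/14.4 Hz.  An explicit ``frequencies`` list
    overrides the construction rule.
    """
    if max_freq is None:
        max_freq = event_rate
    if frequencies is None:
        out: list[float] = []
        for c in cycles:
            base = event_rate / c
            k = 1
            while k * base <= max_freq + 1e-9:
                if not _member(k * base, out):
                    out.append(k * base)
                k += 1
        frequencies = out
    return TargetFrequencySet(tuple(sorted(frequencies)), resolution)


def extract_amplitudes(spec: MagnitudeSpectrum, fs: TargetFrequencySet) -> np.ndarray:
    """Read the amplitude at each target frequency off a 1-D spectrum."""
    a = spec.amplitudes
    if a.ndim != 1:
        raise ValueError("extraction expects a channel-averaged (1-D) spectrum")
    nyquist_bins = a.shape[0]
    out = np.empty(len(fs.frequencies))
    for i, (f, exact) in enumerate(zip(fs.frequencies, fs.exact_bin)):
        x = f / spec.resolution
        if x > nyquist_bins - 1:
            raise ValueError(f"target frequency {f} Hz above Nyquist")
        if exact:
            out[i] = a[int(round(x))]
        else:
            lo, hi = int(np.floor(x)), int(np.ceil(x))
            out[i] = max(a[lo], a[hi])
    return out


@dataclass(frozen=True)
class ZScoreSummary:
    """Amplitudes standardized across the target set; mean z over meter subset."""

    z: np.ndarray
    frequencies: tuple[float, ...]
    meter_mean_z: float


def zscore_amplitudes(amps: np.ndarray, fs: TargetFrequencySet) -> ZScoreSummary:
    """Standardize across the target set: (x − mean) / SD, sample (n−1) SD."""
    amps = np.asarray(amps, dtype=float)
    if amps.shape != (len(fs.frequencies),):
        raise ValueError("amplitude vector does not match the target-frequency set")
    sd = np.std(amps, ddof=1)
    if sd == 0:
        raise ValueError("zero variance across target frequencies; z-scores undefined")
    z = (amps - amps.mean()) / sd
    return ZScoreSummary(
        z=z,
        frequencies=fs.frequencies,
        meter_mean_z=float(z[list(fs.meter_indices)].mean()),
    )


def meter_z_difference(periphery_z: ZScoreSummary, response_z: ZScoreSummary) -> float:
    """Cochlear-model minus response meter prominence (positive ⇒ response
    tracks meter *less* than the periphery would predict)."""
    if periphery_z.frequencies != response_z.frequencies:
        raise ValueError("z-score summaries built on different frequency sets")
    return periphery_z.meter_mean_z - response_z.meter_mean_z


def segments_to_zscores(
    segmented: SegmentedSignal,
    fs: TargetFrequencySet | None = None,
    noise_subtraction: bool = True,
) -> list[ZScoreSummary]:
    """Full per-segment path: FFT per channel → (noise subtraction) →
    channel-average → extraction → z-scoring."""
    out = []
    for k in range(N_SEGMENTS):
        spec = magnitude_spectrum(segmented.segments[k], segmented.rate)
        if fs is None:
            fs = build_target_frequencies(spec.resolution)
        if noise_subtraction:
            spec = subtract_noise(spec)
        spec = average_channels(spec)
        out.append(zscore_amplitudes(extract_amplitudes(spec, fs), fs))
    return out
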