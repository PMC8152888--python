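"""Synthetic EEG-like and tapping-like signals with known ground truth.

The EEG generator emulates what frequency tagging assumes about steady-state
responses: a deterministic sum of cosines at the target frequencies whose
phases are fixed per (virtual) participant and reused across trials — so
time-domain trial averaging preserves the stimulus-locked component while
independent 1/f^α background noise cancels.  Meter-subset amplitudes follow a
declining profile across segments for regular-to-degraded sequences (and its
mirror for the inverted direction), emulating the loss of acoustic meter cues
with degradation.  A *context gain* γ ≥ 1 multiplies the meter-subset
amplitudes in chosen (direction, segment) cells; γ = 1 reproduces the null
world in which the two directions differ in nothing but time order.

Because the downstream prominence measure is z-scored (gain-free), injecting
the effect as a multiplicative meter-subset gain makes recovery nontrivial:
a global gain would change nothing.

The tapping generator produces impulse trains with Gaussian motor jitter and
optional per-boundary phase resets, period switches between meter pulses, and
missed taps — the failure modes the ITI-error and spectral measures are
designed to tease apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import eeg, freqtag
from .freqtag import TargetFrequencySet, build_target_frequencies
from .sequences import PADDED_DURATION, CORE_DURATION

REGULAR = "regular_to_degraded"
DEGRADED = "degraded_to_regular"
DIRECTIONS = (REGULAR, DEGRADED)


@dataclass(frozen=True)
class SyntheticEEGConfig:
    """Study-sized defaults: 16 virtual participants, 15 trials per direction."""

    n_participants: int = 16
    n_trials_per_direction: int = 15
    rate: float = 512.0
    n_channels: int = 4
    #: Fixed channel mixing profile for the deterministic component.
    mixing: tuple[float, ...] = (1.0, 0.6, -0.4, -0.8)
    #: Amplitude at meter frequencies per segment (1..7) in the
    #: regular-to-degraded direction; mirrored for the inverted direction.
    #: Meter amplitudes stay well above the unrelated amplitude even in the
    #: most degraded segment — steady-state meter prominence declines with
    #: degradation but does not vanish — which also keeps the z-score
    #: denominator (SD across the target set) well conditioned.
    meter_profile: tuple[float, ...] = (1.2, 1.1, 1.0, 0.9, 0.8, 0.7, 0.6)
    #: Amplitude at meter-unrelated target frequencies (all segments).
    unrelated_amplitude: float = 0.3
    #: Context gain γ on meter-subset amplitudes per (direction, segment) cell.
    context_gain: Mapping[tuple[str, int], float] = field(default_factory=dict)
    noise_alpha: float = 1.0
    noise_scale: float = 20.0  # time-domain RMS of the 1/f^α background
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mixing) != self.n_channels:
            raise ValueError("mixing profile length must equal n_channels")
        if len(self.meter_profile) != freqtag.N_SEGMENTS:
            raise ValueError("meter profile needs one amplitude per segment")
        if any(g < 0 for g in self.context_gain.values()):
            raise ValueError("context gains must be non-negative")

    def segment_amplitude(self, direction: str, raw_segment: int) -> float:
        """Meter amplitude in a given raw segment of a given direction."""
        if direction == DEGRADED:
            base = self.meter_profile[freqtag.N_SEGMENTS - raw_segment]
        else:
            base = self.meter_profile[raw_segment - 1]
        return base * float(self.context_gain.get((direction, raw_segment), 1.0))


def pink_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^α noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _segment_gain_curve(cfg: SyntheticEEGConfig, direction: str, t_core: np.ndarray) -> np.ndarray:
    """Meter-amplitude envelope over core time.

    Piecewise-linear between segment centers (constant beyond the first and
    last), so amplitudes cross-fade smoothly at segment boundaries and the
    window mean approximates the per-segment target.
    """
    centers = np.array(
        [k * freqtag.SEGMENT_HOP + freqtag.SEGMENT_WINDOW / 2 for k in range(freqtag.N_SEGMENTS)]
    )
    values = np.array(
        [cfg.segment_amplitude(direction, s) for s in range(1, freqtag.N_SEGMENTS + 1)]
    )
    return np.interp(t_core, centers, values)


def simulate_eeg_trial(
    direction: str,
    cfg: SyntheticEEGConfig,
    participant: int,
    trial: int,
    fs: TargetFrequencySet | None = None,
) -> np.ndarray:
    """One padded trial (channels × samples, 58.4 s at ``cfg.rate``).

    Deterministic given (config, participant, trial, direction): target-
    frequency phases are drawn once per participant; the noise stream is
    unique per trial and channel.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if fs is None:
        fs = build_target_frequencies(resolution=1.0 / freqtag.SEGMENT_WINDOW)
    n = int(round(PADDED_DURATION * cfg.rate))
    first = int(round(eeg.EPOCH_OFFSET * cfg.rate))
    t_core = (np.arange(n) - first) / cfg.rate  # 0 at core start
    rng_phase = np.random.default_rng((cfg.master_seed, participant, 0xFA5E))
    phases = rng_phase.uniform(0, 2 * np.pi, len(fs.frequencies))
    meter_idx = set(fs.meter_indices)
    gain = _segment_gain_curve(cfg, direction, np.clip(t_core, 0.0, CORE_DURATION))
    sig = np.zeros(n)
    for i, f in enumerate(fs.frequencies):
        a = gain if i in meter_idx else cfg.unrelated_amplitude
        sig += a * np.cos(2 * np.pi * f * t_core + phases[i])
    dir_code = DIRECTIONS.index(direction)
    out = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        rng_noise = np.random.default_rng(
            (cfg.master_seed, participant, trial, dir_code, c)
        )
        out[c] = cfg.mixing[c] * sig + cfg.noise_scale * pink_noise(
            n, cfg.noise_alpha, rng_noise
        )
    return out


def simulate_participant_summary(
    cfg: SyntheticEEGConfig,
    participant: int,
    fs: TargetFrequencySet | None = None,
    do_preprocess: bool = False,
) -> pd.DataFrame:
    """Run one virtual participant through the EEG pipeline.

    Trials are laid back-to-back in a continuous recording with an onset
    table, exactly as a real session would be analyzed.
    """
    trial_len = int(round(PADDED_DURATION * cfg.rate))
    rows, chunks = [], []
    idx = 0
    for trial in range(cfg.n_trials_per_direction):
        for direction in DIRECTIONS:
            chunks.append(simulate_eeg_trial(direction, cfg, participant, trial))
            rows.append(
                {
                    "trial": idx,
                    "onset": idx * trial_len / cfg.rate,
                    "direction": direction,
                    "stimulus_seed": trial,
                }
            )
            idx += 1
    rec = eeg.EEGRecording(
        data=np.concatenate(chunks, axis=1), rate=cfg.rate, trials=pd.DataFrame(rows)
    )
    result = eeg.run_participant(
        rec, fs=fs, participant=f"sim{participant:02d}", do_preprocess=do_preprocess
    )
    return result["summary"]


def simulate_cohort_summary(
    cfg: SyntheticEEGConfig, fs: TargetFrequencySet | None = None
) -> pd.DataFrame:
    """Per-participant per-cell meter prominence for the whole virtual cohort."""
    return pd.concat(
        [simulate_participant_summary(cfg, p, fs) for p in range(cfg.n_participants)],
        ignore_index=True,
    )


def direction_differences(summary: pd.DataFrame) -> pd.DataFrame:
    """Regular-to-degraded minus degraded-to-regular meter prominence,
    per participant and *aligned* segment."""
    pivot = summary.pivot_table(
        index=["participant", "segment_aligned"],
        columns="direction",
        values="meter_mean_z",
    ).reset_index()
    pivot["difference"] = pivot[REGULAR] - pivot[DEGRADED]
    return pivot[["participant", "segment_aligned", "difference"]]


@dataclass(frozen=True)
class SyntheticTapConfig:
    base_period_ms: float = 400.0
    jitter_sd_ms: float = 10.0
    phase_reset_p: float = 0.0
    period_switch_p: float = 0.0
    miss_p: float = 0.0
    rate: float = 512.0
    pulse_duration_ms: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.phase_reset_p, self.period_switch_p, self.miss_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter SD must be non-negative")
        if self.base_period_ms not in (200.0, 400.0, 600.0, 800.0, 1200.0):
            raise ValueError("base period must be one of the meter pulse periods (ms)")


def simulate_tapping_trial(
    cfg: SyntheticTapConfig, duration: float = CORE_DURATION
) -> np.ndarray:
    """Single-channel tap-sensor signal: one brief raised-cosine pulse per tap.

    At every 7.2-s analysis boundary the tapper may reset phase (uniform
    shift within one period) and/or switch to another pulse period of the
    induced meter; individual taps may be missed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(duration * cfg.rate))
    out = np.zeros(n)
    n_pulse = max(3, int(round(cfg.pulse_duration_ms / 1000.0 * cfg.rate)))
    pulse = np.hanning(n_pulse)
    periods = [200.0, 400.0, 800.0]
    period = cfg.base_period_ms
    t = 0.100  # first tap shortly after onset
    next_boundary = freqtag.SEGMENT_HOP
    while t < duration:
        if t >= next_boundary:
            if rng.uniform() < cfg.phase_reset_p:
                t += rng.uniform(0, period / 1000.0)
            if rng.uniform() < cfg.period_switch_p:
                others = [p for p in periods if p != period]
                period = others[rng.integers(len(others))]
            next_boundary += freqtag.SEGMENT_HOP
            continue
        tap_time = t + rng.normal(0.0, cfg.jitter_sd_ms / 1000.0)
        if rng.uniform() >= cfg.miss_p and 0 <= tap_time < duration:
            i = int(round(tap_time * cfg.rate))
            j = min(i + n_pulse, n)
            out[i:j] += pulse[: j - i]
        t += period / 1000.0
    return out


def simulate_cohort(
    out_dir: str | Path,
    eeg_cfg: SyntheticEEGConfig | None = None,
    tap_cfg: SyntheticTapConfig | None = None,
    n_tapping_trials: int = 5,
) -> Path:
    """Write a full synthetic dataset (EEG text recordings, tapping WAVs,
    manifests, ground-truth JSON) laid out like a real-data session."""
    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eeg_cfg = eeg_cfg or SyntheticEEGConfig()
    tap_cfg = tap_cfg or SyntheticTapConfig()
    trial_len = int(round(PADDED_DURATION * eeg_cfg.rate))
    manifest_rows = []
    for p in range(eeg_cfg.n_participants):
        chunks, rows = [], []
        idx = 0
        for trial in range(eeg_cfg.n_trials_per_direction):
            for direction in DIRECTIONS:
                chunks.append(simulate_eeg_trial(direction, eeg_cfg, p, trial))
                rows.append(
                    {
                        "trial": idx,
                        "onset": idx * trial_len / eeg_cfg.rate,
                        "direction": direction,
                        "stimulus_seed": trial,
                    }
                )
                idx += 1
        pid = f"sim{p:02d}"
        eeg_path = out / f"{pid}_eeg.tsv"
        onset_path = out / f"{pid}_trials.tsv"
        if chunks:
            mio.write_columnar(eeg_path, np.concatenate(chunks, axis=1), eeg_cfg.rate)
            pd.DataFrame(rows).to_csv(onset_path, sep="\t", index=False)
            manifest_rows.append(
                {"participant": pid, "eeg": eeg_path.name, "trials": onset_path.name}
            )
        tap_dir = out / "tapping"
        tap_dir.mkdir(exist_ok=True)
        for trial in range(n_tapping_trials):
            for direction in DIRECTIONS:
                sub = SyntheticTapConfig(
                    **{
                        **asdict(tap_cfg),
                        "seed": int(
                            np.random.SeedSequence(
                                (tap_cfg.seed, p, trial, DIRECTIONS.index(direction))
                            ).generate_state(1)[0]
                            % (2**31)
                        ),
                    }
                )
                sig = simulate_tapping_trial(sub)
                mio.write_wav(
                    tap_dir / f"{pid}_t{trial:02d}_{direction}.wav", sig, tap_cfg.rate
                )
    pd.DataFrame(manifest_rows, columns=["participant", "eeg", "trials"]).to_csv(
        out / "manifest.tsv", sep="\t", index=False
    )
    truth = {
        "eeg_config": {
            **{k: v for k, v in asdict(eeg_cfg).items() if k != "context_gain"},
            "context_gain": {
                f"{d}:{s}": g for (d, s), g in eeg_cfg.context_gain.items()
            },
        },
        "tap_config": asdict(tap_cfg),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return out
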