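"""Tap-onset extraction and sensorimotor-synchronization measures.

Three complementary measures of tapping behavior:

* **meter match** — which of three candidate meters ({2,4}, {2,6}, {3,6}
  event groupings, i.e. periods {200,400,800}, {200,400,1200},
  {200,600,1200} ms) the median inter-tap interval is closest to;
* **ITI-error** — mean percent deviation of inter-tap intervals from the
  nearest pulse period of the induced meter, after discarding intervals
  longer than 2 s (pauses).  Robust to changes in tapping *phase*, sensitive
  to changes in tapping *period*;
* **tapping spectrum** — the continuous sensor signal routed through the
  frequency-tagging engine.  Robust to period changes among meter pulses
  (energy stays at meter-related frequencies), sensitive to phase changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import freqtag
from .freqtag import TargetFrequencySet, segment_signal, segments_to_zscores


@dataclass(frozen=True)
class TapOnsets:
    """Strictly increasing tap times with the detection parameters used."""

    times: np.ndarray  # s
    threshold: float
    refractory: float  # s

    def itis(self) -> np.ndarray:
        """Inter-tap intervals in seconds."""
        return np.diff(self.times)


@dataclass(frozen=True)
class MeterCandidate:
    label: str
    periods_ms: tuple[float, float, float]


METER_CANDIDATES = (
    MeterCandidate("{2,4}", (200.0, 400.0, 800.0)),
    MeterCandidate("{2,6}", (200.0, 400.0, 1200.0)),
    MeterCandidate("{3,6}", (200.0, 600.0, 1200.0)),
)
#: The meter predominantly induced by the sequences (nested 200/400/800 ms pulses).
INDUCED_METER = METER_CANDIDATES[0]

MAX_ITI = 2.0  # s; longer gaps are pauses, not tapped intervals


def default_threshold(signal: np.ndarray) -> float:
    """5× the median absolute amplitude — a per-recording starting point.

    Sensor traces that are silent between taps have a near-zero median; fall
    back to half the maximum so sparse impulse trains remain detectable.
    """
    med = 5.0 * float(np.median(np.abs(signal)))
    if med > 0:
        return med
    return 0.5 * float(np.max(np.abs(signal), initial=0.0))


def detect_taps(
    signal: np.ndarray,
    rate: float,
    threshold: float | None = None,
    refractory: float = 0.100,
) -> TapOnsets:
    """Onsets where the signal is rising, exceeds the threshold, and respects
    the refractory gap from the previous detection (greedy scan)."""
    signal = np.asarray(signal, dtype=float)
    if threshold is None:
        threshold = default_threshold(signal)
        if threshold == 0:  # silent recording: nothing to detect
            return TapOnsets(np.empty(0), 0.0, float(refractory))
    if threshold <= 0 or refractory <= 0:
        raise ValueError("threshold and refractory must be positive")
    rising = np.zeros(signal.shape, dtype=bool)
    rising[1:] = np.diff(signal) > 0
    candidates = np.flatnonzero(rising & (signal > threshold))
    times = []
    gap = refractory * rate
    last = -np.inf
    for i in candidates:
        if i - last >= gap:
            times.append(i / rate)
            last = i
    return TapOnsets(np.asarray(times), float(threshold), float(refractory))


def percent_difference(value_ms: float, period_ms: float) -> float:
    return 100.0 * abs(value_ms - period_ms) / period_ms


def meter_match(
    median_iti_ms: float,
    candidates: Sequence[MeterCandidate] = METER_CANDIDATES,
) -> pd.DataFrame:
    """Minimum percent difference between the median ITI and each meter's periods.

    The candidate with the smallest difference is the meter the tapping most
    plausibly realized.
    """
    if median_iti_ms <= 0:
        raise ValueError("median ITI must be positive")
    rows = []
    for cand in candidates:
        diffs = [percent_difference(median_iti_ms, p) for p in cand.periods_ms]
        rows.append(
            {
                "meter": cand.label,
                "min_percent_diff": min(diffs),
                "closest_period_ms": cand.periods_ms[int(np.argmin(diffs))],
            }
        )
    df = pd.DataFrame(rows)
    df["best"] = df["min_percent_diff"] == df["min_percent_diff"].min()
    return df


def iti_error(
    onsets: TapOnsets,
    window: tuple[float, float] | None = None,
    meter: MeterCandidate = INDUCED_METER,
) -> float:
    """Mean percent deviation of within-window ITIs from the chosen pulse period.

    ITIs longer than 2 s are treated as pauses and removed before choosing
    the period (the meter period closest to the median ITI).  Returns NaN if
    fewer than two taps fall in the window.  A global time shift of all
    onsets leaves the value unchanged.
    """
    times = onsets.times
    if window is not None:
        t0, t1 = window
        times = times[(times >= t0) & (times < t1)]
    if len(times) < 2:
        return float("nan")
    itis_ms = np.diff(times) * 1000.0
    itis_ms = itis_ms[itis_ms <= MAX_ITI * 1000.0]
    if len(itis_ms) == 0:
        return float("nan")
    median = float(np.median(itis_ms))
    period = meter.periods_ms[int(np.argmin([abs(median - p) for p in meter.periods_ms]))]
    return float(np.mean([percent_difference(i, period) for i in itis_ms]))


def segment_windows() -> list[tuple[float, float]]:
    """The seven 14.4-s analysis windows (s, relative to core start)."""
    return [
        (k * freqtag.SEGMENT_HOP, k * freqtag.SEGMENT_HOP + freqtag.SEGMENT_WINDOW)
        for k in range(freqtag.N_SEGMENTS)
    ]


def iti_error_per_segment(
    onsets: TapOnsets, meter: MeterCandidate = INDUCED_METER
) -> list[float]:
    return [iti_error(onsets, w, meter) for w in segment_windows()]


def tapping_spectrum(
    trials: Sequence[np.ndarray],
    rate: float,
    fs: TargetFrequencySet | None = None,
    core_start_offset: float = 0.0,
):
    """Continuous sensor signals through the freqtag engine.

    Trials are averaged in the time domain, then segmented spectra are
    noise-subtracted, extracted, and z-scored exactly as for the EEG.
    Returns the per-segment z-score summaries.
    """
    segmented = [
        segment_signal(t, rate, core_start_offset, origin="tapping") for t in trials
    ]
    averaged = freqtag.average_trials(segmented)
    return segments_to_zscores(averaged, fs)


def run_tapping_participant(
    trials: pd.DataFrame,
    signals: dict[object, np.ndarray],
    rate: float,
    participant: str = "p01",
    threshold: float | None = None,
    refractory: float = 0.100,
    fs: TargetFrequencySet | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-direction tapping measures for one participant.

    ``trials`` needs columns ``trial`` and ``direction``; ``signals`` maps
    trial id to the single-channel sensor signal (core-aligned).
    """
    measure_rows, summary_rows = [], []
    for direction, sub in trials.groupby("direction"):
        sigs = [np.asarray(signals[t]) for t in sub["trial"]]
        all_itis = []
        for trial_id, sig in zip(sub["trial"], sigs):
            onsets = detect_taps(sig, rate, threshold, refractory)
            errors = iti_error_per_segment(onsets)
            itis = onsets.itis() * 1000.0
            all_itis.extend(itis[itis <= MAX_ITI * 1000.0])
            for k, err in enumerate(errors, start=1):
                measure_rows.append(
                    {
                        "participant": participant,
                        "direction": direction,
                        "trial": trial_id,
                        "segment": k,
                        "iti_error": err,
                    }
                )
        median_iti = float(np.median(all_itis)) if all_itis else float("nan")
        if np.isfinite(median_iti):
            match = meter_match(median_iti)
            best = match.loc[match["best"]].iloc[0]
            best_label, best_diff = best["meter"], best["min_percent_diff"]
        else:
            best_label, best_diff = None, float("nan")
        try:
            zs = tapping_spectrum(sigs, rate, fs)
            meter_z = [s.meter_mean_z for s in zs]
        except ValueError:  # e.g. silent recordings: zero variance
            meter_z = [float("nan")] * freqtag.N_SEGMENTS
        for k, z in enumerate(meter_z, start=1):
            summary_rows.append(
                {
                    "participant": participant,
                    "direction": direction,
                    "segment": k,
                    "meter_mean_z": z,
                    "median_iti_ms": median_iti,
                    "best_meter": best_label,
                    "best_meter_percent_diff": best_diff,
                }
            )
    return {
        "iti_errors": pd.DataFrame(measure_rows),
        "summary": pd.DataFrame(summary_rows),
    }
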