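"""Thin orchestration from raw multichannel recordings to freqtag summaries.

Preprocessing follows the standard steady-state pipeline: 0.1-Hz zero-phase
Butterworth high-pass, epoching at 0.4 s after trial onset (skipping the two
padding sounds), segmentation, common-average rereference, and time-domain
trial averaging per (direction, segment).  Deliberately pluggable: hooks for
artifact removal (ICA, channel interpolation) are accepted but default to
no-ops.  The pipeline is deterministic — it contains no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import freqtag
from .freqtag import (
    N_SEGMENTS,
    SegmentedSignal,
    TargetFrequencySet,
    average_trials,
    segment_signal,
    segments_to_zscores,
)

EPOCH_OFFSET = 0.4  # s after trial onset: skip the two padding sound events


@dataclass
class EEGRecording:
    """Continuous multichannel EEG plus its trial-onset table.

    ``trials`` needs columns ``trial`` (id), ``onset`` (s), ``direction``,
    and ``stimulus_seed`` (pairs each trial with the inversion of the same
    stimulus); an optional boolean ``include`` marks artifact-rejected trials.
    """

    data: np.ndarray  # channels × samples
    rate: float
    ch_names: list[str] = field(default_factory=list)
    trials: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[0])]


def highpass_filter(
    x: np.ndarray, rate: float, cutoff: float = 0.1, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth high-pass.

    Filtering both ways doubles the effective order but removes phase
    distortion, which matters for time-domain trial averaging.
    """
    sos = sps.butter(order, cutoff, btype="highpass", fs=rate, output="sos")
    # the impulse response of a 0.1-Hz high-pass spans seconds; pad on that
    # timescale so edge transients do not leak into the data
    padlen = min(x.shape[-1] - 1, int(round(3.0 / cutoff * rate)))
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def preprocess(
    rec: EEGRecording,
    cutoff: float = 0.1,
    order: int = 4,
    hooks: Sequence[Callable[[EEGRecording], EEGRecording]] = (),
) -> EEGRecording:
    """High-pass filter plus optional artifact-removal hooks (no-ops by default)."""
    out = replace(rec, data=highpass_filter(rec.data, rec.rate, cutoff, order))
    for hook in hooks:
        out = hook(out)
    return out


def rereference_common_average(epoch: np.ndarray) -> np.ndarray:
    """Subtract the per-sample channel mean; channel sum becomes 0 everywhere."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[0] < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    return epoch - epoch.mean(axis=0, keepdims=True)


def extract_epoch(rec: EEGRecording, onset: float, offset: float = EPOCH_OFFSET) -> np.ndarray:
    """57.6-s epoch starting ``offset`` after trial onset, nearest-sample aligned."""
    first = int(round((onset + offset) * rec.rate))
    need = freqtag.required_samples(rec.rate)
    if first < 0 or first + need > rec.data.shape[1]:
        raise ValueError(
            f"epoch at onset {onset} s runs outside the recording "
            f"({rec.data.shape[1] / rec.rate:.1f} s long)"
        )
    return rec.data[:, first : first + need]


def _paired_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop excluded trials and their direction-matched twins.

    A discarded trial removes the other direction's trial with the same
    stimulus seed, so every average is built from matched stimulus pairs.
    """
    t = trials.copy()
    if "include" not in t.columns:
        t["include"] = True
    excluded_seeds = set(t.loc[~t["include"], "stimulus_seed"])
    dropped_twins = t["stimulus_seed"].isin(excluded_seeds) & t["include"]
    if dropped_twins.any():
        warnings.warn(
            f"dropping {int(dropped_twins.sum())} trial(s) whose direction-matched "
            "twin was excluded",
            stacklevel=3,
        )
    keep = t[t["include"] & ~t["stimulus_seed"].isin(excluded_seeds)]
    # unmatched trials (no twin at all) are excluded too
    counts = keep.groupby("stimulus_seed")["direction"].nunique()
    unmatched = set(counts[counts < 2].index)
    if unmatched:
        warnings.warn(
            f"excluding {len(unmatched)} stimulus seed(s) without a matched pair",
            stacklevel=3,
        )
    return keep[~keep["stimulus_seed"].isin(unmatched)]


def aligned_segment(direction: str, raw_segment: int) -> int:
    """Segment index used when comparing directions.

    Degraded-to-regular segment order is reversed so that aligned segments
    share identical stimulus-envelope spectra with the other direction.
    """
    if direction == "degraded_to_regular":
        return N_SEGMENTS + 1 - raw_segment
    return raw_segment


def run_participant(
    rec: EEGRecording,
    trials: pd.DataFrame | None = None,
    fs: TargetFrequencySet | None = None,
    participant: str = "p01",
    noise_subtraction: bool = True,
    do_preprocess: bool = True,
) -> dict[str, pd.DataFrame]:
    """Epochs → segments → trial average per direction → spectra → z-scores.

    Returns ``{"amplitudes": long table, "summary": per-(direction, segment)
    meter_mean_z}``; degraded-to-regular rows carry both raw and reversed
    segment indices.
    """
    if trials is None:
        trials = rec.trials
    if trials is None:
        raise ValueError("no trial table supplied")
    if do_preprocess:
        rec = preprocess(rec)
    keep = _paired_trials(trials)
    by_direction: dict[str, SegmentedSignal] = {}
    for direction, sub in keep.groupby("direction"):
        segs = []
        for _, row in sub.iterrows():
            epoch = extract_epoch(rec, float(row["onset"]))
            if epoch.shape[0] >= 2:
                epoch = rereference_common_average(epoch)
            segs.append(segment_signal(epoch, rec.rate, origin="eeg"))
        by_direction[direction] = average_trials(segs)
    amp_rows, sum_rows = [], []
    for direction, segmented in by_direction.items():
        zs = segments_to_zscores(segmented, fs, noise_subtraction)
        for k, summary in enumerate(zs, start=1):
            sum_rows.append(
                {
                    "participant": participant,
                    "direction": direction,
                    "segment": k,
                    "segment_aligned": aligned_segment(direction, k),
                    "meter_mean_z": summary.meter_mean_z,
                }
            )
            for f, z in zip(summary.frequencies, summary.z):
                amp_rows.append(
                    {
                        "participant": participant,
                        "origin": "eeg",
                        "direction": direction,
                        "segment": k,
                        "segment_aligned": aligned_segment(direction, k),
                        "frequency": f,
                        "z": z,
                    }
                )
    return {
        "amplitudes": pd.DataFrame(amp_rows),
        "summary": pd.DataFrame(sum_rows),
    }
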