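"""Construction of regular-to-degraded rhythm sequences and their time inversions.

A sequence concatenates 24 placed patterns — three drawn (with replacement)
from each syncopation-range group, walking from range 8 down to range 1 — so
that cues to the meter degrade gradually.  Each pattern's starting phase is
chosen so its syncopation score is as close as possible to a per-group target,
making the score increase through the sequence.  Two sound events pad each end
of the 288-event core (57.6 s at 200 ms/event), giving 292 events (58.4 s).

Time inversion of the core yields the degraded-to-regular twin; by the
symmetry of the discrete Fourier transform the two cores have identical
envelope magnitude spectra, so any response difference between them must come
from recent context rather than from the spectral content of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .patterns import (
    CYCLE,
    DEFAULT_TEMPLATE,
    MetricTemplate,
    RhythmPattern,
    categorize_patterns,
    enumerate_unique_patterns,
    score_events_linear,
    syncopation_profile,
)

N_GROUPS = 8
PATTERNS_PER_GROUP = 3
N_PLACEMENTS = N_GROUPS * PATTERNS_PER_GROUP
CORE_EVENTS = N_PLACEMENTS * CYCLE          # 288
PAD_EVENTS = 2                              # sound events pre/appended
PADDED_EVENTS = CORE_EVENTS + 2 * PAD_EVENTS  # 292
EVENT_DURATION = 0.200                      # s
CORE_DURATION = CORE_EVENTS * EVENT_DURATION    # 57.6 s
PADDED_DURATION = PADDED_EVENTS * EVENT_DURATION  # 58.4 s

#: Per-group syncopation-score targets for range groups 8, 7, ..., 1.
SCORE_TARGETS = (1, -1, 0, 1, 2, 3, 4, 4)

REGULAR_TO_DEGRADED = "regular_to_degraded"
DEGRADED_TO_REGULAR = "degraded_to_regular"

# Segment-level analysis of sequences
SEGMENT_EVENTS = 72
SEGMENT_HOP_EVENTS = 36
N_SEGMENTS = 7
SEGMENT_SHIFTS = range(-2, 3)
#: Template for segment scoring: the construction meter without its slowest
#: (12-event) pulse, since patterns do not repeat within the sequence.
SEGMENT_TEMPLATE = MetricTemplate((2, 4), cycle=4)
ALTERNATIVE_TEMPLATES = (
    MetricTemplate((2, 4), cycle=4),
    MetricTemplate((3, 6), cycle=6),
    MetricTemplate((2, 6), cycle=6),
)


@dataclass(frozen=True)
class Placement:
    """One placed pattern: which necklace, at which phase, and how it scored."""

    pattern_id: int
    phase: int
    group_range: int
    target_score: int
    achieved_score: int


@dataclass(frozen=True)
class RhythmSequence:
    """An ordered sequence of 24 placed patterns plus padding."""

    placements: tuple[Placement, ...]
    direction: str
    core_events: np.ndarray
    seed: int
    reversed_placements: bool = False

    def __post_init__(self) -> None:
        if self.direction not in (REGULAR_TO_DEGRADED, DEGRADED_TO_REGULAR):
            raise ValueError(f"unknown direction {self.direction!r}")
        if len(self.core_events) != CORE_EVENTS:
            raise ValueError(f"core must have {CORE_EVENTS} events")

    @property
    def padded_events(self) -> np.ndarray:
        pad = np.ones(PAD_EVENTS, dtype=self.core_events.dtype)
        return np.concatenate([pad, self.core_events, pad])


def build_sequence(
    seed: int,
    template: MetricTemplate = DEFAULT_TEMPLATE,
    score_targets: Sequence[int] = SCORE_TARGETS,
    variant: str = "positive",
    patterns: Sequence[RhythmPattern] | None = None,
) -> RhythmSequence:
    """Build a seeded regular-to-degraded sequence.

    For each range group from 8 down to 1, three patterns are drawn uniformly
    with replacement; for each draw, the phase whose syncopation score is
    closest to the group target is selected (ties broken by a seeded uniform
    draw).  Identical seeds give bit-identical sequences.
    """
    if patterns is None:
        patterns = enumerate_unique_patterns()
    groups = categorize_patterns(patterns, template, variant)
    max_range = max(groups)
    working = {r: g for r, g in groups.items() if r != max_range}
    ranges = sorted(working, reverse=True)
    if len(score_targets) != len(ranges):
        raise ValueError(
            f"{len(score_targets)} score targets for {len(ranges)} range groups"
        )
    rng = np.random.default_rng(seed)
    placements: list[Placement] = []
    events: list[int] = []
    for grp_range, target in zip(ranges, score_targets):
        group = working.get(grp_range)
        if not group:
            raise ValueError(
                f"no patterns in range group {grp_range} under the chosen template/variant"
            )
        for _ in range(PATTERNS_PER_GROUP):
            pat = group[rng.integers(len(group))]
            prof = syncopation_profile(pat, template, variant)
            dist = np.abs(np.asarray(prof.per_phase_scores) - target)
            best = np.flatnonzero(dist == dist.min())
            phase = int(best[rng.integers(len(best))])
            placements.append(
                Placement(
                    pattern_id=pat.id,
                    phase=phase,
                    group_range=grp_range,
                    target_score=target,
                    achieved_score=prof.per_phase_scores[phase],
                )
            )
            events.extend(pat.rotate(phase))
    return RhythmSequence(
        placements=tuple(placements),
        direction=REGULAR_TO_DEGRADED,
        core_events=np.asarray(events, dtype=np.int8),
        seed=seed,
    )


def invert_sequence(seq: RhythmSequence) -> RhythmSequence:
    """Time-invert the core (first event becomes last); padding is re-applied.

    Inversion is an involution and preserves the core envelope magnitude
    spectrum bin-by-bin.
    """
    return replace(
        seq,
        direction=(
            DEGRADED_TO_REGULAR
            if seq.direction == REGULAR_TO_DEGRADED
            else REGULAR_TO_DEGRADED
        ),
        core_events=seq.core_events[::-1].copy(),
        placements=tuple(reversed(seq.placements)),
        reversed_placements=not seq.reversed_placements,
    )


@dataclass(frozen=True)
class StimulusWaveform:
    """Rendered audio: one 200-ms frame per padded event."""

    samples: np.ndarray
    rate: float
    event_duration: float = EVENT_DURATION
    carrier: float = 440.0
    ramp: float = 0.010


def render_audio(seq: RhythmSequence, rate: float = 44100.0) -> StimulusWaveform:
    """Render padded events to audio: ramped 440-Hz tone frames, zero silences.

    Every sound frame carries the same 200-ms pure tone with 10-ms linear
    onset and offset ramps, so peak amplitude is identical across events and
    each event envelope equals its own time reversal.
    """
    return StimulusWaveform(
        samples=render_event_audio(seq.padded_events, rate), rate=float(rate)
    )


def render_event_audio(
    events: np.ndarray,
    rate: float,
    carrier: float = 440.0,
    ramp: float = 0.010,
) -> np.ndarray:
    """Audio for an arbitrary event grid (helper shared with tests)."""
    if rate < 8000:
        raise ValueError(
            f"sampling rate {rate} too low; need >= 8000 samples/s to represent the "
            f"{carrier}-Hz carrier well above Nyquist"
        )
    n_frame = int(round(EVENT_DURATION * rate))
    t = np.arange(n_frame) / rate
    tone = np.sin(2 * np.pi * carrier * t)
    n_ramp = int(round(ramp * rate))
    env = np.ones(n_frame)
    env[:n_ramp] = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
    env[n_frame - n_ramp:] = env[:n_ramp][::-1]
    frame = tone * env
    out = np.zeros(len(events) * n_frame)
    for i, e in enumerate(np.asarray(events)):
        if e:
            out[i * n_frame : (i + 1) * n_frame] = frame
    return out


def event_envelope(events: np.ndarray, rate: float) -> np.ndarray:
    """Ideal event-gate envelope (1 during sound frames, 0 during silence)."""
    n_frame = int(round(EVENT_DURATION * rate))
    return np.repeat(np.asarray(events, dtype=float), n_frame)


@dataclass(frozen=True)
class SegmentSyncopation:
    """Minimum syncopation per 72-event analysis window, over ±2-event shifts."""

    per_segment: tuple[int, ...]
    template: MetricTemplate
    shifts: tuple[int, ...] = tuple(SEGMENT_SHIFTS)


def segment_syncopation(
    seq: RhythmSequence,
    template: MetricTemplate = SEGMENT_TEMPLATE,
    variant: str = "positive",
) -> SegmentSyncopation:
    """Score the 7 half-overlapping 72-event windows of the core.

    Each window is scored linearly (non-cyclic) at shifts of −2..+2 events;
    shifted windows at the sequence ends run into the padding sounds.  The
    minimum across shifts is kept, on the reading that listeners align their
    metric interpretation to minimize syncopation.
    """
    padded = seq.padded_events
    scores = []
    for k in range(N_SEGMENTS):
        start = k * SEGMENT_HOP_EVENTS + PAD_EVENTS  # window start in padded grid
        per_shift = []
        for s in SEGMENT_SHIFTS:
            window = padded[start + s : start + s + SEGMENT_EVENTS]
            per_shift.append(score_events_linear(window, template, variant))
        scores.append(min(per_shift))
    return SegmentSyncopation(tuple(scores), template)


def alternative_meter_check(
    seq: RhythmSequence,
    templates: Sequence[MetricTemplate] = ALTERNATIVE_TEMPLATES,
    variant: str = "positive",
):
    """Per-template per-segment minimum scores, as a table for trend inspection."""
    import pandas as pd

    rows = []
    for tpl in templates:
        seg = segment_syncopation(seq, tpl, variant)
        for i, score in enumerate(seg.per_segment):
            rows.append({"template": tpl.label(), "segment": i + 1, "score": score})
    return pd.DataFrame(rows, columns=["template", "segment", "score"])
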