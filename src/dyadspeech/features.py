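"""Session-level and blockwise (TAMA) prosodic statistics.

The time-aligned moving average (TAMA) representation summarises a frame
track as means over long overlapping windows (16 s, hopped by 8 s), which
exposes the slow dynamics of pitch and loudness.  The Pearson correlation
of the two speakers' paired block means quantifies prosodic synchrony.

All SDs here are population SDs (divide by N, not N-1): the session is
treated as the full population of frames/blocks, and the same convention
is used for speaking-time statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedFeatureError, ValidationError
from .prosody import FrameTrack, restrict_to_speech
from .session import (
    ADMINISTRATOR,
    FEATURE_ORDER,
    PARTICIPANT,
    SessionTimeline,
)
from .turns import TurnConfig, gap_stats, pause_to_turn_ratio, segment_turns, turn_taking_gaps


@dataclass(frozen=True)
class BlockConfig:
    """TAMA window: 16 s blocks advanced by an 8 s hop."""

    block_len_s: float = 16.0
    hop_s: float = 8.0

    def __post_init__(self):
        if not self.hop_s > 0:
            raise ValidationError("hop_s must be > 0")
        if self.block_len_s < self.hop_s:
            raise ValidationError("block_len_s must be >= hop_s")


@dataclass
class BlockSeries:
    """Blockwise means of one track.

    ``means[k]`` averages the valid frames whose centres fall in
    ``[k*hop, k*hop + block_len)``; it is NaN when ``counts[k] == 0``.
    """

    config: BlockConfig
    means: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.means.shape != self.counts.shape:
            raise ValidationError("means and counts must have equal length")

    def __len__(self) -> int:
        return len(self.means)

    @property
    def t_start(self) -> np.ndarray:
        return self.config.hop_s * np.arange(len(self.means))

    def to_frame(self, speaker: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "k": np.arange(len(self.means)),
                "t_start_s": self.t_start,
                "block_mean": self.means,
                "frame_count": self.counts,
            }
        )
        if speaker is not None:
            df.insert(0, "speaker", speaker)
        return df


@dataclass(frozen=True)
class SynchronyResult:
    """Pearson correlation of paired block means and the blocks used."""

    r: float
    n_blocks_used: int


def overall_stats(track: FrameTrack) -> tuple[float, float]:
    """Mean and population SD of a track over its valid frames."""
    vals = track.valid_values
    if vals.size == 0:
        raise UndefinedFeatureError("no valid frames")
    return float(np.mean(vals)), float(np.std(vals))


def blockwise_means(
    track: FrameTrack,
    cfg: BlockConfig = BlockConfig(),
    session_duration_s: float | None = None,
) -> BlockSeries:
    """TAMA blockwise means of a frame track.

    Blocks are enumerated from t=0 while the block start precedes the
    session end (the track end by default); block *k* averages the valid
    frames with centre in ``[k*hop, k*hop + block_len)``.
    """
    times = track.times
    if session_duration_s is None:
        session_duration_s = float(times[-1]) + track.frame_shift_s / 2 if len(track) else 0.0
    n_blocks = max(int(math.ceil(session_duration_s / cfg.hop_s)), 0)
    order = times[track.valid]
    vals = track.valid_values
    # `order` is sorted because frame times are an increasing grid
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    starts = cfg.hop_s * np.arange(n_blocks)
    lo = np.searchsorted(order, starts, side="left")
    hi = np.searchsorted(order, starts + cfg.block_len_s, side="left")
    counts = hi - lo
    means = np.full(n_blocks, np.nan)
    nz = counts > 0
    means[nz] = (csum[hi[nz]] - csum[lo[nz]]) / counts[nz]
    return BlockSeries(cfg, means, counts)


def blockwise_sd(series: BlockSeries) -> float:
    """Population SD of the block means over non-empty blocks."""
    usable = series.means[series.counts >= 1]
    if usable.size == 0:
        raise UndefinedFeatureError("no usable blocks")
    return float(np.std(usable))


def blockwise_correlation(x: BlockSeries, y: BlockSeries) -> SynchronyResult:
    """Prosodic synchrony: Pearson r of paired block means.

    Only blocks where both speakers have at least one valid frame enter the
    correlation.  Fewer than two common blocks, or a constant series, leave
    the feature undefined rather than zero.
    """
    if x.config != y.config:
        raise ValidationError("block series must share a BlockConfig")
    n = min(len(x), len(y))
    common = (x.counts[:n] >= 1) & (y.counts[:n] >= 1)
    xm = x.means[:n][common]
    ym = y.means[:n][common]
    if xm.size < 2:
        raise UndefinedFeatureError("fewer than 2 common blocks")
    if np.ptp(xm) == 0 or np.ptp(ym) == 0:
        raise UndefinedFeatureError("constant block series")
    r = float(np.corrcoef(xm, ym)[0, 1])
    return SynchronyResult(r, int(xm.size))


def speech_rate(timeline: SessionTimeline, speaker_id: str) -> float:
    """Articulation rate in morae per second of actual speech.

    Total mora count divided by total IPU duration; silence between IPUs
    does not dilute the rate (pausing is quantified separately).
    """
    ipus = timeline.speaker_ipus(speaker_id)
    if not ipus:
        raise UndefinedFeatureError("no IPUs for speaker")
    if any(u.mora_count is None for u in ipus):
        raise UndefinedFeatureError("mora_count missing on some IPUs")
    total_time = sum(u.duration_s for u in ipus)
    if total_time <= 0:
        raise UndefinedFeatureError("zero speech time")
    return sum(u.mora_count for u in ipus) / total_time


def speaking_time_stats(timeline: SessionTimeline, speaker_id: str) -> tuple[float, float]:
    """Mean and population SD of the speaker's IPU durations in seconds."""
    durations = np.array([u.duration_s for u in timeline.speaker_ipus(speaker_id)])
    if durations.size == 0:
        raise UndefinedFeatureError("no IPUs for speaker")
    return float(np.mean(durations)), float(np.std(durations))


@dataclass
class SessionFeatureVector:
    """The 13 exported speech features of one participant.

    Undefined components are NaN with the reason in ``undefined_reasons``.
    The session-mean intensity is kept internally (``mean_intensity``) but
    never exported: it depends on the unknown microphone distance.
    """

    mean_log_f0: float = math.nan
    sd_log_f0: float = math.nan
    sd_block_log_f0: float = math.nan
    corr_block_log_f0: float = math.nan
    sd_intensity: float = math.nan
    sd_block_intensity: float = math.nan
    corr_block_intensity: float = math.nan
    speech_rate: float = math.nan
    mean_speaking_time_s: float = math.nan
    sd_speaking_time_s: float = math.nan
    mean_turn_gap_s: float = math.nan
    sd_turn_gap_s: float = math.nan
    pause_to_turn_ratio: float = math.nan
    mean_intensity: float = math.nan  # internal, not exported
    frac_negative_gap: float = math.nan  # diagnostic, not one of the 13
    undefined_reasons: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        """The 13 exported features in canonical order."""
        return {name: getattr(self, name) for name in FEATURE_ORDER}

    @property
    def is_complete(self) -> bool:
        return not self.undefined_reasons


def assemble_features(
    timeline: SessionTimeline,
    participant_f0: FrameTrack,
    participant_intensity: FrameTrack,
    administrator_f0: FrameTrack,
    administrator_intensity: FrameTrack,
    block_cfg: BlockConfig = BlockConfig(),
    turn_cfg: TurnConfig = TurnConfig(),
    restrict: bool = True,
) -> SessionFeatureVector:
    """Compute the full 13-feature vector for one session.

    Tracks are restricted to each speaker's own non-overlapping speech
    (unless ``restrict=False``, for tracks already restricted).  Undefined
    components are recorded with reasons, never silently zeroed.
    """
    out = SessionFeatureVector()

    def attempt(names, fn):
        try:
            values = fn()
        except UndefinedFeatureError as exc:
            for name in names:
                out.undefined_reasons[name] = exc.reason
            return
        if not isinstance(values, tuple):
            values = (values,)
        for name, value in zip(names, values):
            setattr(out, name, value)

    if restrict:
        p_f0 = restrict_to_speech(participant_f0, timeline, PARTICIPANT)
        p_int = restrict_to_speech(participant_intensity, timeline, PARTICIPANT)
        a_f0 = restrict_to_speech(administrator_f0, timeline, ADMINISTRATOR)
        a_int = restrict_to_speech(administrator_intensity, timeline, ADMINISTRATOR)
    else:
        p_f0, p_int = participant_f0, participant_intensity
        a_f0, a_int = administrator_f0, administrator_intensity

    attempt(("mean_log_f0", "sd_log_f0"), lambda: overall_stats(p_f0))
    attempt(("mean_intensity", "sd_intensity"), lambda: overall_stats(p_int))

    dur = timeline.duration_s
    p_f0_blocks = blockwise_means(p_f0, block_cfg, dur)
    p_int_blocks = blockwise_means(p_int, block_cfg, dur)
    a_f0_blocks = blockwise_means(a_f0, block_cfg, dur)
    a_int_blocks = blockwise_means(a_int, block_cfg, dur)

    attempt(("sd_block_log_f0",), lambda: blockwise_sd(p_f0_blocks))
    attempt(("sd_block_intensity",), lambda: blockwise_sd(p_int_blocks))
    attempt(
        ("corr_block_log_f0",),
        lambda: blockwise_correlation(p_f0_blocks, a_f0_blocks).r,
    )
    attempt(
        ("corr_block_intensity",),
        lambda: blockwise_correlation(p_int_blocks, a_int_blocks).r,
    )

    attempt(("speech_rate",), lambda: speech_rate(timeline, PARTICIPANT))
    attempt(
        ("mean_speaking_time_s", "sd_speaking_time_s"),
        lambda: speaking_time_stats(timeline, PARTICIPANT),
    )

    gaps = turn_taking_gaps(timeline)
    attempt(
        ("mean_turn_gap_s", "sd_turn_gap_s", "frac_negative_gap"),
        lambda: gap_stats(gaps),
    )
    turns = segment_turns(timeline, turn_cfg)
    attempt(
        ("pause_to_turn_ratio",),
        lambda: pause_to_turn_ratio(turns, PARTICIPANT),
    )
    return out
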