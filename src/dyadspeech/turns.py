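"""Turn-taking gaps, speaking turns, and the pause-to-turn ratio.

A turn-taking gap is the signed latency from the end of the
administrator's utterance to the start of the participant's next
utterance; it is negative when the participant starts before the
administrator finishes.  Backchannels — short utterances inserted into
the interlocutor's speech without claiming the floor — are excluded: a
participant IPU lying entirely inside an administrator IPU yields no gap
event, and sub-threshold (< 0.5 s) utterances never start or end a turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedFeatureError, ValidationError
from .session import ADMINISTRATOR, PARTICIPANT, IpuSegment, SessionTimeline


@dataclass(frozen=True)
class TurnConfig:
    """Minimum utterance duration for an IPU to start or end a turn."""

    turn_utterance_threshold_s: float = 0.5

    def __post_init__(self):
        if not self.turn_utterance_threshold_s > 0:
            raise ValidationError("turn threshold must be > 0")


@dataclass(frozen=True)
class GapEvent:
    """One administrator-to-participant floor exchange."""

    admin_end_s: float
    participant_start_s: float

    @property
    def gap_s(self) -> float:
        return self.participant_start_s - self.admin_end_s


@dataclass(frozen=True)
class TurnSegment:
    """One speaker's floor-holding span with its internal speech/pause split."""

    speaker_id: str
    start_s: float
    end_s: float
    speech_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def pause_s(self) -> float:
        return self.duration_s - self.speech_s


def _contained(u: IpuSegment, others: tuple[IpuSegment, ...]) -> bool:
    """True if ``u`` lies entirely within some interval of ``others``."""
    return any(o.start_s <= u.start_s and u.end_s <= o.end_s for o in others)


def turn_taking_gaps(
    timeline: SessionTimeline, merge_admin_ipus: bool = False
) -> list[GapEvent]:
    """Signed response latencies at administrator-to-participant exchanges.

    Fully overlapped IPUs are treated as backchannels and removed before
    speaker-change detection: participant IPUs inside an administrator IPU
    emit no event, and administrator IPUs inside a participant IPU do not
    break the participant's floor.  For each remaining participant IPU *p*
    that directly follows administrator speech, the gap is measured from
    the administrator IPU with the latest end among those starting before
    *p* (with ``merge_admin_ipus``, from the end of the administrator's
    last IPU chain instead; both conventions coincide on non-overlapping
    question/answer exchanges).
    """
    admin_all = timeline.speaker_ipus(ADMINISTRATOR)
    part_all = timeline.speaker_ipus(PARTICIPANT)
    admin = [u for u in admin_all if not _contained(u, part_all)]
    part = [u for u in part_all if not _contained(u, admin_all)]
    ordered = sorted(admin + part, key=lambda u: (u.start_s, u.end_s))

    events: list[GapEvent] = []
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.speaker_id != PARTICIPANT or prev.speaker_id != ADMINISTRATOR:
            continue
        candidates = [a for a in admin if a.start_s < cur.start_s]
        if not candidates:
            continue
        if merge_admin_ipus:
            anchor_end = max(a.end_s for a in candidates)
        else:
            anchor_end = max(candidates, key=lambda a: a.end_s).end_s
        events.append(GapEvent(anchor_end, cur.start_s))
    return events


def gap_stats(gaps: list[GapEvent]) -> tuple[float, float, float]:
    """Raw mean, population SD, and fraction of negative gaps.

    Cohort-level transforms (the shifted log of the mean gap, the log of
    the gap SD) are applied later, in the group statistics.
    """
    if not gaps:
        raise UndefinedFeatureError("no turn-taking gaps")
    values = np.array([g.gap_s for g in gaps])
    return (
        float(np.mean(values)),
        float(np.std(values)),
        float(np.mean(values < 0)),
    )


def segment_turns(
    timeline: SessionTimeline, cfg: TurnConfig = TurnConfig()
) -> list[TurnSegment]:
    """Partition the session into speaking turns.

    A turn starts at the speaker's first turn-relevant IPU (duration above
    the threshold, not fully inside the other speaker's IPU) after the
    other speaker's floor-holding, and ends at the end of the speaker's
    last IPU before the other speaker's next turn-relevant IPU begins.
    Sub-threshold interjections by the other speaker do not end a turn;
    the time they occupy inside the turn counts as the holder's pause.
    """
    thr = cfg.turn_utterance_threshold_s
    by_speaker = {
        s: timeline.speaker_ipus(s) for s in (PARTICIPANT, ADMINISTRATOR)
    }
    other = {PARTICIPANT: ADMINISTRATOR, ADMINISTRATOR: PARTICIPANT}
    relevant = sorted(
        (
            u
            for u in timeline.ipus
            if u.duration_s > thr and not _contained(u, by_speaker[other[u.speaker_id]])
        ),
        key=lambda u: (u.start_s, u.end_s),
    )
    if not relevant:
        return []

    # group consecutive relevant IPUs of the same speaker into floor runs
    runs: list[list[IpuSegment]] = [[relevant[0]]]
    for u in relevant[1:]:
        if u.speaker_id == runs[-1][0].speaker_id:
            runs[-1].append(u)
        else:
            runs.append([u])

    turns: list[TurnSegment] = []
    for j, run in enumerate(runs):
        speaker = run[0].speaker_id
        turn_start = run[0].start_s
        next_rel_start = runs[j + 1][0].start_s if j + 1 < len(runs) else np.inf
        own = [
            u
            for u in by_speaker[speaker]
            if u.start_s >= turn_start and u.start_s < next_rel_start
        ]
        turn_end = max(u.end_s for u in own)
        speech = sum(
            max(0.0, min(u.end_s, turn_end) - max(u.start_s, turn_start)) for u in own
        )
        turns.append(TurnSegment(speaker, turn_start, turn_end, speech))
    return turns


def pause_to_turn_ratio(turns: list[TurnSegment], speaker_id: str) -> float:
    """Pooled ratio of silent time to total turn time for one speaker.

    Total pause across the speaker's turns divided by total turn duration
    (not the mean of per-turn ratios).
    """
    own = [t for t in turns if t.speaker_id == speaker_id]
    if not own:
        raise UndefinedFeatureError("speaker holds no turns")
    total = sum(t.duration_s for t in own)
    if total <= 0:
        raise UndefinedFeatureError("zero total turn duration")
    return sum(t.pause_s for t in own) / total


def gaps_to_frame(gaps: list[GapEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gap_s": [g.gap_s for g in gaps],
            "admin_end_s": [g.admin_end_s for g in gaps],
            "participant_start_s": [g.participant_start_s for g in gaps],
        }
    )


def turns_to_frame(turns: list[TurnSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "speaker": [t.speaker_id for t in turns],
            "start_s": [t.start_s for t in turns],
            "end_s": [t.end_s for t in turns],
            "speech_s": [t.speech_s for t in turns],
            "pause_s": [t.pause_s for t in turns],
        }
    )
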