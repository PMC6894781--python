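"""Session data model and I/O for dyadic interview recordings.

A session is represented by the two speakers' inter-pausal units (IPUs):
maximal speech intervals bounded by silences longer than a configurable
threshold (200 ms by default).  Same-speaker intervals separated by a
silence at or below the threshold are merged into a single IPU.

Times are seconds from session start; intervals are half-open
``[start_s, end_s)``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

PARTICIPANT = "participant"
ADMINISTRATOR = "administrator"
SPEAKERS = (PARTICIPANT, ADMINISTRATOR)

#: Canonical order of the 13 exported speech features.
FEATURE_ORDER = [
    "mean_log_f0",
    "sd_log_f0",
    "sd_block_log_f0",
    "corr_block_log_f0",
    "sd_intensity",
    "sd_block_intensity",
    "corr_block_intensity",
    "speech_rate",
    "mean_speaking_time_s",
    "sd_speaking_time_s",
    "mean_turn_gap_s",
    "sd_turn_gap_s",
    "pause_to_turn_ratio",
]

SCORE_DOMAINS = ("reciprocity", "communication", "repetitive")
METADATA_COLUMNS = ["participant_id", "group", *SCORE_DOMAINS]


@dataclass(frozen=True)
class SegmentationConfig:
    """Silence threshold used to delimit IPUs.

    A silence of exactly ``ipu_merge_gap_s`` does not split speech: only
    silences strictly longer than the threshold separate two IPUs.
    """

    ipu_merge_gap_s: float = 0.2

    def __post_init__(self):
        if not self.ipu_merge_gap_s > 0:
            raise ValidationError("ipu_merge_gap_s must be > 0")


@dataclass(frozen=True)
class IpuSegment:
    """One inter-pausal unit of one speaker."""

    speaker_id: str
    start_s: float
    end_s: float
    mora_count: int | None = None
    label: str | None = None

    def __post_init__(self):
        if self.speaker_id not in SPEAKERS:
            raise ValidationError(
                f"speaker_id must be one of {SPEAKERS}, got {self.speaker_id!r}"
            )
        if not (math.isfinite(self.start_s) and math.isfinite(self.end_s)):
            raise ValidationError("IPU boundaries must be finite")
        if self.start_s < 0:
            raise ValidationError(f"IPU start {self.start_s} < 0")
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"degenerate IPU [{self.start_s}, {self.end_s}): end must exceed start"
            )
        if self.mora_count is not None and self.mora_count < 0:
            raise ValidationError("mora_count must be nonnegative")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SessionTimeline:
    """Ordered IPUs of both speakers for one session."""

    session_id: str
    ipus: tuple[IpuSegment, ...]
    duration_s: float

    def __post_init__(self):
        object.__setattr__(
            self, "ipus", tuple(sorted(self.ipus, key=lambda u: (u.start_s, u.end_s)))
        )

    def speaker_ipus(self, speaker_id: str) -> tuple[IpuSegment, ...]:
        return tuple(u for u in self.ipus if u.speaker_id == speaker_id)

    def validate(self, config: SegmentationConfig = SegmentationConfig()) -> None:
        """Check the post-merge invariants, raising :class:`ValidationError`."""
        for u in self.ipus:
            if u.end_s > self.duration_s + 1e-9:
                raise ValidationError(
                    f"IPU [{u.start_s}, {u.end_s}) exceeds session duration "
                    f"{self.duration_s}"
                )
        for speaker in SPEAKERS:
            ipus = self.speaker_ipus(speaker)
            for a, b in zip(ipus, ipus[1:]):
                gap = b.start_s - a.end_s
                if gap <= config.ipu_merge_gap_s + 1e-12:
                    raise ValidationError(
                        f"{speaker} IPUs at {a.end_s:.3f}/{b.start_s:.3f} are separated "
                        f"by {gap:.3f} s <= merge threshold; merge_to_ipus not applied?"
                    )

    def shifted(self, dt: float) -> "SessionTimeline":
        """Return a copy with every interval translated by ``dt`` seconds."""
        return SessionTimeline(
            self.session_id,
            tuple(
                replace(u, start_s=u.start_s + dt, end_s=u.end_s + dt)
                for u in self.ipus
            ),
            self.duration_s + dt,
        )


def merge_to_ipus(
    intervals: Sequence[tuple[float, float] | IpuSegment],
    config: SegmentationConfig = SegmentationConfig(),
    speaker_id: str = PARTICIPANT,
) -> list[IpuSegment]:
    """Merge one speaker's speech intervals separated by short silences.

    Consecutive intervals whose silence is at most ``config.ipu_merge_gap_s``
    become a single IPU; mora counts are summed when present on all merged
    parts, and dropped (None) otherwise.  Idempotent.
    """
    segs: list[IpuSegment] = []
    for i, item in enumerate(intervals):
        if isinstance(item, IpuSegment):
            segs.append(item)
            speaker_id = item.speaker_id
        else:
            start, end = item
            if not end > start:
                raise ValidationError(
                    f"interval {i} ({start}, {end}): end must exceed start"
                )
            segs.append(IpuSegment(speaker_id, float(start), float(end)))
    for i, (a, b) in enumerate(zip(segs, segs[1:])):
        if b.start_s < a.start_s:
            raise ValidationError(f"interval {i + 1} starts before interval {i}")
        if b.start_s < a.end_s:
            raise ValidationError(
                f"intervals {i} and {i + 1} overlap ([{a.start_s}, {a.end_s}) vs "
                f"[{b.start_s}, {b.end_s}))"
            )
    merged: list[IpuSegment] = []
    for seg in segs:
        if merged and seg.start_s - merged[-1].end_s <= config.ipu_merge_gap_s:
            prev = merged[-1]
            if prev.mora_count is None or seg.mora_count is None:
                mora = None
            else:
                mora = prev.mora_count + seg.mora_count
            merged[-1] = replace(prev, end_s=seg.end_s, mora_count=mora)
        else:
            merged.append(seg)
    return merged


_DEFAULT_DIALECT = {
    "speaker": "speaker",
    "start": "start_s",
    "end": "end_s",
    "mora_count": "mora_count",
    "label": "label",
    "session_id": "session_id",
}


def read_ipu_table(
    source,
    dialect: Mapping[str, str] | None = None,
    speaker_map: Mapping[str, str] | None = None,
    config: SegmentationConfig = SegmentationConfig(),
    session_id: str | None = None,
    duration_s: float | None = None,
) -> SessionTimeline:
    """Read a per-session IPU table (CSV) into a validated timeline.

    ``dialect`` maps the logical column roles (``speaker``, ``start``,
    ``end``, optional ``mora_count``/``label``/``session_id``) onto the file's
    column names; the default expects ``speaker,start_s,end_s`` with optional
    ``mora_count,label,session_id``.  ``speaker_map`` translates file speaker
    labels to the canonical ``participant``/``administrator``.  Per-speaker
    intervals are sorted and passed through :func:`merge_to_ipus`.
    """
    cols = dict(_DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    try:
        df = pd.read_csv(source)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read IPU table: {exc}") from exc
    for role in ("speaker", "start", "end"):
        if cols[role] not in df.columns:
            raise ParseError(
                f"missing required column {cols[role]!r} (have {list(df.columns)})"
            )
    has_mora = cols["mora_count"] in df.columns
    has_label = cols["label"] in df.columns

    per_speaker: dict[str, list[IpuSegment]] = {s: [] for s in SPEAKERS}
    for idx, row in df.iterrows():
        raw_speaker = str(row[cols["speaker"]])
        speaker = (speaker_map or {}).get(raw_speaker, raw_speaker)
        try:
            start = float(row[cols["start"]])
            end = float(row[cols["end"]])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {idx}: non-numeric time ({exc})") from exc
        mora = None
        if has_mora and pd.notna(row[cols["mora_count"]]):
            mora = int(row[cols["mora_count"]])
        label = None
        if has_label and pd.notna(row[cols["label"]]):
            label = str(row[cols["label"]])
        try:
            seg = IpuSegment(speaker, start, end, mora, label)
        except ValidationError as exc:
            raise ParseError(f"row {idx}: {exc}") from exc
        per_speaker[seg.speaker_id].append(seg)

    ipus: list[IpuSegment] = []
    for speaker, segs in per_speaker.items():
        segs.sort(key=lambda u: u.start_s)
        try:
            ipus.extend(merge_to_ipus(segs, config))
        except ValidationError as exc:
            raise ParseError(f"speaker {speaker!r}: {exc}") from exc

    if session_id is None:
        if cols["session_id"] in df.columns and len(df):
            session_id = str(df[cols["session_id"]].iloc[0])
        else:
            session_id = "session"
    if duration_s is None:
        duration_s = max((u.end_s for u in ipus), default=0.0)
    timeline = SessionTimeline(session_id, tuple(ipus), float(duration_s))
    timeline.validate(config)
    return timeline


def write_ipu_table(timeline: SessionTimeline, sink) -> None:
    """Write a timeline in the canonical IPU CSV layout."""
    rows = [
        {
            "session_id": timeline.session_id,
            "speaker": u.speaker_id,
            "start_s": u.start_s,
            "end_s": u.end_s,
            "mora_count": u.mora_count,
            "label": u.label,
        }
        for u in timeline.ipus
    ]
    pd.DataFrame(
        rows, columns=["session_id", "speaker", "start_s", "end_s", "mora_count", "label"]
    ).to_csv(sink, index=False)


# ---------------------------------------------------------------------------
# Praat TextGrid reading (long and short text form, interval tiers only)
# ---------------------------------------------------------------------------


def _textgrid_tokens(text: str) -> list[str]:
    """Extract the value tokens of a TextGrid file, quoted or bare."""
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == '"':
            j = i + 1
            buf = []
            while j < n:
                if text[j] == '"':
                    if j + 1 < n and text[j + 1] == '"':  # escaped quote
                        buf.append('"')
                        j += 2
                        continue
                    break
                buf.append(text[j])
                j += 1
            tokens.append('"' + "".join(buf))
            i = j + 1
        elif ch.isspace():
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace():
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


def _parse_textgrid(text: str) -> tuple[float, dict[str, list[tuple[float, float, str]]]]:
    """Parse a TextGrid into {tier name: [(xmin, xmax, label), ...]}.

    Handles both the long form (``item [1]: class = "IntervalTier" ...``) and
    the short form (bare tokens).  Point tiers are recorded with an empty
    interval list marker so callers can give a precise error.
    """
    tokens = _textgrid_tokens(text)
    # strip long-form keys like `xmin =`, `intervals [1]:` by keeping only
    # quoted strings and numbers
    values: list[str] = []
    for tok in tokens:
        if tok.startswith('"'):
            values.append(tok)
        else:
            try:
                float(tok)
            except ValueError:
                continue
            values.append(tok)
    if len(values) < 4 or values[0] != '"ooTextFile':
        raise ParseError("not a TextGrid: bad header")
    if values[1] != '"TextGrid':
        raise ParseError("not a TextGrid: object class is " + values[1].lstrip('"'))
    pos = 2
    xmax_file = float(values[pos + 1])
    pos += 2
    n_tiers = int(float(values[pos]))
    pos += 1
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    point_tiers: set[str] = set()
    for _ in range(n_tiers):
        tier_class = values[pos].lstrip('"')
        name = values[pos + 1].lstrip('"')
        pos += 2
        pos += 2  # tier xmin / xmax
        size = int(float(values[pos]))
        pos += 1
        if tier_class == "IntervalTier":
            ivs = []
            for _ in range(size):
                xmin = float(values[pos])
                xmax = float(values[pos + 1])
                label = values[pos + 2].lstrip('"')
                pos += 3
                ivs.append((xmin, xmax, label))
            tiers[name] = ivs
        elif tier_class == "TextTier":
            point_tiers.add(name)
            pos += 2 * size
            tiers[name] = []
        else:
            raise ParseError(f"unknown tier class {tier_class!r}")
    for name in point_tiers:
        tiers[name] = None  # type: ignore[assignment]
    return xmax_file, tiers


def read_textgrid(
    source,
    tier_map: Mapping[str, str],
    config: SegmentationConfig = SegmentationConfig(),
    session_id: str = "session",
) -> SessionTimeline:
    """Read a two-tier Praat TextGrid into a timeline.

    ``tier_map`` maps canonical speaker ids to tier names.  Intervals with a
    non-empty label are speech; empty-label intervals are silence.  Speech
    intervals separated by silences at or below the merge threshold become
    one IPU.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    xmax, tiers = _parse_textgrid(text)
    ipus: list[IpuSegment] = []
    for speaker, tier_name in tier_map.items():
        if tier_name not in tiers:
            raise ParseError(
                f"tier {tier_name!r} not found; available tiers: {sorted(tiers)}"
            )
        ivs = tiers[tier_name]
        if ivs is None:
            raise ParseError(f"tier {tier_name!r} is a point tier, expected intervals")
        speech = [
            (xmin, xmax_i)
            for xmin, xmax_i, label in ivs
            if label.strip()
        ]
        speech.sort()
        ipus.extend(merge_to_ipus(speech, config, speaker_id=speaker))
    timeline = SessionTimeline(session_id, tuple(ipus), xmax)
    timeline.validate(config)
    return timeline


# ---------------------------------------------------------------------------
# Cohort feature table
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Per-participant speech features, group labels and symptom scores.

    Wraps a :class:`pandas.DataFrame` with columns ``participant_id``,
    ``group`` (ASD/TD), the three symptom-score domains and the 13 features
    in :data:`FEATURE_ORDER`.  Missing (undefined) features are NaN with the
    reason recorded in ``undefined_reasons``.
    """

    data: pd.DataFrame
    undefined_reasons: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        for col in ("participant_id", "group"):
            if col not in df.columns:
                raise ValidationError(f"cohort table missing column {col!r}")
        if df["participant_id"].duplicated().any():
            dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
            raise ValidationError(f"duplicate participant_id {dup!r}")
        if df["group"].isna().any() or (df["group"] == "").any():
            raise ValidationError("group labels must be non-empty")
        for col in FEATURE_ORDER + list(SCORE_DOMAINS):
            if col not in df.columns:
                df[col] = np.nan
        for col in SCORE_DOMAINS:
            scores = df[col].dropna()
            if (scores < 0).any():
                raise ValidationError(f"{col} scores must be >= 0")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def group(self, label: str) -> pd.DataFrame:
        return self.data[self.data["group"] == label]

    def features(self, group: str | None = None) -> pd.DataFrame:
        df = self.data if group is None else self.group(group)
        return df.set_index("participant_id")[FEATURE_ORDER]


def write_feature_table(cohort: CohortTable, sink) -> None:
    """Write the cohort feature table as CSV.

    Undefined features become empty cells; a sidecar column
    ``undefined_reason`` lists ``feature=reason`` pairs for the row.
    """
    if not len(cohort):
        raise ValidationError("cannot write an empty cohort")
    df = cohort.data[METADATA_COLUMNS + FEATURE_ORDER].copy()
    reasons = []
    for pid in df["participant_id"]:
        per = cohort.undefined_reasons.get(str(pid), {})
        reasons.append(";".join(f"{k}={v}" for k, v in sorted(per.items())) or None)
    df["undefined_reason"] = reasons
    df.to_csv(sink, index=False, na_rep="")


def read_feature_table(source) -> CohortTable:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(source)
    missing = [c for c in ("participant_id", "group") if c not in df.columns]
    if missing:
        raise ParseError(f"feature table missing columns {missing}")
    df["participant_id"] = df["participant_id"].astype(str)
    reasons: dict[str, dict[str, str]] = {}
    if "undefined_reason" in df.columns:
        for pid, cell in zip(df["participant_id"], df["undefined_reason"]):
            if isinstance(cell, str) and cell:
                reasons[pid] = dict(
                    item.split("=", 1) for item in cell.split(";") if "=" in item
                )
        df = df.drop(columns=["undefined_reason"])
    return CohortTable(df, undefined_reasons=reasons)
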