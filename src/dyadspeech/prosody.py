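"""Frame-level prosodic track extraction.

Produces evenly spaced log-F0 and intensity tracks with a validity mask,
restricted to each speaker's own non-overlapping speech.  Pitch tracking
itself is delegated to a pluggable backend (e.g. a Praat binding); this
module implements the two-pass adaptive pitch-range procedure around it,
a windowed-energy intensity track, and the speech/overlap restriction.

The canonical pipeline path works from precomputed frame tracks (CSV), so
no audio backend is required to run the full analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .session import SessionTimeline

#: Reference power for the intensity scale, (20 uPa)^2 — the auditory
#: threshold convention.  The absolute offset is arbitrary for this analysis:
#: only SDs and correlations of intensity are used downstream.
INTENSITY_REFERENCE = 4e-10


@dataclass(frozen=True)
class FrameConfig:
    """Frame grid: 10 ms hop, 32 ms intensity analysis window."""

    frame_shift_s: float = 0.010
    intensity_window_s: float = 0.032

    def __post_init__(self):
        if not self.frame_shift_s > 0:
            raise ValidationError("frame_shift_s must be > 0")
        if self.intensity_window_s < self.frame_shift_s:
            raise ValidationError("intensity window must be >= frame shift")


@dataclass(frozen=True)
class PitchConfig:
    """Two-pass adaptive pitch range.

    Pass 1 runs the backend with a wide fixed range
    (``pass1_floor_hz``..``pass1_ceiling_hz``).  The lower and upper
    quantiles of the voiced pass-1 F0 values then set the pass-2 range:
    floor = ``floor_multiplier`` x lower quantile, ceiling =
    ``ceiling_multiplier`` x upper quantile.  ``manual_override`` skips the
    adaptation entirely (used when pass 1 fails for atypical voices).
    """

    pass1_floor_hz: float = 32.0
    pass1_ceiling_hz: float = 200.0
    quantile_low: float = 0.25
    quantile_high: float = 0.75
    floor_multiplier: float = 0.75
    ceiling_multiplier: float = 2.0
    manual_override: tuple[float, float] | None = None

    def __post_init__(self):
        if not 0 < self.pass1_floor_hz < self.pass1_ceiling_hz:
            raise ValidationError("need 0 < pass1 floor < pass1 ceiling")
        if not 0 < self.quantile_low < self.quantile_high < 1:
            raise ValidationError("need 0 < quantile_low < quantile_high < 1")
        if self.manual_override is not None:
            lo, hi = self.manual_override
            if not 0 < lo < hi:
                raise ValidationError("manual_override must satisfy 0 < floor < ceiling")


class PitchBackend(Protocol):
    """Contract for an external pitch detector.

    Called as ``backend(signal, rate, floor_hz, ceiling_hz, frame_shift_s)``
    and must return per-frame F0 in Hz with unvoiced frames as NaN; voiced
    values lie within [floor_hz, ceiling_hz].
    """

    def __call__(
        self,
        signal: np.ndarray,
        rate: float,
        floor_hz: float,
        ceiling_hz: float,
        frame_shift_s: float,
    ) -> np.ndarray: ...


@dataclass
class FrameTrack:
    """Evenly spaced frame values with a validity mask.

    ``values`` are natural-log Hz for pitch or dB for intensity; frame *i*
    is centred at ``t0_s + i * frame_shift_s``.  Values must be finite
    wherever ``valid`` is True.
    """

    frame_shift_s: float
    t0_s: float
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape or self.values.ndim != 1:
            raise ValidationError("values and valid must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValidationError("values must be finite wherever valid")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Frame-center times in seconds."""
        return self.t0_s + self.frame_shift_s * np.arange(len(self.values))

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def two_pass_pitch(
    signal: np.ndarray,
    rate: float,
    backend: PitchBackend,
    pcfg: PitchConfig = PitchConfig(),
    fcfg: FrameConfig = FrameConfig(),
) -> FrameTrack:
    """Adaptive two-pass pitch extraction, returning natural-log F0.

    With ``pcfg.manual_override`` set, this reduces to a single backend call
    at the given bounds (log-transformed).
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValidationError("audio signal is empty")
    if pcfg.manual_override is not None:
        floor, ceiling = pcfg.manual_override
    else:
        f0_pass1 = np.asarray(
            backend(signal, rate, pcfg.pass1_floor_hz, pcfg.pass1_ceiling_hz,
                    fcfg.frame_shift_s),
            dtype=np.float64,
        )
        voiced = f0_pass1[np.isfinite(f0_pass1)]
        if voiced.size == 0:
            raise ValidationError(
                "pass-1 pitch detection found no voiced frames; supply "
                "PitchConfig.manual_override with a hand-tuned floor/ceiling"
            )
        q_low, q_high = np.quantile(voiced, [pcfg.quantile_low, pcfg.quantile_high])
        floor = pcfg.floor_multiplier * q_low
        ceiling = pcfg.ceiling_multiplier * q_high
    f0 = np.asarray(
        backend(signal, rate, floor, ceiling, fcfg.frame_shift_s), dtype=np.float64
    )
    valid = np.isfinite(f0)
    if np.any((f0[valid] < floor - 1e-9) | (f0[valid] > ceiling + 1e-9)):
        raise ValidationError("backend returned F0 outside [floor, ceiling]")
    values = np.full_like(f0, np.nan)
    values[valid] = np.log(f0[valid])
    return FrameTrack(fcfg.frame_shift_s, fcfg.frame_shift_s / 2, values, valid)


def intensity_track(
    signal: np.ndarray,
    rate: float,
    fcfg: FrameConfig = FrameConfig(),
    reference: float = INTENSITY_REFERENCE,
) -> FrameTrack:
    """Windowed mean-square intensity in dB re ``reference``.

    Frame *i* is centred at ``(i + 1/2) * frame_shift_s``; the analysis
    window of ``intensity_window_s`` is clipped to the signal.  Frames whose
    window has zero energy are invalid.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValidationError("audio signal is empty")
    duration = signal.size / rate
    if fcfg.frame_shift_s > duration:
        raise ValidationError(
            f"frame shift {fcfg.frame_shift_s} s exceeds signal duration {duration:.4f} s"
        )
    n_frames = int(np.floor(duration / fcfg.frame_shift_s))
    centers = (np.arange(n_frames) + 0.5) * fcfg.frame_shift_s
    half = fcfg.intensity_window_s / 2
    lo = np.maximum(0, np.round((centers - half) * rate).astype(int))
    hi = np.minimum(signal.size, np.round((centers + half) * rate).astype(int))
    sq = np.concatenate([[0.0], np.cumsum(signal**2)])
    energy = sq[hi] - sq[lo]
    count = np.maximum(hi - lo, 1)
    mean_sq = energy / count
    valid = mean_sq > 0
    values = np.full(n_frames, np.nan)
    values[valid] = 10.0 * np.log10(mean_sq[valid] / reference)
    return FrameTrack(fcfg.frame_shift_s, fcfg.frame_shift_s / 2, values, valid)


def read_wav(path, expected_rate: int = 16000) -> tuple[np.ndarray, float]:
    """Read a mono PCM WAV file, normalized to [-1, 1].

    The canonical recording format is 16 kHz, 16-bit PCM; other sample
    rates are rejected (resampling is out of scope — pass
    ``expected_rate=None`` only when the pitch backend handles the rate
    itself).  Stereo files are rejected: channel separation of mixed
    recordings is not this package's job.
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if expected_rate is not None and rate != expected_rate:
        raise ValidationError(
            f"sample rate {rate} Hz != expected {expected_rate} Hz; resample "
            "the recording or pass expected_rate=None if the backend supports it"
        )
    if data.ndim != 1:
        raise ValidationError(
            f"expected a mono signal, got {data.shape[1]} channels; split the "
            "speakers' channels first"
        )
    if data.dtype.kind == "i":
        signal = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        signal = data.astype(np.float64)
    return signal, float(rate)


def _in_intervals(times: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    """Membership of each time in a union of half-open intervals."""
    if not intervals:
        return np.zeros(len(times), dtype=bool)
    starts = np.array([a for a, _ in intervals])
    ends = np.array([b for _, b in intervals])
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    idx = np.searchsorted(starts, times, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(times), dtype=bool)
    out[ok] = times[ok] < ends[idx[ok]]
    return out


def restrict_to_speech(
    track: FrameTrack,
    timeline: SessionTimeline,
    speaker_id: str,
    exclude_overlap: bool = True,
) -> FrameTrack:
    """Keep frames whose centre lies in the speaker's own IPUs.

    With ``exclude_overlap`` (the default), frames inside any other-speaker
    IPU are dropped as well, so overlapping speech never contributes to a
    speaker's prosodic statistics.
    """
    times = track.times
    own = [(u.start_s, u.end_s) for u in timeline.speaker_ipus(speaker_id)]
    keep = track.valid & _in_intervals(times, own)
    if exclude_overlap:
        other = [
            (u.start_s, u.end_s)
            for u in timeline.ipus
            if u.speaker_id != speaker_id
        ]
        keep &= ~_in_intervals(times, other)
    return replace(track, valid=keep)


def write_frame_track_csv(tracks: dict[str, FrameTrack], sink) -> None:
    """Write per-speaker frame tracks as ``speaker,t_s,value,valid`` CSV."""
    frames = []
    for speaker, track in tracks.items():
        frames.append(
            pd.DataFrame(
                {
                    "speaker": speaker,
                    "t_s": track.times,
                    "value": track.values,
                    "valid": track.valid.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(sink, index=False)


def read_frame_track_csv(source) -> dict[str, FrameTrack]:
    """Read tracks written by :func:`write_frame_track_csv`.

    The frame shift is inferred from the time column, which must be an even
    grid per speaker.
    """
    df = pd.read_csv(source)
    for col in ("speaker", "t_s", "value", "valid"):
        if col not in df.columns:
            raise ParseError(f"frame-track CSV missing column {col!r}")
    out: dict[str, FrameTrack] = {}
    for speaker, sub in df.groupby("speaker", sort=False):
        t = sub["t_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ParseError(f"speaker {speaker!r}: need at least two frames")
        shifts = np.diff(t)
        shift = float(np.median(shifts))
        if not np.allclose(shifts, shift, atol=1e-6):
            raise ParseError(f"speaker {speaker!r}: frame times are not an even grid")
        values = sub["value"].to_numpy(dtype=float)
        valid = sub["valid"].to_numpy().astype(bool) & np.isfinite(values)
        out[str(speaker)] = FrameTrack(shift, float(t[0]), values, valid)
    return out
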