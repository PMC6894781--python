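"""Synthetic dyadic interview sessions and cohorts with known ground truth.

The generator emulates a semi-structured question/answer interview:
alternating administrator questions and participant answers, response
latencies drawn from a shifted lognormal (allowing negative gaps, i.e.
answers that begin before the question ends), multi-IPU answers with
within-turn pauses, and short backchannels inserted fully inside the
other speaker's utterances.  Prosody is generated at the block (8 s)
scale: a shared AR(1) latent drives the administrator's block values, and
the participant's block values follow ``rho * z + sqrt(1 - rho^2) * eps``
so the expected blockwise correlation between the speakers equals the
configured coupling ``rho``; frame values add white noise on top.

Everything is drawn from a single seeded generator, so a given seed
reproduces a session byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import BlockConfig, assemble_features
from .prosody import FrameConfig, FrameTrack
from .session import (
    ADMINISTRATOR,
    FEATURE_ORDER,
    PARTICIPANT,
    CohortTable,
    IpuSegment,
    SessionTimeline,
)
from .turns import TurnConfig


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal(mu, sigma) with an optional additive shift and floor."""

    mu: float
    sigma: float
    shift: float = 0.0
    min_value: float | None = None

    def sample(self, rng: np.random.Generator, size=None):
        x = self.shift + rng.lognormal(self.mu, self.sigma, size)
        if self.min_value is not None:
            x = np.maximum(x, self.min_value)
        return x

    @classmethod
    def from_mean_sd(cls, mean: float, sd: float, shift: float = 0.0,
                     min_value: float | None = None) -> "LognormalSpec":
        """Spec whose unshifted part has the given mean and SD."""
        m = mean - shift
        if m <= 0:
            raise ValidationError("mean must exceed shift")
        sigma2 = math.log(1.0 + (sd / m) ** 2)
        return cls(math.log(m) - sigma2 / 2, math.sqrt(sigma2), shift, min_value)


@dataclass(frozen=True)
class SpeakerProsody:
    """Block-scale moments of one speaker's prosody."""

    log_f0_mean: float = 4.8
    log_f0_block_sd: float = 0.088
    intensity_mean: float = 60.0
    intensity_block_sd: float = 3.5


@dataclass(frozen=True)
class DyadSimConfig:
    """Parameters of one simulated interview session.

    Defaults describe a typically developing adult male participant in a
    ~8 minute structured interview: ~2 s questions, response gaps that are
    negative about 60% of the time, 1.5 s answers, sparse within-turn
    pauses, and moderate intensity synchrony (rho ~ 0.34).
    """

    seed: int = 0
    session_duration_s: float = 480.0
    admin_utterance_dur: LognormalSpec = LognormalSpec.from_mean_sd(2.0, 0.7, min_value=0.8)
    gap_dist: LognormalSpec = LognormalSpec(0.0, 0.5, shift=-1.2)
    participant_ipu_dur: LognormalSpec = LognormalSpec.from_mean_sd(1.5, 1.2, min_value=0.25)
    extra_ipu_rate: float = 0.2              # Poisson mean of extra IPUs per answer
    within_turn_pause: LognormalSpec = LognormalSpec.from_mean_sd(0.45, 0.25, min_value=0.25)
    admin_latency: LognormalSpec = LognormalSpec.from_mean_sd(0.5, 0.2, min_value=0.25)
    backchannel_rate_per_min: float = 2.0
    backchannel_dur_range: tuple[float, float] = (0.15, 0.40)
    prosody_coupling: float = 0.34           # rho, expected blockwise correlation
    participant_prosody: SpeakerProsody = SpeakerProsody()
    admin_prosody: SpeakerProsody = SpeakerProsody(
        log_f0_mean=4.7, log_f0_block_sd=0.08, intensity_mean=62.0, intensity_block_sd=3.0
    )
    block_latent_ar1: float = 0.4            # phi of the AR(1) block latent
    block_hop_s: float = 8.0                 # latent piece length; matches the TAMA hop
    frame_noise_sd_f0: float = 0.18
    frame_noise_sd_intensity: float = 5.0
    voicing_prob: float = 0.7
    mora_rate: float = 8.8
    admin_mora_rate: float = 8.0
    frame_shift_s: float = 0.010
    first_ipu_min_s: float = 0.6             # answers must claim the floor (> turn threshold)

    def __post_init__(self):
        if self.session_duration_s < 60:
            raise ValidationError("session must be at least 60 s")
        if abs(self.prosody_coupling) > 1:
            raise ValidationError("|rho| must be <= 1")
        if abs(self.block_latent_ar1) >= 1:
            raise ValidationError("|phi| must be < 1")
        if not 0 < self.voicing_prob <= 1:
            raise ValidationError("voicing_prob must lie in (0, 1]")
        lo, hi = self.backchannel_dur_range
        if not 0 < lo < hi < 0.5:
            raise ValidationError("backchannels must be shorter than 0.5 s")
        if self.admin_utterance_dur.sample(np.random.default_rng(0)) > self.session_duration_s:
            raise ValidationError("utterance durations exceed the session length")


@dataclass
class GroundTruth:
    """What the generator actually drew, for parameter-recovery checks."""

    rho: float
    gaps: list[float] = field(default_factory=list)
    pause_s: float = 0.0
    turn_s: float = 0.0
    f0_block_values: dict[str, np.ndarray] = field(default_factory=dict)
    intensity_block_values: dict[str, np.ndarray] = field(default_factory=dict)
    n_backchannels: int = 0

    @property
    def gap_mean(self) -> float:
        return float(np.mean(self.gaps)) if self.gaps else math.nan

    @property
    def gap_sd(self) -> float:
        return float(np.std(self.gaps)) if self.gaps else math.nan

    @property
    def frac_negative_gap(self) -> float:
        return float(np.mean(np.array(self.gaps) < 0)) if self.gaps else math.nan

    @property
    def pause_to_turn_ratio(self) -> float:
        return self.pause_s / self.turn_s if self.turn_s > 0 else math.nan


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) with unit marginal variance."""
    z = np.empty(n)
    z[0] = rng.normal()
    innov_sd = math.sqrt(1 - phi**2)
    for j in range(1, n):
        z[j] = phi * z[j - 1] + innov_sd * rng.normal()
    return z


def _mora(duration: float, rate: float) -> int:
    return max(int(round(rate * duration)), 1)


def _min_distance_ok(start: float, end: float, ipus: list[IpuSegment], margin: float) -> bool:
    return all(end + margin <= u.start_s or start - margin >= u.end_s for u in ipus)


def simulate_session(
    cfg: DyadSimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SessionTimeline, dict[str, dict[str, FrameTrack]], GroundTruth]:
    """Generate one session: timeline, frame tracks, and ground truth.

    Returns the IPU timeline of both speakers, per-speaker ``f0`` (natural
    log) and ``intensity`` (dB) frame tracks covering the whole session
    (restriction to speech happens in the analysis pipeline), and the
    generator's bookkeeping.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    duration = cfg.session_duration_s
    truth = GroundTruth(rho=cfg.prosody_coupling)

    admin: list[IpuSegment] = []
    part: list[IpuSegment] = []
    t = rng.uniform(0.3, 0.8)
    while True:
        q_dur = float(cfg.admin_utterance_dur.sample(rng))
        q_start, q_end = t, t + q_dur
        if q_end + 2.5 > duration:
            break
        gap = float(cfg.gap_dist.sample(rng))
        gap = max(gap, -0.8 * q_dur)
        p_start = q_end + gap
        first_dur = max(float(cfg.participant_ipu_dur.sample(rng)), cfg.first_ipu_min_s)
        if p_start + first_dur < q_end + 0.2:  # answer must outlast the question
            first_dur = q_end + 0.2 - p_start
        chain = [(p_start, p_start + first_dur)]
        pauses: list[float] = []
        for _ in range(rng.poisson(cfg.extra_ipu_rate)):
            pause = float(cfg.within_turn_pause.sample(rng))
            dur = float(cfg.participant_ipu_dur.sample(rng))
            prev_end = chain[-1][1]
            chain.append((prev_end + pause, prev_end + pause + dur))
            pauses.append(pause)
        answer_end = chain[-1][1]
        if answer_end > duration - 0.5:
            break
        # commit the cycle
        admin.append(
            IpuSegment(ADMINISTRATOR, q_start, q_end,
                       _mora(q_dur, cfg.admin_mora_rate))
        )
        for s, e in chain:
            part.append(IpuSegment(PARTICIPANT, s, e, _mora(e - s, cfg.mora_rate)))
        truth.gaps.append(gap)
        truth.turn_s += answer_end - p_start  # the participant's turn span
        truth.pause_s += sum(pauses)
        t = answer_end + max(float(cfg.admin_latency.sample(rng)), 0.25)

    if not truth.gaps:
        raise ValidationError("session too short for a single question/answer cycle")

    # backchannels: fully inside the other speaker's IPU, clear of own speech
    bc_lo, bc_hi = cfg.backchannel_dur_range
    n_bc = rng.poisson(cfg.backchannel_rate_per_min * duration / 60.0)
    for _ in range(n_bc):
        into_admin = rng.random() < 0.5
        hosts = [u for u in (admin if into_admin else part) if u.duration_s >= 1.2]
        if not hosts:
            continue
        host = hosts[rng.integers(len(hosts))]
        bc_dur = rng.uniform(bc_lo, bc_hi)
        lo = host.start_s + 0.1
        hi = host.end_s - 0.1 - bc_dur
        if hi <= lo:
            continue
        start = rng.uniform(lo, hi)
        own = part if into_admin else admin
        if not _min_distance_ok(start, start + bc_dur, own, 0.25):
            continue
        speaker = PARTICIPANT if into_admin else ADMINISTRATOR
        rate = cfg.mora_rate if into_admin else cfg.admin_mora_rate
        own.append(
            IpuSegment(speaker, start, start + bc_dur, _mora(bc_dur, rate),
                       label="backchannel")
        )
        truth.n_backchannels += 1

    timeline = SessionTimeline("sim", tuple(admin + part), duration)

    # block-scale prosody latents, piecewise constant over hop-length pieces
    n_seg = int(math.ceil(duration / cfg.block_hop_s))
    rho = cfg.prosody_coupling
    mix = math.sqrt(1 - rho**2)
    shift = cfg.frame_shift_s
    n_frames = int(round(duration / shift))
    seg_of_frame = np.minimum(
        ((np.arange(n_frames) + 0.5) * shift / cfg.block_hop_s).astype(int), n_seg - 1
    )
    tracks: dict[str, dict[str, FrameTrack]] = {PARTICIPANT: {}, ADMINISTRATOR: {}}
    for kind, noise_sd, mean_attr, sd_attr, store in (
        ("f0", cfg.frame_noise_sd_f0, "log_f0_mean", "log_f0_block_sd",
         truth.f0_block_values),
        ("intensity", cfg.frame_noise_sd_intensity, "intensity_mean",
         "intensity_block_sd", truth.intensity_block_values),
    ):
        z = _ar1(n_seg, cfg.block_latent_ar1, rng)
        eps = _ar1(n_seg, cfg.block_latent_ar1, rng)
        a_pros = cfg.admin_prosody
        p_pros = cfg.participant_prosody
        seg_admin = getattr(a_pros, mean_attr) + getattr(a_pros, sd_attr) * z
        seg_part = getattr(p_pros, mean_attr) + getattr(p_pros, sd_attr) * (
            rho * z + mix * eps
        )
        store[ADMINISTRATOR] = seg_admin
        store[PARTICIPANT] = seg_part
        for speaker, seg in ((ADMINISTRATOR, seg_admin), (PARTICIPANT, seg_part)):
            values = seg[seg_of_frame] + rng.normal(0, noise_sd, n_frames)
            if kind == "f0" and cfg.voicing_prob < 1:
                valid = rng.random(n_frames) < cfg.voicing_prob
            else:
                valid = np.ones(n_frames, dtype=bool)
            tracks[speaker][kind] = FrameTrack(shift, shift / 2, values, valid)
    return timeline, tracks, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: ASD-minus-TD shifts of the group-level generator parameters, in the
#: directions of the reported group contrasts: longer and more variable
#: response gaps, more and longer within-turn pauses, weaker intensity
#: synchrony, flatter blockwise intensity, and a wider across-participant
#: spread of the blockwise log-F0 SD.
DEFAULT_EFFECTS: dict[str, float] = {
    "gap_mu": 0.35,
    "gap_sigma": 0.2,
    "extra_ipu_rate": 0.2,
    "pause_mean": 0.15,
    "rho": -0.16,
    "sd_block_intensity": -0.9,
    "sd_block_log_f0_spread": 0.019,
}

#: Across-participant SDs of the person-level parameter draws.
_PERSON_SD = {
    "gap_mu": 0.30,
    "rho": 0.18,
    "sd_block_intensity": 0.75,
    "log_f0_mean": 0.15,
    "mora_rate": 0.55,
    "ipu_mu": 0.22,
}


def _participant_config(
    base: DyadSimConfig,
    group: str,
    effects: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[DyadSimConfig, dict[str, float]]:
    """Draw one participant's session config around the group parameters."""
    e = (lambda k: effects.get(k, 0.0)) if group == "ASD" else (lambda k: 0.0)

    gap_mu = rng.normal(base.gap_dist.mu + e("gap_mu"), _PERSON_SD["gap_mu"])
    gap = replace(base.gap_dist, mu=gap_mu, sigma=base.gap_dist.sigma + e("gap_sigma"))
    pause_mean = 0.45 + e("pause_mean")
    # floored so every participant pauses occasionally: a zero pause-to-turn
    # ratio would leave the cohort-level log transform undefined
    ipu_rate = max(rng.normal(base.extra_ipu_rate + e("extra_ipu_rate"), 0.12), 0.04)
    rho = float(np.clip(rng.normal(base.prosody_coupling + e("rho"),
                                   _PERSON_SD["rho"]), -0.85, 0.92))
    sd_int = max(rng.normal(
        base.participant_prosody.intensity_block_sd + e("sd_block_intensity"),
        _PERSON_SD["sd_block_intensity"]), 0.8)
    sd_f0 = max(rng.normal(
        base.participant_prosody.log_f0_block_sd,
        0.023 + e("sd_block_log_f0_spread")), 0.025)
    log_f0 = rng.normal(base.participant_prosody.log_f0_mean, _PERSON_SD["log_f0_mean"])
    mora = max(rng.normal(base.mora_rate, _PERSON_SD["mora_rate"]), 6.0)
    ipu_mu = rng.normal(base.participant_ipu_dur.mu, _PERSON_SD["ipu_mu"])

    cfg = replace(
        base,
        gap_dist=gap,
        extra_ipu_rate=ipu_rate,
        within_turn_pause=LognormalSpec.from_mean_sd(pause_mean, pause_mean / 2,
                                                     min_value=0.25),
        prosody_coupling=rho,
        participant_prosody=replace(
            base.participant_prosody,
            log_f0_mean=log_f0, log_f0_block_sd=sd_f0, intensity_block_sd=sd_int,
        ),
        mora_rate=mora,
        participant_ipu_dur=replace(base.participant_ipu_dur, mu=ipu_mu),
    )
    latent = {
        "z_gap": (gap_mu - base.gap_dist.mu) / _PERSON_SD["gap_mu"],
        "z_pause": (ipu_rate - base.extra_ipu_rate) / 0.12,
        "z_rho": (rho - base.prosody_coupling) / _PERSON_SD["rho"],
    }
    return cfg, latent


def _scores(group: str, latent: dict[str, float], rng: np.random.Generator) -> dict[str, int]:
    """Symptom scores loosely driven by the turn-taking/synchrony latents."""
    if group == "ASD":
        recip = 8.9 + 1.1 * latent["z_gap"] + 0.9 * latent["z_pause"] \
            - 0.6 * latent["z_rho"] + rng.normal(0, 1.4)
        comm = 4.2 + 0.5 * latent["z_gap"] + rng.normal(0, 1.2)
        rep = 2.0 + rng.normal(0, 1.2)
        return {
            "reciprocity": int(np.clip(round(recip), 1, 14)),
            "communication": int(np.clip(round(comm), 0, 8)),
            "repetitive": int(np.clip(round(rep), 0, 8)),
        }
    return {
        "reciprocity": int(np.clip(round(1.5 + 0.5 * latent["z_gap"]
                                         + rng.normal(0, 0.9)), 0, 5)),
        "communication": int(np.clip(round(1.0 + rng.normal(0, 0.8)), 0, 4)),
        "repetitive": int(np.clip(round(0.5 + rng.normal(0, 0.6)), 0, 3)),
    }


def simulate_cohort(
    n_asd: int = 62,
    n_td: int = 17,
    effects: Mapping[str, float] | None = None,
    seed: int = 0,
    base: DyadSimConfig | None = None,
    block_cfg: BlockConfig = BlockConfig(),
    turn_cfg: TurnConfig = TurnConfig(),
) -> tuple[CohortTable, list[GroundTruth]]:
    """Simulate a cohort and push every session through the real pipeline.

    Per-participant session configs are drawn around group-level
    parameters; ``effects`` gives the ASD-minus-TD shifts
    (:data:`DEFAULT_EFFECTS` by default; pass ``{}`` for a null cohort in
    which both groups share one distribution).  Features are computed with
    :func:`dyadspeech.features.assemble_features`, so the cohort exercises
    the entire measurement pipeline, and the generator's ground truth is
    returned alongside.
    """
    if n_asd < 2 or n_td < 2:
        raise ValidationError("need at least 2 participants per group")
    if effects is None:
        effects = DEFAULT_EFFECTS
    if base is None:
        base = DyadSimConfig()
    rng = np.random.default_rng(seed)
    rows = []
    truths: list[GroundTruth] = []
    for i in range(n_asd + n_td):
        group = "ASD" if i < n_asd else "TD"
        cfg, latent = _participant_config(base, group, effects, rng)
        timeline, tracks, truth = simulate_session(cfg, rng)
        vec = assemble_features(
            timeline,
            tracks[PARTICIPANT]["f0"], tracks[PARTICIPANT]["intensity"],
            tracks[ADMINISTRATOR]["f0"], tracks[ADMINISTRATOR]["intensity"],
            block_cfg, turn_cfg,
        )
        row = {"participant_id": f"{group}{i:03d}", "group": group}
        row.update(_scores(group, latent, rng))
        row.update(vec.as_dict())
        rows.append(row)
        truths.append(truth)
    cohort = CohortTable(pd.DataFrame(rows))
    return cohort, truths


# Feature-level moments used by `simulate_feature_cohort`; loosely matched
# to the observed TD marginals so null calibration runs at realistic scale.
_FEATURE_MARGINALS: dict[str, tuple[str, float, float]] = {
    "mean_log_f0": ("normal", 4.75, 0.15),
    "sd_log_f0": ("normal", 0.20, 0.05),
    "sd_block_log_f0": ("normal", 0.088, 0.025),
    "corr_block_log_f0": ("normal", 0.20, 0.25),
    "sd_intensity": ("normal", 5.8, 0.65),
    "sd_block_intensity": ("normal", 3.2, 0.85),
    "corr_block_intensity": ("normal", 0.30, 0.22),
    "speech_rate": ("normal", 8.8, 0.60),
    "mean_speaking_time_s": ("normal", 1.5, 0.45),
    "sd_speaking_time_s": ("normal", 1.3, 0.45),
    "mean_turn_gap_s": ("shifted_lognormal", 0.1, 0.4),
    "sd_turn_gap_s": ("lognormal", math.log(0.7), 0.4),
    "pause_to_turn_ratio": ("lognormal", math.log(0.04), 0.8),
}


def simulate_feature_cohort(
    n_asd: int = 62,
    n_td: int = 17,
    shifts: Mapping[str, float] | None = None,
    seed: int = 0,
) -> CohortTable:
    """Draw feature vectors directly, without session-level simulation.

    A fast synthetic stand-in for statistical calibration studies that
    need hundreds of cohorts: both groups share one joint distribution
    unless per-feature ASD shifts are given.  No timelines or tracks are
    produced; use :func:`simulate_cohort` to exercise the pipeline itself.
    """
    rng = np.random.default_rng(seed)
    shifts = dict(shifts or {})
    rows = []
    for i in range(n_asd + n_td):
        group = "ASD" if i < n_asd else "TD"
        row: dict[str, object] = {"participant_id": f"{group}{i:03d}", "group": group}
        for feature, (kind, a, b) in _FEATURE_MARGINALS.items():
            delta = shifts.get(feature, 0.0) if group == "ASD" else 0.0
            if kind == "normal":
                value = rng.normal(a, b)
            elif kind == "lognormal":
                value = rng.lognormal(a, b)
            else:  # shifted lognormal with support down to -1.2 s
                value = -1.2 + rng.lognormal(a, b)
            row[feature] = value + delta
        row["sd_turn_gap_s"] = max(float(row["sd_turn_gap_s"]), 1e-3)
        row["pause_to_turn_ratio"] = max(float(row["pause_to_turn_ratio"]), 1e-4)
        row.update(
            {
                "reciprocity": int(rng.integers(0, 15)),
                "communication": int(rng.integers(0, 9)),
                "repetitive": int(rng.integers(0, 9)),
            }
        )
        rows.append(row)
    return CohortTable(pd.DataFrame(rows))
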