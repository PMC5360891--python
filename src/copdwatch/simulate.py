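"""Synthetic telemonitoring cohorts and modulated PPG waveforms.

The trial data behind this method are not publicly deposited, so this
module generates cohorts with the same statistical structure and a known
ground truth:

* each patient alternates latent stable stretches and exacerbation
  episodes (onsets from a Poisson process with a dead time equal to the
  episode length; lengths log-normal with a configurable mean);
* diary sessions occur on roughly ``sessions_per_week_mean / 7`` of days,
  at a uniformly random daytime hour (patients record at a time of their
  choosing);
* diary answers and medication flags are generated so that running the
  finite-state machine over the sessions enters the EXACERBATION state at
  the latent onsets: symptoms worsen and an antibiotics/steroids course
  starts at the first session of each episode, symptoms improve at the
  first session after it ends, and benign transitional "blips" (symptom
  worsening without medication) occur at a low rate in stable stretches
  and at an elevated rate during the 7-day prodrome;
* vitals are class-conditional gaussians: around the stable means outside
  episodes, and drifting linearly through the prodromal means (centred at
  the prodrome midpoint, slope ``prodromal_trend``) during the 7 days
  before each onset.

PPG segments are a pulse train of raised-cosine-like (gaussian) bumps with
sinusoidal amplitude modulation at the respiratory frequency, optional
period (frequency) modulation emulating respiratory sinus arrhythmia, and
additive white noise.  Only the modulation structure matters for the
respiratory-rate estimator; physiological pulse morphology is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

from .fsm import DiarySession, SYMPTOM_KEYS
from .ppg import PPGSegment

__all__ = [
    "CohortConfig",
    "PPGConfig",
    "CohortData",
    "generate_ppg",
    "generate_cohort",
    "EPOCH",
]

EPOCH = datetime(2015, 1, 1)

VITAL_NAMES = ("spo2", "pulse_rate", "resp_rate")


class ConfigError(ValueError):
    """A generator configuration field violates its invariant."""


@dataclass
class PPGConfig:
    """Configuration for one synthetic PPG segment."""

    fs_hz: float = 100.0
    duration_s: float = 30.0
    hr_bpm: float = 75.0
    rr_brpm: float = 18.0
    am_depth: float = 0.2
    fm_depth: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.rr_brpm < self.hr_bpm:
            raise ConfigError(
                f"rr_brpm must satisfy 0 < rr_brpm < hr_bpm; got rr_brpm={self.rr_brpm}, "
                f"hr_bpm={self.hr_bpm}"
            )
        if self.fs_hz <= 2 * self.hr_bpm / 60.0:
            raise ConfigError(f"fs_hz={self.fs_hz} must exceed twice the cardiac frequency")
        if self.duration_s <= 2 * 60.0 / self.rr_brpm:
            raise ConfigError(
                f"duration_s={self.duration_s} must exceed two respiratory cycles"
            )
        if not 0 <= self.am_depth < 1:
            raise ConfigError(f"am_depth must be in [0, 1), got {self.am_depth}")
        if not 0 <= self.fm_depth < 1:
            raise ConfigError(f"fm_depth must be in [0, 1), got {self.fm_depth}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be non-negative, got {self.noise_sd}")


def generate_ppg(config: PPGConfig) -> PPGSegment:
    """Synthesise one amplitude/frequency-modulated PPG segment.

    signal = (1 + am_depth * sin(2 pi f_r t)) * pulse_train + noise, where
    the pulse train is a sequence of gaussian bumps whose inter-beat
    period is sinusoidally modulated at the respiratory frequency with
    fractional depth ``fm_depth``.  Ground-truth rates are recorded on the
    returned segment.  Deterministic given the config (seeded noise).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = round(config.fs_hz * config.duration_s)
    t = np.arange(n) / config.fs_hz
    f_r = config.rr_brpm / 60.0
    period0 = 60.0 / config.hr_bpm

    beats = []
    tb = 0.0
    while tb < config.duration_s + period0:
        beats.append(tb)
        tb += period0 * (1.0 + config.fm_depth * math.sin(2.0 * math.pi * f_r * tb))

    sigma = 0.12 * period0
    x = np.zeros(n)
    half = int(math.ceil(4 * sigma * config.fs_hz))
    for b in beats:
        c = int(round(b * config.fs_hz))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo < hi:
            x[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - b) / sigma) ** 2)

    x *= 1.0 + config.am_depth * np.sin(2.0 * np.pi * f_r * t)
    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, n)
    return PPGSegment(
        samples=x, fs_hz=config.fs_hz, rr_true_brpm=config.rr_brpm, hr_true_bpm=config.hr_bpm
    )


@dataclass
class CohortConfig:
    """Study-scale cohort parameters.

    Defaults follow the monitored population: ~5.3 sessions/week over 12
    months, ~3.6 exacerbation episodes per patient-year with a mean length
    of 8.8 days, stable vitals (SpO2 94%, PR 80 bpm, RR 22 brpm) and
    prodromal vitals (93, 83, 24).  ``prodromal_trend`` (units/day per
    vital) defaults to the per-day gradient that carries a vital from its
    stable mean to its prodromal mean across the 7-day prodrome.  Within-
    class SDs are not reported for the source population; the defaults
    (2%, 8 bpm, 3 brpm) produce heavily overlapping class distributions.
    """

    n_patients: int = 100
    duration_days: int = 365
    sessions_per_week_mean: float = 5.3
    exacerbation_rate: float = 3.6  # events / patient / year
    exacerbation_length_mean: float = 8.8  # days
    exacerbation_length_min: float = 1.0  # observed events last at least a day
    exacerbation_length_sigma: float = 1.38  # log-normal shape (median ~4 d at mean 8.8)
    stable_vitals_mean: tuple[float, float, float] = (94.0, 80.0, 22.0)
    prodromal_vitals_mean: tuple[float, float, float] = (93.0, 83.0, 24.0)
    vitals_sd: tuple[float, float, float] = (2.0, 8.0, 3.0)
    prodromal_trend: Optional[tuple[float, float, float]] = None
    prodrome_days: float = 7.0
    p_worse_prodrome: float = 0.3  # per-session prob of a symptom-worsening answer pre-onset
    p_blip: float = 0.03  # per-session prob of starting a benign transitional blip
    blip_length_days: float = 2.5
    hcp_contact_rate: float = 0.0  # the trial had no HCP-contact channel
    seed: int = 0

    def validate(self) -> None:
        pos = {
            "n_patients": self.n_patients,
            "duration_days": self.duration_days,
            "sessions_per_week_mean": self.sessions_per_week_mean,
            "exacerbation_length_mean": self.exacerbation_length_mean,
            "exacerbation_length_sigma": self.exacerbation_length_sigma,
            "prodrome_days": self.prodrome_days,
        }
        for name, v in pos.items():
            if v <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {v}")
        if not 0 <= self.exacerbation_length_min < self.exacerbation_length_mean:
            raise ConfigError(
                "exacerbation_length_min must be non-negative and below the mean length"
            )
        if self.exacerbation_rate < 0:
            raise ConfigError(f"exacerbation_rate must be >= 0, got {self.exacerbation_rate}")
        s_spo2, s_pr, s_rr = self.stable_vitals_mean
        p_spo2, p_pr, p_rr = self.prodromal_vitals_mean
        for label, v in (("stable", s_spo2), ("prodromal", p_spo2)):
            if not 50.0 < v <= 100.0:
                raise ConfigError(f"{label} SpO2 mean must be in (50, 100], got {v}")
        if p_spo2 > s_spo2:
            raise ConfigError("prodromal SpO2 mean must not exceed the stable mean")
        if p_pr < s_pr or p_rr < s_rr:
            raise ConfigError("prodromal PR and RR means must be >= the stable means")
        if any(sd <= 0 for sd in self.vitals_sd):
            raise ConfigError(f"vitals_sd must be strictly positive, got {self.vitals_sd}")
        for name, p in (("p_worse_prodrome", self.p_worse_prodrome), ("p_blip", self.p_blip)):
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")

    def trend(self) -> np.ndarray:
        if self.prodromal_trend is not None:
            return np.asarray(self.prodromal_trend, dtype=float)
        return (
            np.asarray(self.prodromal_vitals_mean) - np.asarray(self.stable_vitals_mean)
        ) / self.prodrome_days


@dataclass
class CohortData:
    """Generated cohort: sessions plus latent ground truth.

    Session times are re-origined so each patient's first session is at
    t = 0 (matching what a reader reconstructs from timestamps); latent
    episode times use the same origin.  ``rr_truth`` maps
    (patient_id, t) to the session's latent respiratory rate — the value a
    perfect waveform analysis would recover.
    """

    config: CohortConfig
    sessions: dict[str, list[DiarySession]]
    episodes: dict[str, list[tuple[float, float]]]
    rr_truth: dict[tuple[str, float], float] = field(default_factory=dict)


def _draw_episodes(
    rng: np.random.Generator, config: CohortConfig
) -> list[tuple[float, float]]:
    """Non-overlapping (onset, end) episode intervals over the study."""
    lam = config.exacerbation_rate / 365.0  # onsets per day
    if lam <= 0:
        return []
    # shifted log-normal: episodes last at least exacerbation_length_min days
    # (an observed event spans at least one day by definition), with the
    # configured overall mean
    excess = config.exacerbation_length_mean - config.exacerbation_length_min
    mu = math.log(excess) - 0.5 * config.exacerbation_length_sigma**2
    episodes = []
    t = rng.exponential(1.0 / lam)
    while t < config.duration_days:
        length = config.exacerbation_length_min + float(
            rng.lognormal(mu, config.exacerbation_length_sigma)
        )
        episodes.append((t, min(t + length, float(config.duration_days))))
        t = t + length + rng.exponential(1.0 / lam)
    return episodes


def _session_times(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    p_day = min(1.0, config.sessions_per_week_mean / 7.0)
    days = np.flatnonzero(rng.random(config.duration_days) < p_day)
    hours = rng.uniform(8.0, 20.0, size=days.size)
    t = days + hours / 24.0
    return np.round(t * 86400.0) / 86400.0  # whole-second resolution


def _answers(worse: Sequence[str] = (), improved: Sequence[str] = ()) -> dict[str, str]:
    a = {k: "no_change" for k in SYMPTOM_KEYS}
    for k in worse:
        a[k] = "worse"
    for k in improved:
        a[k] = "improved"
    return a


def _generate_patient(
    pid: str, rng: np.random.Generator, config: CohortConfig
) -> tuple[list[DiarySession], list[tuple[float, float]], dict[tuple[str, float], float]]:
    episodes = _draw_episodes(rng, config)
    times = _session_times(rng, config)
    stable_mean = np.asarray(config.stable_vitals_mean, dtype=float)
    prod_mean = np.asarray(config.prodromal_vitals_mean, dtype=float)
    sd = np.asarray(config.vitals_sd, dtype=float)
    trend = config.trend()

    def episode_at(tau: float) -> Optional[tuple[float, float]]:
        for on, off in episodes:
            if on <= tau < off:
                return (on, off)
        return None

    def prodrome_onset(tau: float) -> Optional[float]:
        for on, _ in episodes:
            if on - config.prodrome_days <= tau < on:
                return on
        return None

    sessions: list[DiarySession] = []
    rr_truth: dict[tuple[str, float], float] = {}
    handled_onsets: set[float] = set()
    pending_recovery = False  # improvement due at the first post-episode session
    blip_until = -math.inf
    blip_recovery = False

    for tau in times:
        ep = episode_at(tau)
        onset = prodrome_onset(tau)

        # --- latent vital means -------------------------------------------
        if ep is not None:
            level = prod_mean + trend * (config.prodrome_days / 2.0)
        elif onset is not None:
            level = prod_mean + trend * (tau - onset + config.prodrome_days / 2.0)
        else:
            level = stable_mean
        vitals = level + rng.normal(0.0, sd)
        spo2 = float(min(vitals[0], 100.0))
        pr = float(np.clip(vitals[1], 30.0, 200.0))
        rr = float(np.clip(vitals[2], 5.0, 60.0))

        # --- diary answers and medication flags ---------------------------
        worse: list[str] = []
        improved: list[str] = []
        antibiotics = steroids = reliever = False

        if ep is not None:
            on, _ = ep
            if on not in handled_onsets:
                handled_onsets.add(on)
                worse = ["breathlessness", "chest_tightness"]
                if rng.random() < 0.3:
                    worse.append("run_down")
            else:
                # symptoms never read as improving mid-episode: breathlessness
                # stays "worse" throughout (a lone persisting answer defeats
                # the two-symptom improvement rule at the next session too)
                worse = ["breathlessness"]
                if rng.random() < 0.6:
                    worse.append("sputum_volume")
            # drug course flags are made consistent per episode afterwards so
            # the rising edge fires exactly once, at the onset session
            antibiotics = True
            reliever = True
            pending_recovery = True
            blip_until, blip_recovery = -math.inf, False
        elif pending_recovery:
            improved = ["breathlessness", "chest_tightness", "sputum_volume"]
            pending_recovery = False
        elif onset is not None:
            # prodrome: elevated chance of symptom worsening without meds
            if rng.random() < config.p_worse_prodrome:
                worse = ["breathlessness", "run_down"]
            blip_until, blip_recovery = -math.inf, False
        else:
            if blip_recovery and tau > blip_until:
                improved = ["breathlessness", "run_down"]
                blip_recovery = False
            elif tau <= blip_until:
                worse = ["breathlessness"]  # mid-blip: complaint persists
            elif rng.random() < config.p_blip:
                worse = ["breathlessness", "run_down"]
                blip_until = tau + config.blip_length_days
                blip_recovery = True
            elif rng.random() < 0.10:
                # an isolated single-symptom complaint; never "significant"
                worse = [str(rng.choice(SYMPTOM_KEYS))]

        hcp = bool(rng.random() < config.hcp_contact_rate / 365.0) if config.hcp_contact_rate else False
        ts = EPOCH + timedelta(seconds=round(tau * 86400.0))
        sessions.append(
            DiarySession(
                patient_id=pid,
                t=float(tau),
                symptoms=_answers(worse, improved),
                reliever_increased=reliever,
                antibiotics=antibiotics,
                steroids=steroids,
                hcp_contact=hcp,
                spo2=spo2,
                pulse_rate=pr,
                timestamp=ts.isoformat(),
            )
        )
        rr_truth[(pid, float(tau))] = rr

    # steroids/antibiotics must be consistent within one episode so the
    # rising edge fires exactly once, at the onset session
    _fix_course_drug(sessions, episodes, rng)

    # re-origin times at the first session
    if sessions:
        t0 = sessions[0].t
        if t0 > 0:
            for s in sessions:
                s.t = round((s.t - t0) * 86400.0) / 86400.0
            rr_truth = {(pid, round((t - t0) * 86400.0) / 86400.0): v for (_, t), v in rr_truth.items()}
            episodes = [(on - t0, off - t0) for on, off in episodes]
    return sessions, episodes, rr_truth


def _fix_course_drug(
    sessions: list[DiarySession],
    episodes: list[tuple[float, float]],
    rng: np.random.Generator,
) -> None:
    for on, off in episodes:
        members = [s for s in sessions if on <= s.t < off]
        if not members:
            continue
        use_steroids = bool(rng.random() < 0.3)
        for s in members:
            s.steroids = use_steroids
            s.antibiotics = not use_steroids


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate a seeded synthetic cohort (bit-reproducible per config)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients)
    width = len(str(max(config.n_patients - 1, 1)))
    sessions: dict[str, list[DiarySession]] = {}
    episodes: dict[str, list[tuple[float, float]]] = {}
    rr_truth: dict[tuple[str, float], float] = {}
    for i, child in enumerate(children):
        pid = f"P{i:0{width}d}"
        s, e, rt = _generate_patient(pid, np.random.default_rng(child), config)
        sessions[pid] = s
        episodes[pid] = e
        rr_truth.update(rt)
    return CohortData(config=config, sessions=sessions, episodes=episodes, rr_truth=rr_truth)


def ppg_for_session(
    rr_brpm: float,
    hr_bpm: float,
    *,
    fs_hz: float = 50.0,
    duration_s: float = 30.0,
    am_depth: float = 0.2,
    fm_depth: float = 0.05,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> PPGSegment:
    """Convenience wrapper: the 30-s waveform an oximeter would record for a
    session with the given latent rates."""
    cfg = PPGConfig(
        fs_hz=fs_hz,
        duration_s=duration_s,
        hr_bpm=hr_bpm,
        rr_brpm=rr_brpm,
        am_depth=am_depth,
        fm_depth=fm_depth,
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_ppg(cfg)
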