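"""Synthetic dyads, cohorts and frame stacks with known ground truth.

Real interview recordings behind motion-energy studies are rarely shareable,
so every downstream stage of this package is exercised on simulated data
whose coupling structure is known exactly. The generative model mirrors the
qualitative features of preprocessed motion-energy series from seated
conversations:

* non-negative, burst-like activity over a near-zero baseline, values in
  [0, 100] (percent of the region of interest), 25 frames/s;
* episodic coupling: most of the time the two members move independently,
  but during *synchronization intervals* the second member linearly copies
  the first member's motion at a fixed time lag;
* a cohort of dyads split into two groups (control / patient) whose latent
  coupling strength differs, with questionnaire-style symptom sum scores
  (PHQ9-like 0-27, GAD7-like 0-21) generated from the latent coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_FPS,
    CouplingInterval,
    DyadTimeSeries,
    FrameStack,
    MotionEnergySeries,
    spawn_seeds,
)

__all__ = [
    "DyadConfig",
    "SymptomModel",
    "CohortConfig",
    "generate_burst_series",
    "generate_coupled_dyad",
    "generate_schedule",
    "generate_cohort",
    "generate_frame_stack",
]


@dataclass(frozen=True)
class DyadConfig:
    """Parameters of one member's burst process.

    Defaults give a 10-minute recording (15 000 frames at 25 fps, inside the
    10 000-45 000 frame range typical of anamnestic interviews) with about
    two movement bursts per minute of 10 s each, peaking at 20 % of the ROI.
    """

    length_frames: int = 15_000
    fps: int = DEFAULT_FPS
    burst_rate: float = 2.0            # expected bursts per minute
    burst_duration_frames: int = 250   # 10 s at 25 fps
    burst_amplitude: float = 20.0      # percent of ROI at burst peak
    noise_sd: float = 1.0
    baseline: float = 0.5

    def __post_init__(self) -> None:
        if self.length_frames <= 0:
            raise ValueError("length_frames must be positive")
        if self.fps <= 0 or self.burst_duration_frames <= 0:
            raise ValueError("fps and burst_duration_frames must be positive")
        if self.burst_rate < 0 or self.noise_sd < 0 or self.baseline < 0:
            raise ValueError("rates, noise and baseline must be non-negative")
        if not 0 < self.burst_amplitude <= 100:
            raise ValueError("burst_amplitude must be in (0, 100]")


@dataclass(frozen=True)
class SymptomModel:
    """Linear map from latent coupling to an integer symptom sum score.

    score = intercept + slope * coupling + group_offset[patient] + noise,
    rounded and truncated to the instrument range.
    """

    intercept: float
    slope: float
    noise_sd: float
    group_offset: float = 0.0
    max_score: int = 27


@dataclass(frozen=True)
class CohortConfig:
    """Study-level design: two groups whose mean coupling differs.

    ``coupling_effect`` is the control-minus-patient difference in the mean
    of the latent coupling coefficient beta; symptom scores decrease with
    coupling and carry a patient offset, emulating a depressed in-patient
    versus healthy control contrast.
    """

    n_dyads: int = 30
    group_fractions: tuple[float, float] = (0.5, 0.5)
    coupling_mean: float = 0.9
    coupling_sd: float = 0.25
    coupling_effect: float = 0.45
    interval_rate_per_min: float = 0.8
    interval_duration_frames: int = 500
    max_lag_frames: int = 25
    phq9: SymptomModel = field(default_factory=lambda: SymptomModel(
        intercept=4.0, slope=-4.0, noise_sd=2.0, group_offset=9.0, max_score=27))
    gad7: SymptomModel = field(default_factory=lambda: SymptomModel(
        intercept=3.0, slope=-3.0, noise_sd=2.0, group_offset=7.0, max_score=21))
    dyad: DyadConfig = field(default_factory=DyadConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 4:
            raise ValueError("need at least 4 dyads")
        f0, f1 = self.group_fractions
        if not (0 < f0 < 1 and 0 < f1 < 1 and abs(f0 + f1 - 1) < 1e-9):
            raise ValueError("group_fractions must be in (0,1) and sum to 1")


def _place_non_overlapping(rng: np.random.Generator, length: int, duration: int,
                           n_wanted: int, lo: int = 0, hi: int | None = None) -> list[int]:
    """Place up to ``n_wanted`` non-overlapping length-``duration`` blocks.

    Starts are drawn uniformly over the positions where the block still fits
    into free space within [lo, hi); blocks that no longer fit are dropped
    (hard-core thinning of the Poisson count).
    """
    hi = length if hi is None else hi
    gaps = [(lo, hi)]  # half-open free intervals
    starts: list[int] = []
    for _ in range(n_wanted):
        feasible = [(g0, g1 - duration + 1) for g0, g1 in gaps if g1 - g0 >= duration]
        total = sum(g1 - g0 for g0, g1 in feasible)
        if total == 0:
            break
        pick = int(rng.integers(total))
        for g0, g1 in feasible:
            if pick < g1 - g0:
                start = g0 + pick
                break
            pick -= g1 - g0
        starts.append(start)
        new_gaps = []
        for g0, g1 in gaps:
            if g1 <= start or g0 >= start + duration:
                new_gaps.append((g0, g1))
            else:
                if g0 < start:
                    new_gaps.append((g0, start))
                if start + duration < g1:
                    new_gaps.append((start + duration, g1))
        gaps = new_gaps
    return sorted(starts)


def generate_burst_series(config: DyadConfig,
                          seed: int | np.random.SeedSequence) -> MotionEnergySeries:
    """Simulate one member's motion-energy series.

    The burst count is Poisson with mean ``burst_rate * minutes``; bursts are
    placed uniformly in the remaining free space so they never overlap. Each
    burst is a raised-cosine hump of height ``burst_amplitude``; Gaussian
    noise and the baseline are added and the result is clipped to [0, 100].
    """
    rng = np.random.default_rng(seed)
    L = config.length_frames
    minutes = L / config.fps / 60.0
    values = np.zeros(L)
    n_bursts = rng.poisson(config.burst_rate * minutes)
    starts = _place_non_overlapping(rng, L, config.burst_duration_frames, n_bursts)
    d = config.burst_duration_frames
    hump = config.burst_amplitude * 0.5 * (1 - np.cos(2 * np.pi * (np.arange(d) + 0.5) / d))
    for s in starts:
        values[s:s + d] += hump[: L - s]
    values += config.baseline
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=L)
    np.clip(values, 0.0, 100.0, out=values)
    return MotionEnergySeries(values, fps=config.fps, kind="smoothed")


def generate_coupled_dyad(config: DyadConfig,
                          schedule: list[CouplingInterval],
                          seed: int | np.random.SeedSequence,
                          dyad_id: str = "dyad") -> DyadTimeSeries:
    """Simulate a dyad with episodic lagged linear coupling.

    Outside the scheduled intervals both members are independent burst
    series. Inside an interval the follower's segment is overwritten with
    ``sign * beta * A`` (anti-phase maps through the burst peak level so the
    result stays non-negative) shifted by ``lag_tau`` frames, plus fresh
    noise. The input schedule is returned untouched as the ground truth.
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    seed_a, seed_b, seed_eps = ss.spawn(3)
    L = config.length_frames
    for iv in schedule:
        if iv.end_frame > L or not (0 <= iv.start_frame + iv.lag_tau
                                    and iv.end_frame + iv.lag_tau <= L):
            raise ValueError(f"interval {iv} exceeds series bounds (L={L})")
    a = generate_burst_series(config, seed_a).values
    b = generate_burst_series(config, seed_b).values
    rng = np.random.default_rng(seed_eps)
    peak = config.burst_amplitude + config.baseline
    for iv in schedule:
        src = a[iv.start_frame:iv.end_frame]
        coupled = iv.strength_beta * (src if iv.sign > 0 else peak - src)
        if config.noise_sd > 0:
            coupled = coupled + rng.normal(0.0, config.noise_sd, size=coupled.size)
        b[iv.start_frame + iv.lag_tau: iv.end_frame + iv.lag_tau] = np.clip(coupled, 0.0, 100.0)
    return DyadTimeSeries(a=a, b=b, fps=config.fps, dyad_id=dyad_id, schedule=list(schedule))


def generate_schedule(config: CohortConfig, beta: float,
                      rng: np.random.Generator) -> list[CouplingInterval]:
    """Draw a random non-overlapping synchronization-interval schedule.

    Interval count is Poisson with mean ``interval_rate_per_min * minutes``;
    lags are uniform integers in [-max_lag, +max_lag]. A margin of
    ``max_lag_frames`` keeps every lag-shifted interval inside the series.
    """
    dc = config.dyad
    minutes = dc.length_frames / dc.fps / 60.0
    n = rng.poisson(config.interval_rate_per_min * minutes)
    m = config.max_lag_frames
    starts = _place_non_overlapping(rng, dc.length_frames, config.interval_duration_frames,
                                    n, lo=m, hi=dc.length_frames - m)
    out = []
    for s in starts:
        lag = int(rng.integers(-m, m + 1))
        out.append(CouplingInterval(start_frame=s,
                                    end_frame=s + config.interval_duration_frames,
                                    lag_tau=lag, strength_beta=beta, sign=1))
    return out


def generate_cohort(config: CohortConfig) -> tuple[list[DyadTimeSeries], pd.DataFrame]:
    """Simulate a full cohort: dyad series plus the cohort-table skeleton.

    Returns the list of dyads (each carrying its ground-truth schedule) and
    a DataFrame with columns dyad_id, group, phq9, gad7 and the latent
    coupling coefficient ``coupling_beta``. Group allocation is exact
    (``round(fraction * n)`` controls first), latent coupling is Gaussian
    per group truncated at zero, and symptom scores follow the two
    :class:`SymptomModel` maps.
    """
    n = config.n_dyads
    n_control = int(round(config.group_fractions[0] * n))
    groups = ["control"] * n_control + ["patient"] * (n - n_control)
    children = spawn_seeds(config.seed, n + 1)
    rng = np.random.default_rng(children[-1])

    dyads: list[DyadTimeSeries] = []
    rows = []
    for i, group in enumerate(groups):
        mean = config.coupling_mean - (config.coupling_effect if group == "patient" else 0.0)
        beta = max(0.0, float(rng.normal(mean, config.coupling_sd)))
        schedule = generate_schedule(config, beta, rng)
        dyad = generate_coupled_dyad(config.dyad, schedule, children[i], dyad_id=f"dyad{i:02d}")
        dyads.append(dyad)
        rows.append({
            "dyad_id": dyad.dyad_id,
            "group": group,
            "phq9": _symptom_score(config.phq9, beta, group, rng),
            "gad7": _symptom_score(config.gad7, beta, group, rng),
            "coupling_beta": beta,
        })
    return dyads, pd.DataFrame(rows)


def _symptom_score(model: SymptomModel, beta: float, group: str,
                   rng: np.random.Generator) -> int:
    score = model.intercept + model.slope * beta
    if group == "patient":
        score += model.group_offset
    if model.noise_sd > 0:
        score += rng.normal(0.0, model.noise_sd)
    return int(np.clip(round(score), 0, model.max_score))


def generate_frame_stack(height: int, width: int, n_frames: int,
                         object_size: int = 5, step_px: int = 1,
                         intensity: int = 255,
                         seed: int | np.random.SeedSequence = 0) -> FrameStack:
    """Bright square translating ``step_px`` per frame on a black background.

    The seed only randomizes the start position; the object must stay inside
    the frame for the whole clip, otherwise a ValueError is raised. Serves
    as a fixture with analytically known changed-pixel counts.
    """
    travel = step_px * (n_frames - 1)
    if object_size + travel > width or object_size > height:
        raise ValueError("object leaves the frame")
    rng = np.random.default_rng(seed)
    row0 = int(rng.integers(0, height - object_size + 1))
    col0 = int(rng.integers(0, width - object_size - travel + 1))
    frames = np.zeros((n_frames, height, width), dtype=np.uint8)
    for t in range(n_frames):
        c = col0 + step_px * t
        frames[t, row0:row0 + object_size, c:c + object_size] = intensity
    return FrameStack(frames)
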