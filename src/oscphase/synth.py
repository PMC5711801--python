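"""Synthetic bimanual finger-oscillation experiments.

Generates two-hand lateral-position trajectories with the statistical
structure the downstream analysis assumes: a metronome ramping through ten
discrete speeds (five beats each, ~22 s per trial), one movement cycle per
beat, per-cycle correctness drawn from a factorial logistic model with
participant intercepts, and per-cycle relative phase drawn around the
instructed target (180 deg symmetrical / 0 deg parallel, external space).

Correctness is drawn first (Bernoulli) and the phase error second — a
truncated von Mises inside the tolerance window for correct cycles, uniform
over its complement for incorrect ones — so the scoring stage recovers the
generating probabilities exactly.  The dominant (right) hand leads by a
constant time shift; the left hand is phase-locked to the shifted right hand
at the drawn relative phase, so the drawn phase is exactly what an ideal
phase estimator should measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .factors import (
    EFFECT_NAMES,
    FACTOR_LEVELS,
    POSTURE_RAW_LEVELS,
    TARGET_PHASE,
    cell_codes,
    pool_posture,
    pool_speed,
)

#: Default group-level effects (logit scale): a strong symmetry advantage,
#: a speed cost, a homologous-muscle advantage carried by the
#: instruction x posture terms, and a small mirror x instruction modulation.
#: Magnitudes are representative of adult performance in this task.
DEFAULT_TRUE_BETAS: dict[str, float] = {
    "intercept": 2.06,
    "instruction": 0.82,
    "mirror": 0.02,
    "posture": 0.12,
    "speed": -0.62,
    "instruction_mirror": -0.09,
    "instruction_posture": 0.48,
    "instruction_speed": 0.25,
    "mirror_posture": 0.00,
    "mirror_speed": 0.00,
    "posture_speed": 0.02,
    "instruction_mirror_posture": -0.03,
    "instruction_mirror_speed": -0.04,
    "instruction_posture_speed": 0.05,
    "mirror_posture_speed": 0.02,
    "instruction_mirror_posture_speed": -0.01,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Defaults mirror the study design this generator emulates: 20
    participants, two sessions, four repetitions of each of the 16 block
    conditions, 100 Hz sampling, ten metronome speeds from 1.4 to 3.4 Hz
    held for five beats each (50 beats, ~22 s per trial).
    """

    n_participants: int = 20
    sessions: int = 2
    reps_per_condition: int = 4  # total across sessions
    sampling_rate: float = 100.0  # Hz
    speeds: tuple[float, ...] = tuple(np.linspace(1.4, 3.4, 10).round(6))
    beats_per_speed: int = 5
    amplitude_mm: float = 20.0
    true_betas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETAS)
    )
    participant_sd: float = 0.5  # logit-scale s.d. of participant intercepts
    kappa_correct: float = 8.0  # von Mises concentration, correct cycles
    tolerance_deg: float = 50.0  # half-width of the correct window
    dropout_rate: float = 0.02  # per-sample probability of a missing marker
    lead_ms: float = 25.0  # dominant-hand temporal lead
    noise_mm: float = 0.5  # additive positional noise s.d.
    cycle_loss_rate: float = 0.025  # paused / off-beat cycles never produced
    seed: int = 0

    def __post_init__(self) -> None:
        speeds = np.asarray(self.speeds, dtype=float)
        if speeds.ndim != 1 or len(speeds) < 1:
            raise ValueError("speeds must be a non-empty 1-d sequence")
        if np.any(speeds <= 0) or np.any(np.diff(speeds) <= 0):
            raise ValueError("speeds must be strictly increasing and positive")
        if self.kappa_correct <= 0:
            raise ValueError("kappa_correct must be > 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.cycle_loss_rate < 1:
            raise ValueError("cycle_loss_rate must be in [0, 1)")
        if self.amplitude_mm <= 0:
            raise ValueError("amplitude_mm must be > 0")
        if not 0 < self.tolerance_deg < 90:
            raise ValueError("tolerance_deg must be in (0, 90)")
        missing = set(EFFECT_NAMES) - set(self.true_betas)
        extra = set(self.true_betas) - set(EFFECT_NAMES)
        if missing or extra:
            raise ValueError(
                f"true_betas must have exactly the 16 effects; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    @property
    def beta_vector(self) -> np.ndarray:
        """Betas as a 16-vector in canonical effect order."""
        return np.array([self.true_betas[e] for e in EFFECT_NAMES])

    def schedule(self) -> "MetronomeSchedule":
        return MetronomeSchedule(self.speeds, self.beats_per_speed)


@dataclass(frozen=True)
class TrialCondition:
    """Block condition of one trial, before factor pooling."""

    instruction: str
    mirror: str
    posture_raw: str
    participant: int = 0
    session: int = 1
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.instruction not in FACTOR_LEVELS["instruction"]:
            raise ValueError(f"unknown instruction {self.instruction!r}")
        if self.mirror not in FACTOR_LEVELS["mirror"]:
            raise ValueError(f"unknown mirror level {self.mirror!r}")
        if self.posture_raw not in POSTURE_RAW_LEVELS:
            raise ValueError(f"unknown raw posture {self.posture_raw!r}")

    @property
    def posture_pooled(self) -> str:
        return pool_posture(self.posture_raw)


class MetronomeSchedule:
    """Piecewise-constant speed ramp: each speed held for a fixed beat count."""

    def __init__(self, speeds, beats_per_speed: int):
        self.speeds = np.asarray(speeds, dtype=float)
        self.beats_per_speed = int(beats_per_speed)
        # plateau durations and absolute boundaries
        durations = self.beats_per_speed / self.speeds
        self.boundaries = np.concatenate([[0.0], np.cumsum(durations)])
        self.duration = float(self.boundaries[-1])
        self.n_beats = len(self.speeds) * self.beats_per_speed
        # per-beat frequency and beat start times
        self.beat_freqs = np.repeat(self.speeds, self.beats_per_speed)
        self.beat_starts = np.concatenate([[0.0], np.cumsum(1.0 / self.beat_freqs)])

    @property
    def f_max(self) -> float:
        return float(self.speeds.max())

    def level_at(self, t) -> np.ndarray:
        """1-based speed plateau containing each time (clipped at the ends)."""
        idx = np.searchsorted(self.boundaries, np.asarray(t, float), side="right")
        return np.clip(idx, 1, len(self.speeds)).astype(int)

    def phase_at(self, t) -> np.ndarray:
        """Phase-continuous metronome phase (rad); one beat == one 2*pi cycle."""
        t = np.asarray(t, dtype=float)
        beat = np.clip(
            np.searchsorted(self.beat_starts, t, side="right") - 1,
            0,
            self.n_beats - 1,
        )
        return 2 * np.pi * (beat + (t - self.beat_starts[beat]) * self.beat_freqs[beat])

    def beat_of_phase(self, phi) -> np.ndarray:
        return np.clip(
            (np.asarray(phi, float) // (2 * np.pi)).astype(int), 0, self.n_beats - 1
        )


def wrap_phase(deg):
    """Wrap angles (degrees) into the analysis interval [-90, 270)."""
    return (np.asarray(deg, dtype=float) + 90.0) % 360.0 - 90.0


def true_probability(
    config: SimulationConfig,
    condition: TrialCondition,
    speed_level: str,
    participant_effect: float = 0.0,
) -> float:
    """P(correct cycle) at a design cell under the generating model.

    The inverse logit of intercept + sum of effect x (+/-1 code) +
    participant offset, using the same sum-to-zero coding as the model
    module.
    """
    if speed_level not in FACTOR_LEVELS["speed"]:
        raise ValueError(f"unknown speed level {speed_level!r}")
    levels = {
        "instruction": condition.instruction,
        "mirror": condition.mirror,
        "posture": condition.posture_pooled,
        "speed": speed_level,
    }
    eta = float(np.dot(cell_codes(levels), config.beta_vector)) + participant_effect
    return float(1.0 / (1.0 + np.exp(-eta)))


def _draw_cycle_phases(
    rng: np.random.Generator,
    correct: np.ndarray,
    target_deg: float,
    kappa: float,
    tol: float,
) -> np.ndarray:
    """Per-cycle relative phase: truncated von Mises inside the tolerance
    window around the target when correct, uniform over the complement when
    not.  Returns degrees wrapped to [-90, 270)."""
    n = len(correct)
    err = np.empty(n)
    # correct: rejection-sample von Mises(0, kappa) truncated to +/- tol
    idx = np.flatnonzero(correct)
    need = idx.copy()
    while need.size:
        cand = np.degrees(rng.vonmises(0.0, kappa, size=need.size))
        ok = np.abs(cand) <= tol
        err[need[ok]] = cand[ok]
        need = need[~ok]
    # incorrect: uniform over (-180, 180] minus [-tol, tol]
    idx = np.flatnonzero(~correct)
    span = 360.0 - 2 * tol
    u = rng.uniform(0.0, span, size=idx.size)
    err[idx] = np.where(u < 180.0 - tol, tol + u, tol + u - 360.0)
    return wrap_phase(target_deg + err)


def _trial_rng(config: SimulationConfig, trial: int) -> np.random.Generator:
    # counter-based substream: each trial reproducible independently
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(trial,)))


def _participant_effects(config: SimulationConfig) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(10**6,))
    )
    return rng.normal(0.0, config.participant_sd, size=config.n_participants)


def _draw_trial_cycles(
    config: SimulationConfig,
    condition: TrialCondition,
    participant_effect: float,
    rng: np.random.Generator,
    lose_cycles: bool,
):
    """Per-beat correctness and relative phase for one trial.

    Returns (beat indices kept, correct flags, phases deg, speed levels).
    """
    sched = config.schedule()
    levels = sched.level_at(sched.beat_starts[: sched.n_beats] + 1e-9)
    p_slow = true_probability(config, condition, "slow", participant_effect)
    p_fast = true_probability(config, condition, "fast", participant_effect)
    p = np.where(np.array([pool_speed(l) for l in levels]) == "slow", p_slow, p_fast)
    correct = rng.random(sched.n_beats) < p
    target = TARGET_PHASE[condition.instruction]
    phases = _draw_cycle_phases(
        rng, correct, target, config.kappa_correct, config.tolerance_deg
    )
    keep = np.ones(sched.n_beats, dtype=bool)
    if lose_cycles and config.cycle_loss_rate > 0:
        keep = rng.random(sched.n_beats) >= config.cycle_loss_rate
    return np.flatnonzero(keep), correct[keep], phases[keep], levels[keep]


def simulate_trial(
    config: SimulationConfig,
    condition: TrialCondition,
    participant_effect: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Simulate one trial; returns (left, right) hand sample tables.

    Each table has columns t (s), x (lateral mm), y (secondary mm) and
    missing.  The right hand tracks the metronome with the configured lead;
    the left hand carries, per beat, a constant phase offset equal to the
    drawn relative phase.  Offset discontinuities sit at beat boundaries,
    outside the max->min half-cycles the kinematics stage fits.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sched = config.schedule()
    n = int(np.floor(sched.duration * config.sampling_rate)) + 1
    t = np.arange(n) / config.sampling_rate
    phi = sched.phase_at(t)
    lead = 2 * np.pi * sched.beat_freqs[sched.beat_of_phase(phi)] * (
        config.lead_ms / 1000.0
    )
    _, correct, phases, _ = _draw_trial_cycles(
        config, condition, participant_effect, rng, lose_cycles=False
    )
    del correct
    # Per-beat phase offset for the left hand.  The offset changes between
    # beats; a smoothstep blend removes the position discontinuity.  The
    # fitted max->min window of beat b spans beat fractions
    # [0.25, 0.75] - lead*f, so the blend is centered in the unfitted
    # min->max half-cycle (fraction 1 - lead*f, i.e. the following beat's
    # start shifted by the lead) where it cannot contaminate measured phase.
    beat = sched.beat_of_phase(phi)
    psi = np.radians(phases)
    frac = phi / (2 * np.pi) - beat  # position within the beat, [0, 1)
    lead_frac = sched.beat_freqs[beat] * (config.lead_ms / 1000.0)
    # distance past the blend center; blend spans +/- 0.03 beat around it
    rel = frac - (1.0 - lead_frac)
    in_prev_gap = rel < -0.5  # samples before this beat's own blend center
    lo = np.where(in_prev_gap, np.maximum(beat - 1, 0), beat)
    hi = np.where(in_prev_gap, beat, np.minimum(beat + 1, len(psi) - 1))
    step = np.angle(np.exp(1j * (psi[hi] - psi[lo])))
    s = np.clip((np.where(in_prev_gap, rel + 1.0, rel) + 0.03) / 0.06, 0.0, 1.0)
    offset = psi[lo] + step * (3 * s**2 - 2 * s**3)
    out = []
    for hand, x in (
        ("left", config.amplitude_mm * np.sin(phi + lead + offset)),
        ("right", config.amplitude_mm * np.sin(phi + lead)),
    ):
        x = x + rng.normal(0.0, config.noise_mm, size=n)
        y = rng.normal(0.0, config.noise_mm, size=n)  # secondary dimension: noise only
        missing = rng.random(n) < config.dropout_rate
        x[missing] = np.nan
        out.append(
            pd.DataFrame({"t": t, "x": x, "y": y, "missing": missing, "hand": hand})
        )
    return out[0], out[1]


def condition_grid(config: SimulationConfig) -> list[TrialCondition]:
    """Full factorial block-condition grid x repetitions x participants."""
    # repetitions distributed round-robin across sessions
    sessions = [i % config.sessions + 1 for i in range(config.reps_per_condition)]
    grid = []
    for p in range(1, config.n_participants + 1):
        for instruction in FACTOR_LEVELS["instruction"]:
            for mirror in FACTOR_LEVELS["mirror"]:
                for posture_raw in POSTURE_RAW_LEVELS:
                    for s in sessions:
                        grid.append(
                            TrialCondition(
                                instruction=instruction,
                                mirror=mirror,
                                posture_raw=posture_raw,
                                participant=p,
                                session=s,
                            )
                        )
    return grid


def _metadata_frame(grid: list[TrialCondition]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": np.arange(len(grid)),
            "participant": [c.participant for c in grid],
            "session": [c.session for c in grid],
            "instruction": [c.instruction for c in grid],
            "mirror": [c.mirror for c in grid],
            "posture_raw": [c.posture_raw for c in grid],
            "excluded": [c.excluded for c in grid],
        }
    )


def simulate_experiment(config: SimulationConfig):
    """Full experiment: (long-format trajectory table, trial metadata table).

    Deterministic under a fixed config seed; per-trial substreams are
    derived by counter so any single trial can be regenerated on its own.
    """
    grid = condition_grid(config)
    effects = _participant_effects(config)
    meta = _metadata_frame(grid)
    frames = []
    for trial, cond in enumerate(grid):
        rng = _trial_rng(config, trial)
        left, right = simulate_trial(config, cond, effects[cond.participant - 1], rng)
        for df in (left, right):
            df.insert(0, "trial", trial)
            df.insert(0, "participant", cond.participant)
        frames.append(left)
        frames.append(right)
    traj = pd.concat(frames, ignore_index=True)
    traj = traj[["participant", "trial", "t", "hand", "x", "y", "missing"]]
    return traj, meta


def simulate_cycle_outcomes(config: SimulationConfig) -> pd.DataFrame:
    """Cycle-level view of the generator: the per-cycle outcome table the
    full pipeline would recover, without waveform synthesis.

    One row per analyzable cycle with the block condition, metronome speed
    level, drawn relative phase and the generating correctness flag.  Uses
    the same per-trial substreams as :func:`simulate_experiment` up to the
    waveform-only draws.
    """
    grid = condition_grid(config)
    effects = _participant_effects(config)
    rows = []
    for trial, cond in enumerate(grid):
        rng = _trial_rng(config, trial)
        beats, correct, phases, levels = _draw_trial_cycles(
            config, cond, effects[cond.participant - 1], rng, lose_cycles=True
        )
        rows.append(
            pd.DataFrame(
                {
                    "participant": cond.participant,
                    "session": cond.session,
                    "trial": trial,
                    "cycle_index": beats,
                    "instruction": cond.instruction,
                    "mirror": cond.mirror,
                    "posture_raw": cond.posture_raw,
                    "speed_level": levels,
                    "relative_phase": phases,
                    "generating_correct": correct.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: a copy of ``config`` with a different master seed."""
    return replace(config, seed=int(seed))
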