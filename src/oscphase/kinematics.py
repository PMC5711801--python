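"""From raw two-hand trajectories to per-cycle relative phase.

The pipeline per trial is: interpolate occasional missing samples, zero-phase
first-order Butterworth low-pass at 7.5 Hz, demean; segment the right
finger's trajectory into movement cycles (each consecutive maximum ->
minimum interval); fit a sine to each finger within each cycle window; and
take the relative phase as the phase difference of the two fitted sines,
wrapped into [-90, 270) so that both attractors (0 = parallel / in-phase,
180 = symmetrical / anti-phase in external space) sit in the interior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .synth import MetronomeSchedule, wrap_phase

FILTER_CUTOFF_HZ = 7.5
MAX_MISSING_FRACTION = 0.2
#: Extremum prominence threshold as a fraction of the trial position s.d.
PROMINENCE_FRACTION = 0.1
#: Cycles with peak-to-peak excursion below this fraction of the trial
#: median are dropped as unidentifiably small movements.
SMALLNESS_FRACTION = 0.2
#: Samples shaved off each end of a cycle window before sine fitting, so
#: that filter transients at the window edges cannot bias phase estimates.
EDGE_TRIM = 2


class ExcludedTrialError(ValueError):
    """Raised when a trial cannot be analyzed (e.g. too many missing samples)."""


@dataclass
class Trajectory:
    """One hand's uniformly sampled lateral-position time series.

    Positions are in mm, time in seconds.  ``extra_dims`` holds optional
    secondary position components (e.g. the up-down dimension) used only for
    quality control.
    """

    time: np.ndarray
    position: np.ndarray
    missing: np.ndarray
    hand: str
    extra_dims: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (len(self.time) == len(self.position) == len(self.missing)):
            raise ValueError("time, position and missing must have equal length")
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > 0.5 * dt[0]):
                raise ValueError("time must be uniformly sampled")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class SineFit:
    """Least-squares sine description of one finger within one cycle window."""

    amplitude: float  # mm, >= 0
    frequency: float  # Hz, > 0
    phase: float  # degrees in (-180, 180], at the window's time origin
    offset: float  # mm
    residual_rms: float  # mm
    converged: bool = True


@dataclass(frozen=True)
class CycleBounds:
    start: int  # sample index of the right-finger maximum
    end: int  # sample index of the following minimum (inclusive)
    speed_level: int  # metronome plateau (1-10) containing the midpoint


@dataclass(frozen=True)
class CycleRecord:
    trial: int
    cycle_index: int
    bounds: CycleBounds
    fit_left: SineFit
    fit_right: SineFit
    relative_phase: float  # degrees in [-90, 270)
    valid: bool


def preprocess(raw: Trajectory) -> Trajectory:
    """Interpolate missing samples, zero-phase low-pass filter, demean.

    Missing runs at the edges are held constant at the nearest observed
    value.  Raises :class:`ExcludedTrialError` when more than
    ``MAX_MISSING_FRACTION`` of the samples are missing, and ``ValueError``
    when fewer than two samples were observed at all.
    """
    x = raw.position.copy()
    miss = raw.missing | ~np.isfinite(x)
    n_ok = int((~miss).sum())
    if n_ok < 2:
        raise ValueError("preprocess requires at least 2 non-missing samples")
    if miss.mean() > MAX_MISSING_FRACTION:
        raise ExcludedTrialError(
            f"{miss.mean():.0%} of samples missing exceeds "
            f"{MAX_MISSING_FRACTION:.0%} threshold"
        )
    if miss.any():
        ok = np.flatnonzero(~miss)
        x[miss] = np.interp(np.flatnonzero(miss), ok, x[ok])
    fs = raw.sampling_rate
    b, a = signal.butter(1, FILTER_CUTOFF_HZ, fs=fs)
    x = signal.filtfilt(b, a, x)
    x = x - x.mean()
    extra = {
        k: signal.filtfilt(b, a, np.nan_to_num(v) - np.nanmean(v))
        for k, v in raw.extra_dims.items()
    }
    return Trajectory(
        time=raw.time,
        position=x,
        missing=np.zeros_like(miss),
        hand=raw.hand,
        extra_dims=extra,
    )


def filter_gain(freq_hz: float, fs: float = 100.0) -> float:
    """Two-pass (zero-phase) magnitude response of the preprocessing filter."""
    b, a = signal.butter(1, FILTER_CUTOFF_HZ, fs=fs)
    _, h = signal.freqz(b, a, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


def segment_cycles(
    right: Trajectory, schedule: MetronomeSchedule
) -> list[CycleBounds]:
    """Cycle bounds from the right finger: consecutive maximum -> minimum.

    Extrema are located with a prominence criterion (a fraction of the trial
    position s.d.) and a minimum spacing of half the fastest metronome
    period.  Each cycle is assigned the speed plateau containing its
    temporal midpoint.  Cycles whose peak-to-peak excursion falls below a
    fraction of the trial median are dropped as unidentifiably small.
    """
    x = right.position
    sd = float(np.std(x))
    if sd == 0.0:
        return []
    fs = right.sampling_rate
    distance = max(1, int(0.5 / schedule.f_max * fs))
    prominence = PROMINENCE_FRACTION * sd
    maxima, _ = signal.find_peaks(x, prominence=prominence, distance=distance)
    minima, _ = signal.find_peaks(-x, prominence=prominence, distance=distance)
    if len(maxima) == 0 or len(minima) == 0:
        return []
    # for each maximum take the first following minimum
    pairs = []
    j = np.searchsorted(minima, maxima, side="right")
    for i, mx in enumerate(maxima):
        if j[i] >= len(minima):
            break
        mn = minima[j[i]]
        if i + 1 < len(maxima) and maxima[i + 1] < mn:
            continue  # two maxima without an intervening minimum
        pairs.append((int(mx), int(mn)))
    if not pairs:
        return []
    ptp = np.array([x[a] - x[b] for a, b in pairs])
    keep = ptp >= SMALLNESS_FRACTION * np.median(ptp)
    mids = right.time[[(a + b) // 2 for a, b in pairs]]
    levels = schedule.level_at(mids)
    return [
        CycleBounds(a, b, int(lv))
        for (a, b), lv, k in zip(pairs, levels, keep)
        if k
    ]


def _sine_ls(t: np.ndarray, x: np.ndarray, freq: float, weights=None):
    """(Weighted) linear least squares for offset + a sin + b cos at fixed
    frequency."""
    w = 2 * np.pi * freq
    design = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    if weights is None:
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    else:
        sw = np.sqrt(weights)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], x * sw, rcond=None)
    resid = x - design @ coef
    return coef, float(np.sqrt(np.mean(resid**2)))


def fit_sine(
    time: np.ndarray,
    position: np.ndarray,
    freq_init: float | None = None,
    refine: bool = True,
) -> SineFit:
    """Least-squares sine fit ``offset + A sin(2 pi f t + phase)``.

    The frequency is initialized from the window's implied half period
    (a max -> min window spans half an oscillation) unless given, then
    refined by bounded scalar minimization of the residual; amplitude and
    phase come from the conditionally linear subproblem.  With
    ``refine=False`` the frequency is held at ``freq_init`` (used for the
    second finger of a cycle, which shares the metronome rate with the
    first).  The fit is canonicalized to amplitude >= 0 and phase in
    (-180, 180] degrees, referenced to the window's first sample.
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(position, dtype=float)
    if len(t) < 4:
        raise ValueError("fit_sine requires a window of at least 4 samples")
    t0 = t[0]
    t = t - t0
    span = t[-1]
    if freq_init is None:
        freq_init = 1.0 / (2.0 * span)  # half-period window
    if refine:
        try:
            res = optimize.minimize_scalar(
                lambda f: _sine_ls(t, x, f)[1],
                bounds=(0.5 * freq_init, 2.0 * freq_init),
                method="bounded",
                options={"xatol": 1e-9 * freq_init},
            )
            freq = float(res.x)
            converged = bool(res.success)
        except Exception:  # pragma: no cover - defensive
            freq, converged = freq_init, False
    else:
        freq, converged = float(freq_init), True
    coef, rms = _sine_ls(t, x, freq)
    offset, a, b = coef
    amplitude = float(np.hypot(a, b))
    phase = float(np.degrees(np.arctan2(b, a)))
    if phase <= -180.0:
        phase += 360.0
    return SineFit(
        amplitude=amplitude,
        frequency=freq,
        phase=phase,
        offset=float(offset),
        residual_rms=rms,
        converged=converged,
    )


def relative_phase(fit_left: SineFit, fit_right: SineFit) -> float:
    """Phase difference (left minus right, degrees) wrapped to [-90, 270).

    180 means anti-phase in external space (perfect symmetry), 0 in-phase
    (perfect parallel movement).
    """
    return float(wrap_phase(fit_left.phase - fit_right.phase))


def _fit_cycle_pair(
    left_p: Trajectory,
    right_p: Trajectory,
    bounds: CycleBounds,
    schedule: MetronomeSchedule,
) -> tuple[SineFit, SineFit]:
    """Sine fits of both fingers for one cycle.

    The cycle frequency is refined on a window of up to 1.5 periods of the
    right finger (the segmentation reference), clipped to the cycle's own
    metronome plateau so a tempo change never leaks into the estimate.  The
    amplitude, phase and offset of each finger then come from a
    Hann-weighted least-squares fit at that frequency on a 0.7-period
    window centered on the cycle; the model-based fit is unbiased under
    any weighting, and the taper suppresses the influence of neighbouring
    cycles at the window edges.  Both fits share the window's time origin
    so their phases are directly comparable.  Cycles too close to the
    trial edges fall back to the plain max->min window.
    """
    fs = right_p.sampling_rate
    n = len(right_p.position)
    mid = (bounds.start + bounds.end) // 2
    t_half = max(bounds.end - bounds.start, 1) / fs  # implied half period
    freq0 = 1.0 / (2.0 * t_half)
    h = int(round(0.75 / freq0 * fs))
    a, b = max(mid - h, 0), min(mid + h + 1, n)
    # clip the frequency window to the plateau containing the cycle
    lo_t = schedule.boundaries[bounds.speed_level - 1]
    hi_t = schedule.boundaries[bounds.speed_level]
    a = max(a, int(np.ceil((lo_t - right_p.time[0]) * fs)))
    b = min(b, int(np.floor((hi_t - right_p.time[0]) * fs)) + 1)
    if b - a < 4:
        a, b = max(mid - h, 0), min(mid + h + 1, n)
    fr_long = fit_sine(right_p.time[a:b], right_p.position[a:b], freq_init=freq0)
    freq = fr_long.frequency
    h2 = int(round(0.35 / freq * fs))
    a2, b2 = mid - h2, mid + h2 + 1
    if a2 < 0 or b2 > n:  # trial edge: plain fit on the max->min window
        a2 = bounds.start + EDGE_TRIM
        b2 = bounds.end + 1 - EDGE_TRIM
        if b2 - a2 < 4:
            a2, b2 = bounds.start, bounds.end + 1
        weights = None
    else:
        m = b2 - a2
        weights = 0.5 - 0.5 * np.cos(2 * np.pi * (np.arange(m) + 0.5) / m)
    t0 = right_p.time[a2]
    fits = []
    for traj in (left_p, right_p):
        coef, rms = _sine_ls(
            traj.time[a2:b2] - t0, traj.position[a2:b2], freq, weights
        )
        offset, ca, cb = coef
        phase = float(np.degrees(np.arctan2(cb, ca)))
        if phase <= -180.0:
            phase += 360.0
        fits.append(
            SineFit(
                amplitude=float(np.hypot(ca, cb)),
                frequency=freq,
                phase=phase,
                offset=float(offset),
                residual_rms=rms,
                converged=fr_long.converged,
            )
        )
    return fits[0], fits[1]


def analyze_trial(
    left: Trajectory,
    right: Trajectory,
    schedule: MetronomeSchedule,
    trial: int = 0,
) -> list[CycleRecord]:
    """Preprocess both hands, segment on the right, fit both per cycle."""
    left_p = preprocess(left)
    right_p = preprocess(right)
    records = []
    for i, bounds in enumerate(segment_cycles(right_p, schedule)):
        try:
            fl, fr = _fit_cycle_pair(left_p, right_p, bounds, schedule)
        except (ValueError, np.linalg.LinAlgError):
            continue
        valid = fl.converged and fr.converged and fl.amplitude > 0 and fr.amplitude > 0
        records.append(
            CycleRecord(
                trial=trial,
                cycle_index=i,
                bounds=bounds,
                fit_left=fl,
                fit_right=fr,
                relative_phase=relative_phase(fl, fr),
                valid=valid,
            )
        )
    return records


def cycle_table(records: list[CycleRecord]) -> pd.DataFrame:
    """Flatten cycle records into the delimited cycle-table layout."""
    return pd.DataFrame(
        {
            "trial": [r.trial for r in records],
            "cycle_index": [r.cycle_index for r in records],
            "start": [r.bounds.start for r in records],
            "end": [r.bounds.end for r in records],
            "speed_level": [r.bounds.speed_level for r in records],
            "relative_phase": [r.relative_phase for r in records],
            "freq_left": [r.fit_left.frequency for r in records],
            "freq_right": [r.fit_right.frequency for r in records],
            "amp_left": [r.fit_left.amplitude for r in records],
            "amp_right": [r.fit_right.amplitude for r in records],
            "residual_left": [r.fit_left.residual_rms for r in records],
            "residual_right": [r.fit_right.residual_rms for r in records],
            "valid": [r.valid for r in records],
        }
    )


def process_experiment(
    traj: pd.DataFrame, meta: pd.DataFrame, schedule: MetronomeSchedule
) -> pd.DataFrame:
    """Run the kinematic pipeline over a long-format trajectory table.

    Trials that fail preprocessing (too many missing samples) are skipped
    with a warning; the returned cycle table carries participant and trial
    keys for the scoring stage.
    """
    frames = []
    for (participant, trial), g in traj.groupby(["participant", "trial"], sort=True):
        hands = {}
        for hand, gh in g.groupby("hand"):
            extra = {
                c: gh[c].to_numpy()
                for c in gh.columns
                if c not in ("participant", "trial", "t", "hand", "x", "missing")
            }
            hands[hand] = Trajectory(
                time=gh["t"].to_numpy(),
                position=gh["x"].to_numpy(),
                missing=gh["missing"].to_numpy(dtype=bool),
                hand=str(hand),
                extra_dims=extra,
            )
        if set(hands) != {"left", "right"}:
            warnings.warn(f"trial {trial}: missing a hand, skipped")
            continue
        try:
            records = analyze_trial(
                hands["left"], hands["right"], schedule, trial=int(trial)
            )
        except ExcludedTrialError as e:
            warnings.warn(f"trial {trial} excluded: {e}")
            continue
        tab = cycle_table(records)
        tab.insert(0, "participant", participant)
        frames.append(tab)
    if not frames:
        return cycle_table([]).assign(participant=pd.Series(dtype=int))
    return pd.concat(frames, ignore_index=True)


def continuous_phase_diff(
    left: Trajectory, right: Trajectory, bounds: list[CycleBounds]
) -> np.ndarray:
    """Per-cycle relative phase from the analytic-signal instantaneous phase.

    An independent cross-check on the sine-fit route: the Hilbert-transform
    phase difference is averaged circularly within each cycle window and
    wrapped with the same convention.
    """
    pl = np.unwrap(np.angle(signal.hilbert(left.position)))
    pr = np.unwrap(np.angle(signal.hilbert(right.position)))
    diff = pl - pr
    out = np.empty(len(bounds))
    for i, bnd in enumerate(bounds):
        d = diff[bnd.start : bnd.end + 1]
        out[i] = np.degrees(np.angle(np.mean(np.exp(1j * d))))
    return wrap_phase(out)


def qc_dimension_stats(
    trajectories: dict[str, Trajectory], schedule: MetronomeSchedule
) -> pd.DataFrame:
    """Per-dimension movement checks on one (preprocessed) trial.

    Finite-difference velocities per named dimension, summarized per speed
    plateau: peak absolute velocity, velocity s.d., and the number of cycles
    found when segmenting that dimension.  Movement should live in the
    lateral dimension: its velocities and cycle counts should dominate.
    """
    rows = []
    for dim, traj in trajectories.items():
        v = np.gradient(traj.position, traj.time)
        levels = schedule.level_at(traj.time)
        cycles = segment_cycles(traj, schedule)
        counts = np.bincount(
            [c.speed_level for c in cycles], minlength=len(schedule.speeds) + 1
        )
        for lv in range(1, len(schedule.speeds) + 1):
            vin = v[levels == lv]
            rows.append(
                {
                    "dimension": dim,
                    "speed_level": lv,
                    "peak_velocity": float(np.max(np.abs(vin))) if vin.size else 0.0,
                    "velocity_sd": float(np.std(vin)) if vin.size else 0.0,
                    "n_cycles": int(counts[lv]),
                }
            )
    return pd.DataFrame(rows)
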