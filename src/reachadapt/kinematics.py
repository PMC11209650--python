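"""Reach trajectories, preprocessing rules and adaptation-index extraction.

The adaptation index (AI) of an error-clamp trial is the ordinary
least-squares slope of the measured lateral channel force on the force the
curl field would have produced (``b`` times the velocity along the channel),
i.e. the fraction of ideal compensation.  A perfectly adapted reach has
AI = 1, an unadapted one AI = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .schedule import TrialSchedule

__all__ = [
    "DT",
    "TARGET_DISTANCE",
    "ChannelSpec",
    "ReachTrajectory",
    "AdaptationSeries",
    "ReachWindow",
    "synth_reach",
    "detect_onset_offset",
    "exclude_trial",
    "compute_ai",
    "baseline_correct",
]

DT = 0.001  # robot sampling interval, s (1 kHz)
TARGET_DISTANCE = 0.12  # m, straight ahead from the home position
SPEED_THRESHOLD = 0.05  # m/s, onset / stall threshold
TARGET_RADIUS = 0.03  # m, arrival zone around target centre
OFFSET_DWELL = 0.200  # s after entering the arrival zone
MIN_DISPLACEMENT = 0.06  # m, trials moving less are excluded


@dataclass(frozen=True)
class ChannelSpec:
    """Stiff spring + damper constants of the simulated error-clamp channel."""

    spring_k: float = 6000.0  # N/m
    damping_c: float = 7.5  # Ns/m

    def __post_init__(self) -> None:
        if self.spring_k <= 0 or self.damping_c <= 0:
            raise ValueError("channel constants must be positive")


@dataclass(frozen=True)
class ReachTrajectory:
    """1 kHz time series of hand state (and, on EC trials, channel force)."""

    t: np.ndarray  # s
    pos: np.ndarray  # (n, 2) m, columns (x lateral, y sagittal)
    vel: np.ndarray  # (n, 2) m/s
    lateral_force: np.ndarray | None = None  # N, EC trials only
    trial_index: int = 0

    def __post_init__(self) -> None:
        n = len(self.t)
        if self.pos.shape != (n, 2) or self.vel.shape != (n, 2):
            raise ValueError("pos and vel must be (n, 2) arrays matching t")
        dt = np.diff(self.t)
        if n > 1 and not np.allclose(dt, DT, atol=1e-9):
            raise ValueError("t must be uniformly sampled at 1 kHz")

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vel[:, 0], self.vel[:, 1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t": self.t,
                "x": self.pos[:, 0],
                "y": self.pos[:, 1],
                "vx": self.vel[:, 0],
                "vy": self.vel[:, 1],
            }
        )
        df["f_lat"] = self.lateral_force if self.lateral_force is not None else np.nan
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, trial_index: int = 0) -> "ReachTrajectory":
        df = pd.read_csv(path)
        f = df["f_lat"].to_numpy()
        return cls(
            t=df["t"].to_numpy(),
            pos=df[["x", "y"]].to_numpy(),
            vel=df[["vx", "vy"]].to_numpy(),
            lateral_force=None if np.isnan(f).all() else f,
            trial_index=trial_index,
        )


@dataclass(frozen=True)
class AdaptationSeries:
    """Per-probe AI values of one participant."""

    participant_id: str
    probe_trial_indices: np.ndarray
    ai: np.ndarray
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        idx = np.asarray(self.probe_trial_indices)
        if len(idx) != len(self.ai):
            raise ValueError("probe indices and AI values must align")
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("probe trial indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ai)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "trial_index": self.probe_trial_indices,
                "ai": self.ai,
            }
        )


class ReachWindow(NamedTuple):
    onset: int | None
    offset: int | None

    @property
    def valid(self) -> bool:
        return self.onset is not None and self.offset is not None


def _minimum_jerk(duration: float, n_pre: int, n_post: int) -> tuple[np.ndarray, ...]:
    """Minimum-jerk sagittal reach to the target, padded with rest samples."""
    n_move = int(round(duration / DT)) + 1
    tau = np.linspace(0.0, 1.0, n_move)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    sdot = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / duration
    y = np.concatenate([np.zeros(n_pre), TARGET_DISTANCE * s, np.full(n_post, TARGET_DISTANCE)])
    vy = np.concatenate([np.zeros(n_pre), TARGET_DISTANCE * sdot, np.zeros(n_post)])
    t = np.arange(len(y)) * DT
    return t, y, vy


def synth_reach(
    ai_true: float,
    b: float = 13.0,
    noise_sd: float = 0.0,
    duration: float = 0.45,
    seed: int | np.random.Generator | None = None,
    trial_index: int = 0,
    pre_s: float = 0.1,
    post_s: float = 0.25,
) -> ReachTrajectory:
    """Synthesize an error-clamp reach with a known underlying AI.

    The hand follows a minimum-jerk profile straight down the channel; the
    measured lateral force is ``ai_true`` times the force the curl field
    would have produced (b * v_y) plus white Gaussian noise.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t, y, vy = _minimum_jerk(duration, int(round(pre_s / DT)), int(round(post_s / DT)))
    theoretical = b * vy
    noise = rng.normal(0.0, noise_sd, size=len(t)) if noise_sd > 0 else 0.0
    measured = ai_true * theoretical + noise
    pos = np.column_stack([np.zeros_like(y), y])
    vel = np.column_stack([np.zeros_like(vy), vy])
    return ReachTrajectory(t=t, pos=pos, vel=vel, lateral_force=measured, trial_index=trial_index)


def detect_onset_offset(traj: ReachTrajectory) -> ReachWindow:
    """Reach onset/offset sample indices.

    Onset: first sample with cursor speed above 5 cm/s.  Offset: 200 ms
    after the cursor comes within 3 cm of the target centre, except that
    (1) leaving the 3 cm zone again within those 200 ms sets the offset at
    the exit sample, and (2) the speed dropping below 5 cm/s outside the
    zone sets the offset there (a stalled reach).
    """
    speed = traj.speed
    above = np.flatnonzero(speed > SPEED_THRESHOLD)
    if len(above) == 0:
        return ReachWindow(None, None)
    onset = int(above[0])

    target = np.array([0.0, TARGET_DISTANCE])
    dist = np.hypot(traj.pos[:, 0] - target[0], traj.pos[:, 1] - target[1])
    dwell = int(round(OFFSET_DWELL / DT))
    n = len(speed)
    i = onset
    while i < n:
        if dist[i] < TARGET_RADIUS:
            exit_rel = np.flatnonzero(dist[i : i + dwell] >= TARGET_RADIUS)
            if len(exit_rel):
                return ReachWindow(onset, int(i + exit_rel[0]))
            return ReachWindow(onset, min(i + dwell, n - 1))
        if speed[i] < SPEED_THRESHOLD and i > onset:
            return ReachWindow(onset, i)
        i += 1
    return ReachWindow(onset, n - 1)


def exclude_trial(traj: ReachTrajectory) -> bool:
    """True iff the hand moved less than 6 cm from the start (strict <)."""
    disp = np.hypot(traj.pos[:, 0] - traj.pos[0, 0], traj.pos[:, 1] - traj.pos[0, 1])
    return bool(disp.max() < MIN_DISPLACEMENT)


def compute_ai(traj: ReachTrajectory, b: float = 13.0, window: ReachWindow | None = None) -> float:
    """AI of an EC trial: OLS slope (with intercept) of the measured lateral
    force on the theoretical field force b * v_along_channel over the
    onset-offset window."""
    if traj.lateral_force is None:
        raise ValueError("trajectory has no channel force: not an EC trial?")
    if window is None:
        window = detect_onset_offset(traj)
    if not window.valid:
        raise ValueError("no reach onset detected")
    sl = slice(window.onset, window.offset + 1)
    theoretical = b * traj.vel[sl, 1]
    measured = traj.lateral_force[sl]
    if np.allclose(theoretical, 0.0):
        raise ValueError("degenerate trial: theoretical force identically zero")
    X = np.column_stack([np.ones_like(theoretical), theoretical])
    coef, *_ = np.linalg.lstsq(X, measured, rcond=None)
    return float(coef[1])


def baseline_correct(series: AdaptationSeries, schedule: TrialSchedule) -> AdaptationSeries:
    """Subtract the mean AI over baseline-phase probes from every AI."""
    lo, hi = schedule.phase_boundaries["baseline"]
    idx = np.asarray(series.probe_trial_indices)
    mask = (idx >= lo) & (idx <= hi)
    if not mask.any():
        raise ValueError("series has no baseline-phase probes")
    return replace(
        series, ai=np.asarray(series.ai) - float(np.mean(np.asarray(series.ai)[mask])),
        baseline_corrected=True,
    )
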