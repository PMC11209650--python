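"""Trial schedule construction for the spontaneous-recovery force-field paradigm.

The experiment is a fixed sequence of reaching trials of three types:

* ``null`` — no robot forces,
* ``force`` — a viscous curl field (clockwise or counter-clockwise,
  set by the sign of the field constant ``b``),
* ``error_clamp`` — the hand is constrained to a straight channel so the
  lateral force expresses the adaptive state without a movement error.

The default paradigm is 100 null trials, 240 clockwise (CW) field trials,
30 counter-clockwise (CCW) field trials and a final block of 50 error-clamp
(EC) trials.  To track learning, probe EC trials are interleaved at a fixed
cadence (every fifth trial) inside a probe window spanning the null and
field blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "TrialType",
    "TrialSpec",
    "TrialSchedule",
    "ScheduleConfig",
    "build_schedule",
    "perturbation_sequence",
]


class TrialType(str, Enum):
    NULL = "null"
    FORCE = "force"
    ERROR_CLAMP = "error_clamp"


@dataclass(frozen=True)
class TrialSpec:
    """One trial: 1-based index, type, field constant (Ns/m) and the
    perturbation in adaptation-index units (+1 CW, -1 CCW, 0 null)."""

    index: int
    trial_type: TrialType
    field_constant_b: float
    perturbation_f: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("trial index must be a positive integer")
        if (self.field_constant_b != 0.0) != (self.trial_type is TrialType.FORCE):
            raise ValueError("field_constant_b must be nonzero iff trial_type is force")
        if self.perturbation_f not in (-1.0, 0.0, 1.0):
            raise ValueError("perturbation_f must be in {-1, 0, +1}")


@dataclass(frozen=True)
class ScheduleConfig:
    """Block lengths, field constant and probe cadence of the paradigm.

    ``probe_anchor`` selects the probe convention inside ``probe_window``
    (closed interval of 1-based trial indices):

    * ``"multiples"`` (default): probes at indices divisible by
      ``probe_every`` — with the default window [21, 370] that is
      25, 30, ..., 370 (70 probes);
    * ``"window_start"``: probes at window start, start+cadence, ... —
      21, 26, ..., 366.

    ``probe_every = 0`` disables interleaved probes entirely.
    """

    n_baseline: int = 100
    n_cw: int = 240
    n_ccw: int = 30
    n_final_ec: int = 50
    b: float = 13.0
    probe_every: int = 5
    probe_window: tuple[int, int] = (21, 370)
    probe_anchor: str = "multiples"

    def __post_init__(self) -> None:
        for name in ("n_baseline", "n_cw", "n_ccw", "n_final_ec"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        if self.n_cw == 0:
            raise ValueError("CW block must be non-empty")
        if self.probe_every < 0:
            raise ValueError("probe_every must be >= 0")
        if self.probe_anchor not in ("multiples", "window_start"):
            raise ValueError("probe_anchor must be 'multiples' or 'window_start'")
        lo, hi = self.probe_window
        if self.probe_every and not (1 <= lo <= hi <= self.n_total):
            raise ValueError("probe window must lie within the schedule")

    @property
    def n_total(self) -> int:
        return self.n_baseline + self.n_cw + self.n_ccw + self.n_final_ec

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScheduleConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "probe_window" in raw:
            raw["probe_window"] = tuple(raw["probe_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["probe_window"] = list(self.probe_window)
        return d


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trial specs plus named phase boundaries (closed 1-based ranges)."""

    trials: tuple[TrialSpec, ...]
    phase_boundaries: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, t in enumerate(self.trials, start=1):
            if t.index != i:
                raise ValueError("trial indices must be contiguous 1..N")

    def __len__(self) -> int:
        return len(self.trials)

    def __getitem__(self, index_1based: int) -> TrialSpec:
        return self.trials[index_1based - 1]

    @property
    def ec_trial_indices(self) -> list[int]:
        return [t.index for t in self.trials if t.trial_type is TrialType.ERROR_CLAMP]

    def probes_in_phase(self, phase: str) -> list[int]:
        lo, hi = self.phase_boundaries[phase]
        return [i for i in self.ec_trial_indices if lo <= i <= hi]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "trial_type": [t.trial_type.value for t in self.trials],
                "b": [t.field_constant_b for t in self.trials],
                "f": [t.perturbation_f for t in self.trials],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialSchedule":
        # keep_default_na: 'null' is a trial type, not a missing value
        df = pd.read_csv(path, keep_default_na=False)
        trials = tuple(
            TrialSpec(int(r.index), TrialType(r.trial_type), float(r.b), float(r.f))
            for r in df.itertuples(index=False)
        )
        return cls(trials=trials)


def _probe_indices(cfg: ScheduleConfig) -> set[int]:
    if cfg.probe_every == 0:
        return set()
    lo, hi = cfg.probe_window
    if cfg.probe_anchor == "multiples":
        start = ((lo + cfg.probe_every - 1) // cfg.probe_every) * cfg.probe_every
        return set(range(start, hi + 1, cfg.probe_every))
    return set(range(lo, hi + 1, cfg.probe_every))


def build_schedule(cfg: ScheduleConfig | None = None) -> TrialSchedule:
    """Build the trial schedule: null + CW + CCW + final-EC blocks, with probe
    EC trials substituted at the configured cadence inside the probe window.

    Probe EC trials carry the perturbation sign of the block they interrupt
    (recorded but unused downstream: the error is clamped to zero on EC trials).
    """
    cfg = cfg or ScheduleConfig()
    probes = _probe_indices(cfg)
    b0, b1 = cfg.n_baseline, cfg.n_baseline + cfg.n_cw
    b2 = b1 + cfg.n_ccw
    n = cfg.n_total

    trials = []
    for i in range(1, n + 1):
        if i <= b0:
            block_type, b, f = TrialType.NULL, 0.0, 0.0
        elif i <= b1:
            block_type, b, f = TrialType.FORCE, cfg.b, 1.0
        elif i <= b2:
            block_type, b, f = TrialType.FORCE, -cfg.b, -1.0
        else:
            block_type, b, f = TrialType.ERROR_CLAMP, 0.0, 0.0
        if i in probes and block_type is not TrialType.ERROR_CLAMP:
            # probe EC replaces the scheduled trial; field sign carried over
            trials.append(TrialSpec(i, TrialType.ERROR_CLAMP, 0.0, f))
        else:
            trials.append(TrialSpec(i, block_type, b, f))

    phases = {
        "baseline": (1, b0),
        "cw": (b0 + 1, b1),
        "ccw": (b1 + 1, b2),
        "final_ec": (b2 + 1, n),
    }
    return TrialSchedule(trials=tuple(trials), phase_boundaries=phases)


def perturbation_sequence(schedule: TrialSchedule) -> tuple[list[float], list[bool]]:
    """Per-trial perturbation f (AI units) and an error-clamp flag.

    On EC trials the recorded field sign is returned in ``f`` but the flag
    tells downstream dynamics to clamp the error to zero.
    """
    f = [t.perturbation_f for t in schedule.trials]
    is_ec = [t.trial_type is TrialType.ERROR_CLAMP for t in schedule.trials]
    return f, is_ec
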