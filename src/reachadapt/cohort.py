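"""Synthetic cohorts: participants drawn from group-level truncated normals.

Each participant's dual-rate parameters are drawn from a group
specification (a truncated-normal mean/SD per parameter); their observed
adaptation-index series are the noisy outputs of the dual-rate dynamics at
the error-clamp probes of a shared trial schedule.  True parameters are
retained so that parameter recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dualrate import DualRateParams, simulate
from .kinematics import AdaptationSeries
from .schedule import TrialSchedule, build_schedule

__all__ = [
    "PARAM_NAMES",
    "RATE_NAMES",
    "GroupSpec",
    "Participant",
    "CohortDataset",
    "draw_participant",
    "generate_cohort",
    "recovery_dataset",
    "POOLED_SPEC",
]

PARAM_NAMES = ("Rf", "Rs", "Lf", "Ls", "sigma_state", "sigma_output")
RATE_NAMES = ("Rf", "Rs", "Lf", "Ls")


@dataclass(frozen=True)
class GroupSpec:
    """Truncated-normal group distribution of the six dual-rate parameters.

    Rates are truncated to [0, 1]; noise SDs to (0, inf).  Draws are
    re-sampled until the dual-rate orderings Rf < Rs and Ls < Lf hold.
    """

    mu: dict[str, float]
    sd: dict[str, float]
    n_participants: int = 20
    label: str = "group"

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.mu) | set(PARAM_NAMES) - set(self.sd)
        if missing:
            raise ValueError(f"missing parameters in spec: {sorted(missing)}")
        for name in RATE_NAMES:
            if not (0.0 < self.mu[name] < 1.0):
                raise ValueError(f"mean of rate {name} must lie in (0, 1)")
        for name in PARAM_NAMES:
            if self.sd[name] < 0:
                raise ValueError("SDs must be non-negative")


# Pooled group-level posterior means/SDs of the published fits (mean of the
# two groups' hyperparameter estimates); used as the default generative
# range for recovery experiments.
POOLED_SPEC = GroupSpec(
    mu={
        "Rf": (0.7765 + 0.9092) / 2,
        "Rs": (0.9962 + 0.9972) / 2,
        "Lf": (0.0700 + 0.0597) / 2,
        "Ls": (0.0151 + 0.0187) / 2,
        "sigma_state": (0.0343 + 0.0239) / 2,
        "sigma_output": (0.1076 + 0.0942) / 2,
    },
    sd={
        "Rf": (0.0878 + 0.0175) / 2,
        "Rs": (0.0010 + 0.0006) / 2,
        "Lf": (0.0391 + 0.0114) / 2,
        "Ls": (0.0051 + 0.0032) / 2,
        "sigma_state": (0.0150 + 0.0124) / 2,
        "sigma_output": (0.0624 + 0.0385) / 2,
    },
    n_participants=20,
    label="pooled",
)


def _truncnorm_draw(rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0.0:
        if not (lo <= mu <= hi):
            raise ValueError("degenerate spec: mean outside truncation bounds")
        return mu
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def draw_participant(
    spec: GroupSpec, rng: np.random.Generator, max_redraws: int = 1000
) -> DualRateParams:
    """Draw one participant's parameters; redraw until the orderings hold."""
    for _ in range(max_redraws):
        vals = {}
        for name in PARAM_NAMES:
            lo, hi = (0.0, 1.0) if name in RATE_NAMES else (0.0, np.inf)
            vals[name] = _truncnorm_draw(rng, spec.mu[name], spec.sd[name], lo, hi)
        if 0.0 < vals["Rf"] < vals["Rs"] < 1.0 and 0.0 < vals["Ls"] < vals["Lf"] < 1.0:
            return DualRateParams(**vals)
    raise RuntimeError(
        f"could not satisfy ordering constraints after {max_redraws} redraws "
        "(degenerate group spec)"
    )


@dataclass(frozen=True)
class Participant:
    id: str
    group: str
    true_params: DualRateParams
    series: AdaptationSeries


@dataclass(frozen=True)
class CohortDataset:
    """Participants sharing one schedule, with generative truth retained."""

    participants: tuple[Participant, ...]
    schedule: TrialSchedule
    label: str = ""

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def observations(self) -> pd.DataFrame:
        return pd.concat(
            [
                p.series.to_frame().assign(group=p.group)
                for p in self.participants
            ],
            ignore_index=True,
        )[["participant_id", "group", "trial_index", "ai"]]

    @property
    def truth(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            row = {"participant_id": p.id}
            row.update(zip(PARAM_NAMES, p.true_params.as_array()))
            rows.append(row)
        return pd.DataFrame(rows)

    def ai_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(probe trial indices, participants x probes AI matrix)."""
        idx = np.asarray(self.participants[0].series.probe_trial_indices)
        mat = np.vstack([np.asarray(p.series.ai) for p in self.participants])
        return idx, mat

    def to_csv(self, obs_path: str | Path, truth_path: str | Path | None = None) -> None:
        self.observations.to_csv(obs_path, index=False)
        if truth_path is not None:
            self.truth.to_csv(truth_path, index=False)


def _simulate_participant(
    pid: str, group: str, params: DualRateParams, schedule: TrialSchedule, rng
) -> Participant:
    sim = simulate(params, schedule, seed=rng)
    ec = sim["trial_type"] == "error_clamp"
    series = AdaptationSeries(
        participant_id=pid,
        probe_trial_indices=sim.loc[ec, "index"].to_numpy(),
        ai=sim.loc[ec, "y"].to_numpy(),
    )
    return Participant(id=pid, group=group, true_params=params, series=series)


def generate_cohort(
    spec_a: GroupSpec,
    spec_b: GroupSpec | None = None,
    schedule: TrialSchedule | None = None,
    seed: int | np.random.Generator | None = None,
) -> CohortDataset | tuple[CohortDataset, CohortDataset]:
    """Generate one or two synthetic cohorts on a shared schedule.

    Per participant: draw true parameters from the group spec, run the
    stochastic dual-rate simulation, record the noisy outputs at EC probes
    as the observed AI series.
    """
    schedule = schedule or build_schedule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def one(spec: GroupSpec) -> CohortDataset:
        parts = []
        for i in range(spec.n_participants):
            params = draw_participant(spec, rng)
            parts.append(
                _simulate_participant(f"{spec.label}_{i + 1:02d}", spec.label, params, schedule, rng)
            )
        return CohortDataset(participants=tuple(parts), schedule=schedule, label=spec.label)

    if spec_b is None:
        return one(spec_a)
    return one(spec_a), one(spec_b)


def recovery_dataset(
    n: int = 20,
    seed: int | np.random.Generator | None = None,
    spec: GroupSpec | None = None,
    schedule: TrialSchedule | None = None,
) -> CohortDataset:
    """Synthetic-recovery cohort: n artificial participants with parameters
    in the range of the published group estimates, on the default schedule."""
    if n < 2:
        raise ValueError("need at least 2 participants")
    base = spec or POOLED_SPEC
    spec_n = GroupSpec(mu=base.mu, sd=base.sd, n_participants=n, label="recovery")
    return generate_cohort(spec_n, schedule=schedule, seed=seed)
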