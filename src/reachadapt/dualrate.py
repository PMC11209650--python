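"""Two-state (dual-rate) trial-by-trial adaptation dynamics.

Net adaptation is the sum of a fast process (high learning rate, low
retention) and a slow process (low learning rate, high retention).  With
states ``xf``, ``xs``, retention rates ``Rf``, ``Rs`` and learning rates
``Lf``, ``Ls``::

    y(n)    = xf(n) + xs(n) + eps_output
    e(n)    = f(n) - y(n)            (0 on error-clamp trials)
    xf(n+1) = Rf * xf(n) + Lf * e(n) + eps_f
    xs(n+1) = Rs * xs(n) + Ls * e(n) + eps_s

where ``f(n)`` is the applied perturbation in adaptation-index (AI) units
(+1 CW field, -1 CCW, 0 null), the state noises ``eps_f``, ``eps_s`` are
independent N(0, sigma_state) draws and the output noise is
N(0, sigma_output).  The rates satisfy 0 < Rf < Rs < 1 and 0 < Ls < Lf < 1.

On error-clamp trials the channel removes the movement error, so the states
purely decay (e = 0) while the output y still expresses the adaptive state —
this is what makes EC trials usable as probes of adaptation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedule import TrialSchedule, perturbation_sequence

__all__ = [
    "DualRateParams",
    "DualRateState",
    "step",
    "simulate",
    "fixed_point_oracle",
    "FIG6_SHARED",
    "FIG6_RF_PATIENT",
    "FIG6_RF_CONTROL",
]

# Deterministic-simulation parameter set used in the published group
# comparison: shared rates, with only the fast retention rate differing.
FIG6_SHARED = {"Ls": 0.0169, "Lf": 0.0649, "Rs": 0.9967}
FIG6_RF_PATIENT = 0.7765
FIG6_RF_CONTROL = 0.9092


@dataclass(frozen=True)
class DualRateParams:
    """Retention/learning rates and noise SDs of one participant."""

    Rf: float
    Rs: float
    Lf: float
    Ls: float
    sigma_state: float = 0.0
    sigma_output: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.Rf < self.Rs < 1.0):
            raise ValueError("retention rates must satisfy 0 < Rf < Rs < 1")
        if not (0.0 < self.Ls < self.Lf < 1.0):
            raise ValueError("learning rates must satisfy 0 < Ls < Lf < 1")
        if self.sigma_state < 0 or self.sigma_output < 0:
            raise ValueError("noise SDs must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.Rf, self.Rs, self.Lf, self.Ls, self.sigma_state, self.sigma_output]
        )

    @classmethod
    def unchecked(cls, Rf, Rs, Lf, Ls, sigma_state=0.0, sigma_output=0.0):
        """Bypass the ordering invariants (boundary/degenerate oracles only)."""
        obj = object.__new__(cls)
        for k, v in dict(
            Rf=Rf, Rs=Rs, Lf=Lf, Ls=Ls, sigma_state=sigma_state, sigma_output=sigma_output
        ).items():
            object.__setattr__(obj, k, float(v))
        return obj

    @classmethod
    def fig6(cls, group: str) -> "DualRateParams":
        """The deterministic simulation parameter sets ('patient' or 'control')."""
        rf = {"patient": FIG6_RF_PATIENT, "control": FIG6_RF_CONTROL}[group]
        return cls(Rf=rf, **FIG6_SHARED)


@dataclass(frozen=True)
class DualRateState:
    xf: float
    xs: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.xf) and math.isfinite(self.xs)):
            raise ValueError("state must be finite")

    @property
    def x(self) -> float:
        return self.xf + self.xs


def step(
    state: DualRateState,
    params: DualRateParams,
    f: float,
    is_error_clamp: bool,
    rng: np.random.Generator | None = None,
) -> tuple[DualRateState, float]:
    """Advance the dynamics by one trial; returns (next_state, output y)."""
    if rng is None or (params.sigma_state == 0 and params.sigma_output == 0):
        eps_out = eps_f = eps_s = 0.0
    else:
        eps_out = rng.normal(0.0, params.sigma_output)
        eps_f = rng.normal(0.0, params.sigma_state)
        eps_s = rng.normal(0.0, params.sigma_state)
    y = state.xf + state.xs + eps_out
    e = 0.0 if is_error_clamp else f - y
    nxt = DualRateState(
        xf=params.Rf * state.xf + params.Lf * e + eps_f,
        xs=params.Rs * state.xs + params.Ls * e + eps_s,
    )
    return nxt, y


def simulate(
    params: DualRateParams,
    schedule: TrialSchedule,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the dual-rate dynamics over a full schedule.

    Starts from (xf, xs) = (0, 0).  Returns one row per trial with the
    pre-update states ``xf``, ``xs``, net adaptation ``x = xf + xs`` and
    the (noisy) output ``y``.  ``seed=None`` gives the noise-free
    deterministic trajectory regardless of the noise SDs.

    At EC trials, ``x`` is the model's adaptation index and ``y`` the
    observed (noisy) AI.
    """
    f, is_ec = perturbation_sequence(schedule)
    rng = None
    if seed is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(schedule)
    xf = np.empty(n)
    xs = np.empty(n)
    y = np.empty(n)
    state = DualRateState(0.0, 0.0)
    for i in range(n):
        xf[i], xs[i] = state.xf, state.xs
        state, y[i] = step(state, params, f[i], is_ec[i], rng)
    df = schedule.to_frame()
    df["xf"], df["xs"], df["x"], df["y"] = xf, xs, xf + xs, y
    return df


def probe_series(sim: pd.DataFrame, observed: bool = True) -> pd.DataFrame:
    """Restrict a simulation frame to EC trials (the probes where AI is
    measurable); ``observed`` selects the noisy output y, else the net x."""
    out = sim[sim["trial_type"] == "error_clamp"][["index", "x", "y"]].copy()
    out["ai"] = out["y"] if observed else out["x"]
    return out[["index", "ai"]].reset_index(drop=True)


def fixed_point_oracle(params: DualRateParams, f_const: float) -> float:
    """Closed-form asymptote of the noise-free dynamics under a constant
    perturbation (no error-clamp trials): solves (I - A) x* = L f.

    A is the state-update matrix with error feedback folded in:
    ``A = [[Rf - Lf, -Lf], [-Ls, Rs - Ls]]``.  Rejects parameter sets for
    which the dynamics are not contracting (spectral radius >= 1).
    """
    A = np.array(
        [
            [params.Rf - params.Lf, -params.Lf],
            [-params.Ls, params.Rs - params.Ls],
        ]
    )
    if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
        raise ValueError("unstable parameter combination: no fixed point")
    L = np.array([params.Lf, params.Ls])
    x_star = np.linalg.solve(np.eye(2) - A, L * f_const)
    return float(x_star.sum())
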