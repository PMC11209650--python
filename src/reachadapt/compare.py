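"""Group comparison: HDI, ROPE decisions and phase-wise AI tests.

Two groups fitted independently (same model, same priors) are compared on
the posterior of the difference of their group-mean hyperparameters.  The
region of practical equivalence (ROPE) around zero has half-width

    0.1 * sqrt((var_1 + var_2) / 2)

where var_1, var_2 are the variances of the two groups' posterior
distributions of the hyperparameter.  If the 95% HDI of the difference lies
entirely inside the ROPE the groups are declared practically equivalent
("no_difference"); entirely outside, "difference"; otherwise the decision
is withheld.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import RATE_NAMES
from .kinematics import AdaptationSeries
from .schedule import TrialSchedule

__all__ = [
    "Decision",
    "RopeDecision",
    "PhaseSummary",
    "hdi",
    "rope_halfwidth",
    "rope_decide",
    "compare_groups",
    "phase_probe_indices",
    "phase_means",
    "two_sample_test",
]


class Decision(str, Enum):
    NO_DIFFERENCE = "no_difference"
    DIFFERENCE = "difference"
    WITHHELD = "withheld"


@dataclass(frozen=True)
class RopeDecision:
    parameter: str
    rope_halfwidth: float
    hdi: tuple[float, float]
    decision: Decision


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, float))
    n = len(x)
    k = int(np.ceil(mass * n))
    if n < max(2, k) or k < 1:
        raise ValueError("too few samples to resolve the interval")
    if k == n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def rope_halfwidth(sigma1: float, sigma2: float) -> float:
    """ROPE half-width from the two groups' posterior SDs."""
    if sigma1 < 0 or sigma2 < 0:
        raise ValueError("posterior SDs must be non-negative")
    return 0.1 * np.sqrt((sigma1**2 + sigma2**2) / 2.0)


def rope_decide(
    diff_samples: np.ndarray, rope: float, mass: float = 0.95, parameter: str = ""
) -> RopeDecision:
    """Three-way HDI + ROPE decision on a group-difference posterior."""
    lo, hi = hdi(diff_samples, mass)
    if -rope <= lo and hi <= rope:
        decision = Decision.NO_DIFFERENCE
    elif hi < -rope or lo > rope:
        decision = Decision.DIFFERENCE
    else:
        decision = Decision.WITHHELD
    return RopeDecision(parameter=parameter, rope_halfwidth=rope, hdi=(lo, hi), decision=decision)


def compare_groups(
    results_a,
    results_b,
    parameters: tuple[str, ...] = RATE_NAMES,
    mass: float = 0.95,
) -> pd.DataFrame:
    """ROPE decisions on the group-mean hyperparameters of two fits.

    Draws from the two independent fits are pooled across chains and paired
    after truncation to a common length to form the difference posterior
    (group A minus group B).
    """
    rows = []
    for nm in parameters:
        a = results_a.hyper_samples(nm, "mu")
        b = results_b.hyper_samples(nm, "mu")
        n = min(len(a), len(b))
        diff = a[:n] - b[:n]
        rope = rope_halfwidth(a.std(ddof=1), b.std(ddof=1))
        dec = rope_decide(diff, rope, mass=mass, parameter=nm)
        rows.append(
            {
                "parameter": nm,
                "rope": rope,
                "hdi_low": dec.hdi[0],
                "hdi_high": dec.hdi[1],
                "decision": dec.decision.value,
            }
        )
    return pd.DataFrame(rows)


# --- phase-wise AI summaries --------------------------------------------

PHASES = ("cw_plateau", "ccw_end", "recovery_start")


def phase_probe_indices(
    schedule: TrialSchedule,
    n_cw_plateau: int = 15,
    n_ccw_end: int = 3,
    n_recovery: int = 12,
) -> dict[str, list[int]]:
    """Probe trial indices of the three comparison phases: the last 15 EC
    trials of the CW block, the last 3 of the CCW block, and the first 12
    of the final EC block."""
    cw = schedule.probes_in_phase("cw")
    ccw = schedule.probes_in_phase("ccw")
    fin = schedule.probes_in_phase("final_ec")
    if len(cw) < n_cw_plateau or len(ccw) < n_ccw_end or len(fin) < n_recovery:
        raise ValueError("schedule has too few probes for the phase definitions")
    return {
        "cw_plateau": cw[-n_cw_plateau:],
        "ccw_end": ccw[-n_ccw_end:],
        "recovery_start": fin[:n_recovery],
    }


@dataclass(frozen=True)
class PhaseSummary:
    participant_id: str
    means: dict[str, float]


def phase_means(series: AdaptationSeries, schedule: TrialSchedule, **kw) -> PhaseSummary:
    """Per-participant mean AI over each comparison phase."""
    phase_idx = phase_probe_indices(schedule, **kw)
    idx = np.asarray(series.probe_trial_indices)
    ai = np.asarray(series.ai)
    means = {}
    for phase, wanted in phase_idx.items():
        mask = np.isin(idx, wanted)
        if mask.sum() != len(wanted):
            raise ValueError(f"series is missing probes for phase {phase}")
        means[phase] = float(ai[mask].mean())
    return PhaseSummary(participant_id=series.participant_id, means=means)


def two_sample_test(
    a: np.ndarray, b: np.ndarray, equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sample t test; returns (t, df, two-sided p).

    ``equal_var=True`` gives the Student (pooled-variance) test with
    df = n1 + n2 - 2; the default is Welch's test with Satterthwaite df.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if equal_var and a.var(ddof=1) + b.var(ddof=1) == 0:
        raise ValueError("degenerate zero-variance samples")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)
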