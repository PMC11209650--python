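"""Hierarchical Bayesian estimation of the dual-rate model.

``HierarchicalDualRate`` is a statsmodels-style model object: built from a
cohort's adaptation-index observations and the trial schedule, its ``fit``
runs MCMC and returns a ``HierarchicalDualRateResults`` carrying posterior
draws, summaries, convergence diagnostics, posterior-predictive simulation
and parameter-recovery scoring.

Hierarchy.  Each participant's rates (Rf, Rs, Lf, Ls) have truncated-normal
priors on [0, 1] whose mean mu and SD sigma are group-level parameters; the
noise SDs (sigma_state, sigma_output) have normal priors truncated to > 0,
again with group-level (mu, sigma).  Hyperpriors: the rate group means have
truncated-normal hyperpriors on [0, 1] with (mean, SD) = (0.85, 0.5) for Rf,
(0.998, 0.01) for Rs and (0.1, 0.5) for both learning rates — the retention
means deliberately informative to aid convergence; all group SDs have
half-Cauchy(0, 0.5) hyperpriors and the noise group means half-Cauchy(0, 1).

The per-participant likelihood is the exact (Kalman-filter) marginal of the
linear-Gaussian dual-rate dynamics, evaluated at the error-clamp probes —
the only trials on which the adaptation index is observed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine
from .cohort import PARAM_NAMES, CohortDataset
from .dualrate import DualRateParams, simulate
from .schedule import TrialSchedule, perturbation_sequence

__all__ = [
    "HierarchicalPriorConfig",
    "McmcConfig",
    "HierarchicalDualRate",
    "HierarchicalDualRateResults",
]


@dataclass(frozen=True)
class HierarchicalPriorConfig:
    """Hyperprior constants.  ``rate_mu_mean``/``rate_mu_sd`` give the
    truncated-normal hyperprior on each rate's group mean, in the order
    (Rf, Rs, Lf, Ls)."""

    rate_mu_mean: tuple[float, ...] = (0.85, 0.998, 0.1, 0.1)
    rate_mu_sd: tuple[float, ...] = (0.5, 0.01, 0.5, 0.5)
    sd_half_cauchy_scale: float = 0.5
    noise_mu_half_cauchy_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.rate_mu_mean) != 4 or len(self.rate_mu_sd) != 4:
            raise ValueError("rate hyperprior constants must have length 4")
        if any(s <= 0 for s in self.rate_mu_sd):
            raise ValueError("hyperprior scales must be positive")

    def less_informative(self, retention_sd: float = 0.5) -> "HierarchicalPriorConfig":
        """Robustness variant: widen the retention-mean hyperpriors."""
        return replace(
            self,
            rate_mu_mean=(0.85, 0.85, 0.1, 0.1),
            rate_mu_sd=(self.rate_mu_sd[0], retention_sd, self.rate_mu_sd[2], self.rate_mu_sd[3]),
        )


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings.  The full profile matches the published analysis
    (4 chains, 3,000 warmup, 25,000 kept iterations, no thinning); the
    reduced profile (4 x 10,000, 2,000 warmup) is for tests and quick runs —
    adaptive random-walk chains need a few thousand warmup iterations to
    tune their proposal covariances, so the reduced profile keeps a longer
    warmup fraction than the full one."""

    n_chains: int = 4
    n_warmup: int = 3000
    n_iter: int = 25000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def from_profile(cls, profile: str, seed: int = 0) -> "McmcConfig":
        if profile == "full":
            return cls(seed=seed)
        if profile == "reduced":
            return cls(n_warmup=2000, n_iter=10000, seed=seed)
        raise ValueError(f"unknown MCMC profile {profile!r}")


# initial proposal SDs: participant (Rf, Rs, Lf, Ls, ss, so), then hyper
# (mu, sigma) pairs in the same parameter order
_INIT_PROP_SD = np.array(
    [0.02, 0.002, 0.01, 0.003, 0.005, 0.01]
    + [0.02, 0.01, 0.002, 0.001, 0.01, 0.005, 0.003, 0.002, 0.005, 0.003, 0.01, 0.005]
)

_INIT_CENTER = {
    "Rf": 0.85, "Rs": 0.995, "Lf": 0.07, "Ls": 0.02,
    "sigma_state": 0.03, "sigma_output": 0.1,
}
_INIT_SD_CENTER = {
    "Rf": 0.05, "Rs": 0.002, "Lf": 0.02, "Ls": 0.005,
    "sigma_state": 0.01, "sigma_output": 0.04,
}


class HierarchicalDualRate:
    """Hierarchical dual-rate model for one group of participants.

    Parameters
    ----------
    observations : DataFrame with columns participant_id, trial_index, ai
        Observed adaptation indices at error-clamp probes.
    schedule : TrialSchedule shared by all participants.
    priors : hyperprior constants (defaults to the published configuration).
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        schedule: TrialSchedule,
        priors: HierarchicalPriorConfig | None = None,
    ):
        self.schedule = schedule
        self.priors = priors or HierarchicalPriorConfig()

        ec = set(schedule.ec_trial_indices)
        bad = set(observations["trial_index"].unique()) - ec
        if bad:
            raise ValueError(f"observations at non-error-clamp trials: {sorted(bad)[:5]}")

        pids = list(pd.unique(observations["participant_id"]))
        probe_idx = np.array(sorted(observations["trial_index"].unique()))
        y_mat = np.empty((len(pids), len(probe_idx)))
        for i, pid in enumerate(pids):
            sub = observations[observations["participant_id"] == pid].set_index("trial_index")
            if not np.array_equal(np.sort(sub.index.to_numpy()), probe_idx):
                raise ValueError(f"participant {pid} is missing probes")
            y_mat[i] = sub.loc[probe_idx, "ai"].to_numpy()
        self.participant_ids = pids
        self.probe_trial_indices = probe_idx
        self.y = y_mat

        f, is_ec = perturbation_sequence(schedule)
        self._f = np.asarray(f, dtype=np.float64)
        self._is_ec = np.asarray(is_ec, dtype=np.bool_)
        obs = np.zeros(len(schedule), dtype=np.bool_)
        obs[probe_idx - 1] = True
        self._obs = obs

    # -- constructors -------------------------------------------------
    @classmethod
    def from_dataframe(cls, df, schedule, priors=None) -> "HierarchicalDualRate":
        return cls(df, schedule, priors)

    @classmethod
    def from_cohort(cls, cohort: CohortDataset, priors=None) -> "HierarchicalDualRate":
        obs = cohort.observations[["participant_id", "trial_index", "ai"]]
        return cls(obs, cohort.schedule, priors)

    # -- dimensions / names -------------------------------------------
    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_dim(self) -> int:
        return 6 * self.n_participants + 12

    @property
    def param_names(self) -> list[str]:
        names = []
        for pid in self.participant_ids:
            names += [f"{nm}[{pid}]" for nm in PARAM_NAMES]
        for nm in PARAM_NAMES:
            names += [f"{nm}_mu", f"{nm}_sd"]
        return names

    # -- densities (exposed for testing and diagnostics) --------------
    def loglike(self, params: DualRateParams | np.ndarray, participant: int = 0) -> float:
        """Exact marginal log-likelihood of one participant's probe series."""
        th = params.as_array() if isinstance(params, DualRateParams) else np.asarray(params, float)
        return float(
            _engine.kalman_loglik(th, self._f, self._is_ec, self._obs, self.y[participant])
        )

    def logpost(self, theta: np.ndarray) -> float:
        """Joint log-density (up to an additive constant)."""
        return float(
            _engine.hierarchical_logpost(
                np.asarray(theta, float), self.n_participants, self._f, self._is_ec,
                self._obs, self.y,
                np.asarray(self.priors.rate_mu_mean), np.asarray(self.priors.rate_mu_sd),
            )
        )

    # -- fitting -------------------------------------------------------
    def _initial_theta(self, rng: np.random.Generator) -> np.ndarray:
        """Over-dispersed but always-valid initial state (rates strictly
        inside (0, 1) with the orderings satisfied, SDs positive)."""

        def jitter(nm: str) -> float:
            c = _INIT_CENTER[nm]
            v = c * (1 + 0.05 * rng.standard_normal())
            if nm in ("Rf", "Rs", "Lf", "Ls"):
                v = float(np.clip(v, 0.005, 0.995 if nm != "Rs" else 0.999))
            return max(v, 1e-4)

        theta = np.empty(self.n_dim)
        blocks = list(range(self.n_participants)) + ["hyper"]
        for b in blocks:
            off = 6 * self.n_participants if b == "hyper" else 6 * b
            vals = {nm: jitter(nm) for nm in PARAM_NAMES}
            vals["Rf"] = min(vals["Rf"], 0.98 * vals["Rs"])
            vals["Ls"] = min(vals["Ls"], 0.5 * vals["Lf"])
            if b == "hyper":
                for j, nm in enumerate(PARAM_NAMES):
                    theta[off + 2 * j] = vals[nm]
                    theta[off + 2 * j + 1] = _INIT_SD_CENTER[nm] * (
                        1 + 0.1 * abs(rng.standard_normal())
                    )
            else:
                for j, nm in enumerate(PARAM_NAMES):
                    theta[off + j] = vals[nm]
        return theta

    def fit(
        self,
        mcmc: McmcConfig | None = None,
        profile: str | None = None,
        seed: int | None = None,
        progress: bool = False,
    ) -> "HierarchicalDualRateResults":
        """Run MCMC and return a results object.

        Either pass a full ``McmcConfig`` or a profile name ("full" or
        "reduced").  Chains run sequentially with distinct sub-seeds and
        over-dispersed initial values; identical configs give identical
        draws.
        """
        if mcmc is None:
            mcmc = McmcConfig.from_profile(profile or "full", seed=seed or 0)
        elif seed is not None:
            mcmc = replace(mcmc, seed=seed)

        m0 = np.asarray(self.priors.rate_mu_mean, float)
        s0 = np.asarray(self.priors.rate_mu_sd, float)
        all_draws = []
        rates = []
        t0 = time.time()
        for c in range(mcmc.n_chains):
            chain_seed = (mcmc.seed * 1_000_003 + 7919 * c + 1) % (2**31 - 1)
            rng = np.random.default_rng(chain_seed)
            theta0 = self._initial_theta(rng)
            draws, acc = _engine.run_chain(
                self.y, self._f, self._is_ec, self._obs, theta0,
                mcmc.n_warmup, mcmc.n_iter, chain_seed, m0, s0, _INIT_PROP_SD,
            )
            if mcmc.thin > 1:
                draws = draws[:: mcmc.thin]
            all_draws.append(draws)
            rates.append(acc)
            if progress:
                print(f"chain {c + 1}/{mcmc.n_chains} done ({time.time() - t0:.1f}s)")
        return HierarchicalDualRateResults(
            model=self,
            draws=np.stack(all_draws),
            acceptance=np.stack(rates),
            mcmc=mcmc,
        )


@dataclass
class HierarchicalDualRateResults:
    """Posterior draws and derived quantities of a hierarchical fit."""

    model: HierarchicalDualRate
    draws: np.ndarray  # (chain, draw, dim)
    acceptance: np.ndarray
    mcmc: McmcConfig
    _idata: object = field(default=None, repr=False)

    # -- access --------------------------------------------------------
    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    def samples(self, name: str) -> np.ndarray:
        """All post-warmup draws of one parameter, chains pooled."""
        i = self.param_names.index(name)
        return self.draws[:, :, i].reshape(-1)

    def hyper_samples(self, param: str, which: str = "mu") -> np.ndarray:
        return self.samples(f"{param}_{which}")

    def posterior_mean(self, name: str) -> float:
        return float(self.samples(name).mean())

    def participant_posterior_means(self) -> pd.DataFrame:
        rows = []
        for pid in self.model.participant_ids:
            rows.append(
                {"participant_id": pid}
                | {nm: self.posterior_mean(f"{nm}[{pid}]") for nm in PARAM_NAMES}
            )
        return pd.DataFrame(rows)

    def _participant_mean_draws(self, nm: str) -> np.ndarray:
        idx = [self.param_names.index(f"{nm}[{pid}]") for pid in self.model.participant_ids]
        return self.draws[:, :, idx].mean(axis=2).reshape(-1)

    def to_inference_data(self):
        """arviz InferenceData view of the draws (built lazily)."""
        if self._idata is None:
            import arviz as az

            data = {nm: self.draws[:, :, i] for i, nm in enumerate(self.param_names)}
            self._idata = az.from_dict(posterior=data)
        return self._idata

    # -- summaries -----------------------------------------------------
    def summary(self, hdi_mass: float = 0.90) -> pd.DataFrame:
        """Posterior mean and HDI per group-level parameter, plus the
        across-participant average of the individual parameters (rows
        suffixed '*'), in a layout mirroring the published tables."""
        from .compare import hdi

        rows = []
        for nm in PARAM_NAMES:
            for suffix, vec in (
                ("_mu", self.samples(f"{nm}_mu")),
                ("_sd", self.samples(f"{nm}_sd")),
            ):
                lo, hi = hdi(vec, hdi_mass)
                rows.append(
                    {"parameter": nm + suffix, "mean": vec.mean(), "hdi_low": lo, "hdi_high": hi}
                )
        for nm in PARAM_NAMES:
            vec = self._participant_mean_draws(nm)
            lo, hi = hdi(vec, hdi_mass)
            rows.append(
                {"parameter": nm + "*", "mean": vec.mean(), "hdi_low": lo, "hdi_high": hi}
            )
        return pd.DataFrame(rows)

    def diagnostics(self) -> pd.DataFrame:
        """Split-chain rank-normalised R-hat, bulk ESS and MCSE per
        parameter; per-participant parameters are additionally summarised
        by their across-participant mean (rows suffixed '*')."""
        import arviz as az

        if self.draws.shape[0] < 2:
            raise ValueError("R-hat requires at least 2 chains")
        rows = []
        for i, nm in enumerate(self.param_names):
            chains = self.draws[:, :, i]
            ess = float(az.ess(chains))
            rhat = float(az.rhat(chains))
            mcse = float(chains.std(ddof=1) / np.sqrt(ess)) if ess > 0 else np.nan
            rows.append({"parameter": nm, "ess": ess, "rhat": rhat, "mcse": mcse})
        df = pd.DataFrame(rows)

        # across-participant means of the individual-level diagnostics
        extra = []
        for nm in PARAM_NAMES:
            mask = df["parameter"].str.startswith(f"{nm}[")
            sub = df[mask]
            extra.append(
                {
                    "parameter": nm + "*",
                    "ess": sub["ess"].mean(),
                    "rhat": sub["rhat"].mean(),
                    "mcse": sub["mcse"].mean(),
                }
            )
        hyper = df[df["parameter"].str.endswith(("_mu", "_sd"))]
        return pd.concat([hyper, pd.DataFrame(extra)], ignore_index=True)

    # -- model checking ------------------------------------------------
    def posterior_predictive(
        self, n_draws: int = 500, seed: int | None = None, include_states: bool = True
    ) -> pd.DataFrame:
        """Per-participant predicted AI time courses: for each participant,
        draw parameter sets from the posterior, simulate the stochastic
        dynamics over the schedule, and average.

        Returns a frame with one row per participant x trial: predicted
        mean and SE of the net output and of the fast/slow states.
        """
        rng = np.random.default_rng(seed)
        n_chain, n_iter, _ = self.draws.shape
        out = []
        for pid in self.model.participant_ids:
            cols = [self.param_names.index(f"{nm}[{pid}]") for nm in PARAM_NAMES]
            acc = []
            for _ in range(n_draws):
                c = rng.integers(n_chain)
                d = rng.integers(n_iter)
                th = self.draws[c, d, cols]
                params = DualRateParams.unchecked(*th)
                sim = simulate(params, self.model.schedule, seed=rng)
                acc.append(sim[["xf", "xs", "x", "y"]].to_numpy())
            cube = np.stack(acc)  # (draws, trials, 4)
            mean = cube.mean(axis=0)
            se = cube.std(axis=0, ddof=1) / np.sqrt(n_draws)
            frame = self.model.schedule.to_frame()
            frame["participant_id"] = pid
            for k, nm in enumerate(["xf", "xs", "x", "y"]):
                frame[nm + "_mean"] = mean[:, k]
                frame[nm + "_se"] = se[:, k]
            out.append(frame)
        return pd.concat(out, ignore_index=True)

    def parameter_recovery(self, truth: CohortDataset | pd.DataFrame) -> pd.Series:
        """Mean absolute error of posterior means vs generative truth,
        per parameter, across participants."""
        tdf = truth.truth if isinstance(truth, CohortDataset) else truth
        est = self.participant_posterior_means().set_index("participant_id")
        tdf = tdf.set_index("participant_id")
        if set(est.index) != set(tdf.index):
            raise ValueError("participant sets of fit and truth differ")
        tdf = tdf.loc[est.index]
        return (est[list(PARAM_NAMES)] - tdf[list(PARAM_NAMES)]).abs().mean()

    # -- persistence ----------------------------------------------------
    def draws_frame(self, thin: int = 1) -> pd.DataFrame:
        n_chain, n_iter, dim = self.draws.shape
        it = np.arange(0, n_iter, thin)
        recs = []
        for c in range(n_chain):
            for i, nm in enumerate(self.param_names):
                recs.append(
                    pd.DataFrame(
                        {"chain": c, "iter": it, "parameter": nm,
                         "value": self.draws[c, it, i]}
                    )
                )
        return pd.concat(recs, ignore_index=True)
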