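"""Bayesian MCMC estimation of (S, theta) from frequency counts.

The joint posterior of total richness S and the TAD parameters theta is
sampled by Metropolis-within-Gibbs: componentwise Gaussian random-walk
proposals on a transformed parameter scale (log for positive parameters),
and a Gibbs draw of S - S_obs from its conditional, which under the flat
prior on S is negative binomial with size S_obs + 1 and zero-count
probability p_0(theta).  Proposal scales adapt towards 30% acceptance by
Robbins-Monro during burn-in only, preserving detailed balance in the
retained chain.

Priors: S uniform on [S_obs, s_max]; transformed theta components
independent N(0, 10^2), vague enough for the likelihood to dominate.

Model choice across the four candidate families uses DIC (posterior mean
deviance plus the effective parameter count p_D), with AICc from the
best-likelihood draw reported alongside; ties in DIC go to the family
with fewer parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .abundance_models import _N_PARAMS, TADModel, _sichel_log_pmf, tad_log_pmf
from .data_model import FrequencyCounts
from .errors import (
    AICcUndefinedError,
    ProposalDegenerateError,
    RareSphereError,
    RichnessCapError,
)

__all__ = [
    "MCMCConfig",
    "PosteriorChain",
    "RichnessEstimate",
    "ModelSelectionResult",
    "fit_tad",
    "richness_estimate",
    "compute_dic",
    "compute_aicc",
    "select_model",
    "write_chain",
    "read_chain",
]


@dataclass(frozen=True)
class MCMCConfig:
    n_burnin: int = 100_000
    n_samples: int = 150_000
    thin: int = 10
    seed: int = 0
    s_max: int = 1_000_000
    proposal_scales: tuple[float, ...] | None = None
    target_accept: float = 0.3

    def __post_init__(self):
        if self.n_burnin <= 0 or self.n_samples <= 0 or self.thin <= 0:
            raise ValueError("n_burnin, n_samples and thin must be positive")


@dataclass(frozen=True)
class PosteriorChain:
    """Retained MCMC draws of (S, theta) with per-draw deviance."""

    family: str
    param_names: tuple[str, ...]
    S: np.ndarray  # int, every S >= s_obs
    theta: np.ndarray  # (n, d) natural scale
    deviance: np.ndarray
    s_obs: int
    config: MCMCConfig
    acceptance_rates: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.S)

    def model_at(self, i: int) -> TADModel:
        return TADModel(self.family, tuple(self.theta[i]))


@dataclass(frozen=True)
class RichnessEstimate:
    point: float  # posterior mean of S
    ci_low: float  # 2.5% posterior quantile
    ci_high: float  # 97.5% posterior quantile
    s_obs: int
    fraction_observed: float  # s_obs / point


@dataclass(frozen=True)
class ModelSelectionResult:
    families: dict  # family -> {"dic","p_d","aicc","chain","estimate"} or {"error"}
    selected: str


# ---------------------------------------------------------------------------
# parameter transforms and initialization

_TRANSFORMS = {
    # name -> (param names on natural scale, to_natural, to_transformed)
    "poisson_lognormal": ("mu", "sigma"),
    "poisson_logstudent": ("mu", "sigma", "nu"),
    "poisson_inverse_gaussian": ("chi", "psi"),
    "sichel": ("gamma", "chi", "psi"),
}
# which transformed components are logs of the natural ones
_LOG_MASK = {
    "poisson_lognormal": (False, True),
    "poisson_logstudent": (False, True, True),
    "poisson_inverse_gaussian": (True, True),
    "sichel": (False, True, True),
}


def _to_natural(family: str, z: np.ndarray) -> tuple[float, ...]:
    mask = _LOG_MASK[family]
    return tuple(np.exp(v) if lg else float(v) for v, lg in zip(z, mask))


def _to_transformed(family: str, theta: Sequence[float]) -> np.ndarray:
    mask = _LOG_MASK[family]
    return np.array([np.log(v) if lg else v for v, lg in zip(theta, mask)])


def _initial_theta(family: str, fc: FrequencyCounts) -> tuple[float, ...]:
    kv, fv = fc.arrays()
    w = fv / fv.sum()
    logk = np.log(kv.astype(float))
    mlog = float(np.dot(w, logk))
    sdlog = float(np.sqrt(max(np.dot(w, (logk - mlog) ** 2), 0.25)))
    mbar = fc.n_reads / fc.s_obs
    if family == "poisson_lognormal":
        return (mlog - 0.5, max(sdlog, 0.5))
    if family == "poisson_logstudent":
        return (mlog - 0.5, max(sdlog, 0.5), 5.0)
    # GIG families: omega = 1, scale matched to the mean count
    if family == "poisson_inverse_gaussian":
        return (mbar, 1.0 / mbar)
    return (-0.5, mbar, 1.0 / mbar)


# ---------------------------------------------------------------------------
# likelihood plumbing


class _Likelihood:
    """Caches the frequency arrays and evaluates the likelihood pieces."""

    def __init__(self, fc: FrequencyCounts, family: str, tol: float = 1e-8):
        self.family = family
        self.kv, self.fv = fc.arrays()
        self.ks = np.concatenate([[0], self.kv])
        self.s_obs = fc.s_obs
        self.log_fk_fact = float(np.sum(gammaln(self.fv + 1.0)))
        self.tol = tol

    def parts(self, theta: Sequence[float]) -> tuple[float, float]:
        """(log p_0, sum_k F_k log p_k) for the given natural theta."""
        if self.family == "sichel":
            logp = _sichel_log_pmf(theta[0], theta[1], theta[2], self.ks)
        elif self.family == "poisson_inverse_gaussian":
            logp = _sichel_log_pmf(-0.5, theta[0], theta[1], self.ks)
        else:
            model = TADModel(self.family, tuple(theta))
            logp = tad_log_pmf(model, self.ks, tol=self.tol)
        return float(logp[0]), float(np.dot(self.fv, logp[1:]))

    def full(self, S: int, logp0: float, dot: float) -> float:
        ll = (
            gammaln(S + 1.0)
            - gammaln(S - self.s_obs + 1.0)
            - self.log_fk_fact
            + dot
        )
        if S > self.s_obs:
            if not np.isfinite(logp0):
                return -np.inf
            ll += (S - self.s_obs) * logp0
        return float(ll)


def _log_prior(z: np.ndarray) -> float:
    return float(-0.5 * np.sum(z**2) / 100.0)


# ---------------------------------------------------------------------------
# the sampler


def fit_tad(
    fc: FrequencyCounts, family: str, config: MCMCConfig | None = None
) -> PosteriorChain:
    """Sample the joint posterior of (theta, S) for one TAD family.

    Reproducible: the same seed and config give a bit-identical chain.
    """
    if family not in _TRANSFORMS:
        raise ValueError(f"unknown family {family!r}")
    config = config or MCMCConfig()
    rng = np.random.default_rng(config.seed)
    lik = _Likelihood(fc, family)
    s_obs = fc.s_obs
    s_max = config.s_max
    if s_max < s_obs:
        raise ValueError("s_max below observed richness")

    names = _TRANSFORMS[family]
    d = len(names)
    z = _to_transformed(family, _initial_theta(family, fc))
    scales = (
        np.array(config.proposal_scales, dtype=float)
        if config.proposal_scales is not None
        else np.full(d, 0.15)
    )
    if len(scales) != d:
        raise ValueError("proposal_scales length mismatch")
    log_scales = np.log(scales)

    logp0, dot = lik.parts(_to_natural(family, z))
    # S init: bias-corrected Chao1-ish point, clipped to the support
    f1, f2 = fc.f(1), fc.f(2)
    S = int(np.clip(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)) + 1, s_obs, s_max))

    def theta_target(S, logp0, dot, z):
        t = dot + _log_prior(z)
        if S > s_obs:
            t += (S - s_obs) * logp0 if np.isfinite(logp0) else -np.inf
        return t

    n_iter = config.n_burnin + config.n_samples
    n_keep = config.n_samples // config.thin
    S_out = np.empty(n_keep, dtype=np.int64)
    th_out = np.empty((n_keep, d))
    dev_out = np.empty(n_keep)
    acc_burn = np.zeros(d, dtype=np.int64)
    acc_post = np.zeros(d, dtype=np.int64)
    n_post_prop = 0
    cap_hits = 0
    adapt_t = np.zeros(d)
    kept = 0

    cur_target = theta_target(S, logp0, dot, z)
    for it in range(n_iter):
        burn = it < config.n_burnin
        # --- componentwise random-walk MH on transformed theta
        for j in range(d):
            z_prop = z.copy()
            z_prop[j] += np.exp(log_scales[j]) * rng.standard_normal()
            if np.all(np.abs(z_prop) < 60.0):
                try:
                    logp0_p, dot_p = lik.parts(_to_natural(family, z_prop))
                    prop_target = theta_target(S, logp0_p, dot_p, z_prop)
                except (ValueError, FloatingPointError, RareSphereError):
                    prop_target = -np.inf
            else:
                prop_target = -np.inf
            accept = np.log(rng.random()) < prop_target - cur_target
            if accept:
                z, logp0, dot, cur_target = z_prop, logp0_p, dot_p, prop_target
                (acc_burn if burn else acc_post)[j] += 1
            if burn:
                adapt_t[j] += 1.0
                step = 1.0 / adapt_t[j] ** 0.6
                log_scales[j] += step * ((1.0 if accept else 0.0) - config.target_accept)
        if not burn:
            n_post_prop += 1
        # --- Gibbs draw of S - S_obs ~ NegBin(S_obs + 1, p0)
        p0 = np.exp(logp0)
        if p0 <= 0.0:
            S_new = s_obs
        elif p0 >= 1.0 - 1e-12:
            # p0 underflowing towards 1: integer random walk fallback
            step = max(1, int(0.1 * max(S - s_obs, 10)))
            S_prop = S + int(rng.integers(-step, step + 1))
            S_new = S
            if s_obs <= S_prop <= s_max:
                lr = (
                    gammaln(S_prop + 1.0)
                    - gammaln(S_prop - s_obs + 1.0)
                    - gammaln(S + 1.0)
                    + gammaln(S - s_obs + 1.0)
                    + (S_prop - S) * logp0
                )
                if np.log(rng.random()) < lr:
                    S_new = S_prop
        else:
            m = int(rng.negative_binomial(s_obs + 1, 1.0 - p0))
            for _ in range(200):
                if m <= s_max - s_obs:
                    break
                m = int(rng.negative_binomial(s_obs + 1, 1.0 - p0))
            else:
                m = s_max - s_obs
                cap_hits += 1
            S_new = s_obs + m
        if S_new != S:
            S = S_new
            cur_target = theta_target(S, logp0, dot, z)
        # --- record
        if not burn and (it - config.n_burnin) % config.thin == config.thin - 1:
            S_out[kept] = S
            th_out[kept] = _to_natural(family, z)
            dev_out[kept] = -2.0 * lik.full(S, logp0, dot)
            kept += 1

    if np.any(acc_burn == 0) and config.n_burnin >= 100:
        j = int(np.argmin(acc_burn))
        raise ProposalDegenerateError(
            f"proposal scale degenerate: no acceptances for {names[j]} over burn-in"
        )
    if cap_hits > 0.01 * n_iter:
        raise RichnessCapError(
            f"richness cap binding: s_max={s_max} hit in {cap_hits} draws"
        )
    rates = {
        names[j]: acc_post[j] / max(n_post_prop, 1) for j in range(d)
    }
    return PosteriorChain(
        family=family,
        param_names=tuple(names),
        S=S_out[:kept],
        theta=th_out[:kept],
        deviance=dev_out[:kept],
        s_obs=s_obs,
        config=config,
        acceptance_rates=rates,
    )


# ---------------------------------------------------------------------------
# posterior summaries and model choice


def richness_estimate(chain: PosteriorChain) -> RichnessEstimate:
    """Posterior mean and central 95% credible interval for S."""
    if len(chain) < 100:
        raise ValueError("chain too short (< 100 retained draws)")
    s = chain.S.astype(float)
    point = float(s.mean())
    lo, hi = np.quantile(s, [0.025, 0.975])
    return RichnessEstimate(
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        s_obs=chain.s_obs,
        fraction_observed=chain.s_obs / point,
    )


def compute_dic(chain: PosteriorChain, fc: FrequencyCounts) -> tuple[float, float]:
    """(DIC, p_D): mean deviance plus effective parameter count, with the
    plug-in deviance evaluated at posterior-mean theta and round(mean S)."""
    dbar = float(chain.deviance.mean())
    theta_bar = tuple(chain.theta.mean(axis=0))
    s_bar = int(round(chain.S.mean()))
    lik = _Likelihood(fc, chain.family)
    logp0, dot = lik.parts(theta_bar)
    d_hat = -2.0 * lik.full(max(s_bar, fc.s_obs), logp0, dot)
    p_d = dbar - d_hat
    return dbar + p_d, p_d


def compute_aicc(chain: PosteriorChain, fc: FrequencyCounts) -> float:
    """AICc from the lowest-deviance draw; k = dim(theta) + 1 (for S),
    effective sample size n = S_obs."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    d_min = float(chain.deviance.min())
    k = chain.theta.shape[1] + 1
    n = fc.s_obs
    if n - k - 1 <= 0:
        raise AICcUndefinedError(f"AICc undefined: n={n}, k={k}")
    return d_min + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def select_model(
    fc: FrequencyCounts,
    families: Sequence[str],
    config: MCMCConfig | None = None,
) -> ModelSelectionResult:
    """Fit each family, tabulate DIC/AICc, select the minimum-DIC family.

    A family whose fit fails is recorded with its error and skipped; the
    call fails only if every family fails.  DIC ties (within 1e-9) break
    towards the family with fewer parameters.
    """
    if len(families) < 1:
        raise ValueError("at least one family required")
    results: dict = {}
    for fam in families:
        try:
            chain = fit_tad(fc, fam, config)
            dic, p_d = compute_dic(chain, fc)
            results[fam] = {
                "dic": dic,
                "p_d": p_d,
                "aicc": compute_aicc(chain, fc),
                "chain": chain,
                "estimate": richness_estimate(chain),
            }
        except RareSphereError as exc:
            results[fam] = {"error": exc}
    ok = {f: r for f, r in results.items() if "dic" in r}
    if not ok:
        raise RareSphereError("all model fits failed")
    best = select_by_dic({f: r["dic"] for f, r in ok.items()})
    return ModelSelectionResult(families=results, selected=best)


def select_by_dic(dics: Mapping[str, float], tie_tol: float = 1e-9) -> str:
    """Family with minimum DIC; ties within ``tie_tol`` break towards the
    family with fewer parameters (parsimony)."""
    dmin = min(dics.values())
    tied = [f for f, d in dics.items() if d - dmin <= tie_tol]
    return min(tied, key=lambda f: (_N_PARAMS[f], f))


# ---------------------------------------------------------------------------
# chain serialization (TSV: iteration, S, theta..., deviance)


def write_chain(chain: PosteriorChain, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# family={chain.family} s_obs={chain.s_obs}\n")
        fh.write(
            "iteration\tS\t" + "\t".join(chain.param_names) + "\tdeviance\n"
        )
        for i in range(len(chain)):
            th = "\t".join(repr(float(v)) for v in chain.theta[i])
            fh.write(f"{i}\t{chain.S[i]}\t{th}\t{repr(float(chain.deviance[i]))}\n")


def read_chain(path) -> PosteriorChain:
    with open(path) as fh:
        header = fh.readline().strip()
    meta = dict(
        kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv
    )
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    names = tuple(c for c in df.columns if c not in ("iteration", "S", "deviance"))
    return PosteriorChain(
        family=meta.get("family", "sichel"),
        param_names=names,
        S=df["S"].to_numpy(dtype=np.int64),
        theta=df[list(names)].to_numpy(dtype=float),
        deviance=df["deviance"].to_numpy(dtype=float),
        s_obs=int(meta.get("s_obs", df["S"].min())),
        config=MCMCConfig(),
    )
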