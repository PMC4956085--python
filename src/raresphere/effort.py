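"""Required sequencing effort (RSE) by hierarchical simulation.

The RSE for a target fraction q of the total richness is the read index
at which the number of distinct species seen so far first exceeds q * S.
It is predicted by simulating repeat sequencing experiments: draw (S,
theta) from the fitted posterior, draw relative abundances from the TAD,
draw multinomial counts for a long horizon (a multiple of the present
effort), and scan a random ordering of the implied reads.

For large horizons the random ordering is never materialized.  In a
uniform random permutation of the multiset of reads, give every read an
i.i.d. Uniform(0,1) key; the first occurrence of a species with c reads
is the minimum of c keys, a Beta(1, c) variate, and the reads of that
species beyond the minimum are i.i.d. uniform above it.  The RSE is the
rank of the t-th smallest species minimum, i.e. t plus a binomial count
of other reads falling below it — an O(S) exact simulation of the
shuffle, testable against explicit shuffles at small sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance_models import TADModel, sample_community, sample_counts
from .bayes_fit import PosteriorChain
from .data_model import FrequencyCounts
from .errors import HorizonTooSmallError

__all__ = [
    "EffortConfig",
    "RSEPrediction",
    "simulate_read_sequence",
    "required_effort",
    "required_effort_from_counts",
    "predict_rse",
    "benchmark_estimators",
]


@dataclass(frozen=True)
class EffortConfig:
    n_sims: int = 80
    horizon_factor: float = 10.0
    q: float = 0.90
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")
        if self.horizon_factor < 1.0:
            raise ValueError("horizon_factor must be >= 1")
        if self.n_sims < 2:
            raise ValueError("n_sims must be >= 2")


@dataclass(frozen=True)
class RSEPrediction:
    point: float  # mean simulated RSE (reads), censored runs excluded
    pi_low: float  # 2.5% quantile over simulations
    pi_high: float  # 97.5% quantile
    n_censored: int  # simulations that never reached q*S within the horizon
    multiple_of_present: float  # point / present effort
    rse_draws: np.ndarray  # uncensored simulated RSE values


def _distinct_threshold(q: float, S_sim: int) -> int:
    """Smallest distinct-species count strictly exceeding q * S_sim."""
    return int(math.floor(q * S_sim)) + 1


def simulate_read_sequence(
    S: int,
    theta: Sequence[float],
    family: str,
    horizon: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """A randomly ordered sequence of species labels for one simulated
    experiment: community draw, multinomial counts, shuffled reads."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    model = TADModel(family, tuple(theta))
    p = sample_community(model, S, rng)
    counts = sample_counts(p, horizon, rng)
    return rng.permutation(np.repeat(np.arange(S), counts))


def required_effort(
    sequence: np.ndarray, q: float, S_sim: int
) -> int | None:
    """RSE of an explicit label sequence: the 1-based index at which the
    running distinct-label count first exceeds q * S_sim; None if the
    sequence never gets there (censored)."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if S_sim < 1:
        raise ValueError("S_sim must be >= 1")
    seq = np.asarray(sequence)
    t = _distinct_threshold(q, S_sim)
    _, first = np.unique(seq, return_index=True)
    if len(first) < t:
        return None
    return int(np.partition(first, t - 1)[t - 1]) + 1


def required_effort_from_counts(
    counts: np.ndarray, q: float, S_sim: int, rng: np.random.Generator
) -> int | None:
    """RSE of one uniformly random ordering of a read multiset, simulated
    without materializing the sequence (see module docstring)."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    t = _distinct_threshold(q, S_sim)
    if len(c) < t:
        return None
    m = rng.beta(1.0, c)  # first-occurrence keys, one per species
    mstar = np.partition(m, t - 1)[t - 1]
    below = m < mstar
    frac = (mstar - m[below]) / (1.0 - m[below])
    extra = int(rng.binomial(c[below] - 1, frac).sum())
    return t + extra


def predict_rse(
    chain: PosteriorChain,
    N_present: int,
    config: EffortConfig | None = None,
) -> RSEPrediction:
    """Predict the RSE distribution for a repeat experiment.

    Each of ``n_sims`` simulations draws (S, theta) uniformly with
    replacement from the posterior chain, simulates ``horizon_factor *
    N_present`` reads, and records the effort at which the distinct-OTU
    count first exceeds q * S.  Censored simulations (target not reached
    within the horizon) are excluded from the point and interval and
    counted in ``n_censored``.
    """
    config = config or EffortConfig()
    if len(chain) == 0:
        raise ValueError("empty chain")
    rng = np.random.default_rng(config.seed)
    horizon = int(round(config.horizon_factor * N_present))
    draws = []
    n_censored = 0
    for _ in range(config.n_sims):
        i = int(rng.integers(len(chain)))
        S = int(chain.S[i])
        model = chain.model_at(i)
        p = sample_community(model, S, rng)
        counts = sample_counts(p, horizon, rng)
        rse = required_effort_from_counts(counts, config.q, S, rng)
        if rse is None:
            n_censored += 1
        else:
            draws.append(rse)
    if not draws:
        raise HorizonTooSmallError(
            f"horizon too small: all {config.n_sims} simulations censored"
        )
    arr = np.array(draws, dtype=float)
    lo, hi = np.quantile(arr, [0.025, 0.975])
    return RSEPrediction(
        point=float(arr.mean()),
        pi_low=float(lo),
        pi_high=float(hi),
        n_censored=n_censored,
        multiple_of_present=float(arr.mean()) / N_present,
        rse_draws=arr,
    )


def benchmark_estimators(
    scenarios: Sequence[tuple[str, Sequence[float], int, int]],
    estimators: Mapping[str, Callable[[FrequencyCounts], float]],
    reps: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulation benchmark of richness estimators.

    ``scenarios`` are (family, theta, S_true, N_reads) tuples; each
    estimator maps a FrequencyCounts to a point estimate of S.  Returns
    one row per scenario x estimator with mean relative bias and RMSE;
    estimator failures count as NA, never abort the benchmark.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rows = []
    for si, (family, theta, S_true, N) in enumerate(scenarios):
        model = TADModel(family, tuple(theta))
        est_values: dict[str, list[float]] = {name: [] for name in estimators}
        for _ in range(reps):
            p = sample_community(model, S_true, rng)
            counts = sample_counts(p, N, rng)
            obs = counts[counts > 0]
            vals, freqs = np.unique(obs, return_counts=True)
            fc = FrequencyCounts(
                {int(k): int(f) for k, f in zip(vals, freqs)}
            )
            for name, fn in estimators.items():
                try:
                    est_values[name].append(float(fn(fc)))
                except Exception:
                    est_values[name].append(np.nan)
        for name in estimators:
            v = np.array(est_values[name])
            ok = np.isfinite(v)
            rel = (v[ok] - S_true) / S_true
            rows.append(
                {
                    "scenario": si,
                    "family": family,
                    "S_true": S_true,
                    "N_reads": N,
                    "estimator": name,
                    "n_ok": int(ok.sum()),
                    "mean_rel_bias": float(rel.mean()) if ok.any() else np.nan,
                    "rmse": float(np.sqrt(np.mean((v[ok] - S_true) ** 2)))
                    if ok.any()
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
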