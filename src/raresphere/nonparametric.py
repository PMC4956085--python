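"""Closed-form richness estimators, collector's curves, and saturating fits.

All the estimators here are functions of the low-order frequency counts
F_1, F_2, ... only; they are cheap companions (and simulation-test
subjects) to the parametric Bayesian fit.  Collector's curves combine
exact analytic rarefaction below the observed effort with the
sample-size-based extrapolation formula of the rarefaction/extrapolation
framework above it, and get 95% confidence bands from a bootstrap over
the estimated community composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.special import gammaln

from .data_model import AbundanceVector, FrequencyCounts, to_frequency_counts
from .errors import ACEUndefinedError

__all__ = [
    "chao1",
    "ichao1",
    "ace",
    "rarefy_richness",
    "CollectorCurve",
    "collector_curve",
    "CurveFitResult",
    "fit_saturating_curves",
]


def chao1(fc: FrequencyCounts, bias_corrected: bool = True) -> float:
    """Chao1 lower-bound richness estimator.

    Default is the bias-corrected form ``S_obs + F1(F1-1)/(2(F2+1))``,
    which is always defined; ``bias_corrected=False`` gives the classical
    ``S_obs + F1^2/(2 F2)``, falling back to the bias-corrected form when
    F2 = 0.
    """
    s_obs = fc.s_obs
    f1, f2 = fc.f(1), fc.f(2)
    if not bias_corrected and f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))


def ichao1(fc: FrequencyCounts) -> float:
    """iChao1: Chao1 plus the F3/F4 higher-order correction.

    When F4 = 0 the correction uses F4 + 1, mirroring the bias-corrected
    Chao1 convention, so the estimator stays defined on sparse tails.
    """
    f1, f2, f3, f4 = fc.f(1), fc.f(2), fc.f(3), fc.f(4)
    base = chao1(fc)
    if f3 == 0:
        return base
    f4e = f4 if f4 > 0 else f4 + 1.0
    corr = (f3 / (4.0 * f4e)) * max(f1 - f2 * f3 / (2.0 * f4e), 0.0)
    return base + corr


def ace(fc: FrequencyCounts, rare_cutoff: int = 10, variant: str = "ace") -> float:
    """Abundance-based coverage estimators (ACE and ACE-1).

    Species with counts <= ``rare_cutoff`` form the rare group; sample
    coverage is 1 - F1/N_rare and the squared coefficient of variation
    corrects for heterogeneity.  ``variant="ace1"`` applies the extended
    CV term for highly uneven assemblages.
    """
    if rare_cutoff < 2:
        raise ValueError("rare_cutoff must be >= 2")
    if variant not in ("ace", "ace1"):
        raise ValueError("variant must be 'ace' or 'ace1'")
    kv, fv = fc.arrays()
    rare = kv <= rare_cutoff
    s_rare = int(fv[rare].sum())
    s_abund = int(fv[~rare].sum())
    if s_rare == 0:
        return float(fc.s_obs)
    n_rare = int(np.dot(kv[rare], fv[rare]))
    f1 = fc.f(1)
    cov = 1.0 - f1 / n_rare
    if cov <= 0.0:
        raise ACEUndefinedError("ACE undefined, coverage zero")
    sum_kk1 = float(np.dot(kv[rare] * (kv[rare] - 1), fv[rare]))
    gamma2 = max(
        (s_rare / cov) * sum_kk1 / (n_rare * (n_rare - 1.0)) - 1.0, 0.0
    )
    if variant == "ace1":
        gamma2 = max(
            gamma2 * (1.0 + (1.0 - cov) / cov * sum_kk1 / (n_rare - 1.0)), 0.0
        )
    return s_abund + s_rare / cov + (f1 / cov) * gamma2


# ---------------------------------------------------------------------------
# rarefaction


def _log_choose(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def rarefy_richness(
    av: AbundanceVector, n: int, variance: bool = False
) -> float | tuple[float, float]:
    """Exact expected richness (and analytic variance) in a random
    subsample of n reads.

    ``E[S(n)] = S_obs - sum_i C(N - N_i, n) / C(N, n)`` evaluated through
    log-gamma; the variance follows Heck et al.'s hypergeometric formula,
    computed over distinct count values so it stays cheap for large S_obs.
    """
    N = av.n_reads
    if not 1 <= n <= N:
        raise ValueError(f"subsample size n={n} outside [1, N={N}]")
    fc = to_frequency_counts(av)
    kv, fv = fc.arrays()
    log_cn = _log_choose(N, n)
    with np.errstate(invalid="ignore"):
        lq = np.where(N - kv >= n, _log_choose(N - kv, n) - log_cn, -np.inf)
    q = np.exp(lq)  # q_i = P(species with count k entirely missed)
    expected = float(fc.s_obs - np.dot(fv, q))
    if not variance:
        return expected
    # var = sum_i q_i(1-q_i) + 2 sum_{i<j} [C(N-Ni-Nj, n)/C(N,n) - qi qj]
    var = float(np.dot(fv, q * (1.0 - q)))
    ksum = kv[:, None] + kv[None, :]
    with np.errstate(invalid="ignore"):
        lqq = np.where(
            N - ksum >= n, _log_choose(np.maximum(N - ksum, 0), n) - log_cn, -np.inf
        )
    cov = np.exp(lqq) - q[:, None] * q[None, :]
    # number of unordered species pairs per count-class pair:
    # fv_a * fv_b across classes a < b, C(fv_a, 2) within a class
    npairs = np.triu(fv[:, None] * fv[None, :].astype(float), k=1)
    np.fill_diagonal(npairs, fv * (fv - 1.0) / 2.0)
    var += 2.0 * float(np.sum(npairs * np.triu(cov)))
    return expected, var


# ---------------------------------------------------------------------------
# collector's curves


@dataclass(frozen=True)
class CollectorCurve:
    efforts: np.ndarray
    expected_richness: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    kind: tuple[str, ...]  # interpolated | observed | extrapolated
    n_reads: int
    s_obs: int


def _extrapolate(s_obs: int, n: int, f1: int, f2: int, m_extra: np.ndarray) -> np.ndarray:
    """Chao-style sample-size extrapolation by m_extra reads beyond n."""
    if f1 == 0:
        return np.full_like(m_extra, float(s_obs), dtype=float)
    f0 = f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0)) if f2 == 0 else f1 * f1 / (2.0 * f2)
    if f0 <= 0:
        return np.full_like(m_extra, float(s_obs), dtype=float)
    return s_obs + f0 * (1.0 - np.exp(-m_extra * f1 / (n * f0 + f1)))


def _curve_values(av: AbundanceVector, grid: np.ndarray) -> np.ndarray:
    N = av.n_reads
    fc = to_frequency_counts(av)
    out = np.empty(len(grid))
    for i, m in enumerate(grid):
        if m <= N:
            out[i] = rarefy_richness(av, int(m))
        else:
            out[i] = _extrapolate(av.s_obs, N, fc.f(1), fc.f(2), np.array([m - N]))[0]
    return out


def collector_curve(
    av: AbundanceVector,
    grid: Sequence[int] | None = None,
    extrapolate_to: int | None = None,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> CollectorCurve:
    """Rarefaction/extrapolation curve with bootstrap 95% CI.

    Interpolation uses exact analytic rarefaction; extrapolation the
    asymptotic sample-size formula with the Chao1 estimate of the number
    of unseen species.  The bootstrap resamples N reads from the
    estimated composition (observed relative abundances scaled to the
    estimated coverage, the unseen probability mass F1/N split equally
    among the estimated unseen species).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    N = av.n_reads
    top = int(extrapolate_to) if extrapolate_to else N
    if grid is None:
        g = np.unique(
            np.concatenate(
                [
                    np.linspace(1, min(N, top), 12, dtype=np.int64),
                    np.geomspace(min(N, top), top, 8, dtype=np.int64)
                    if top > N
                    else np.array([], dtype=np.int64),
                ]
            )
        )
    else:
        g = np.unique(np.asarray(grid, dtype=np.int64))
    if g.min() < 1 or g.max() > top:
        raise ValueError("grid outside (0, extrapolate_to]")
    expected = _curve_values(av, g)
    kind = tuple(
        "observed" if m == N else ("interpolated" if m < N else "extrapolated")
        for m in g
    )
    fc = to_frequency_counts(av)
    f1 = fc.f(1)
    f0 = max(int(np.ceil(chao1(fc) - av.s_obs)), 0) if f1 > 0 else 0
    unseen_mass = f1 / N if f0 > 0 else 0.0
    probs = np.concatenate(
        [
            av.counts / N * (1.0 - unseen_mass),
            np.full(f0, unseen_mass / max(f0, 1)),
        ]
    )
    boot = np.empty((n_boot, len(g)))
    for b in range(n_boot):
        cts = rng.multinomial(N, probs)
        cts = cts[cts > 0]
        bav = AbundanceVector(
            tuple(f"b{i}" for i in range(len(cts))), cts.astype(np.int64)
        )
        boot[b] = _curve_values(bav, g)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    # the band must contain the point estimate
    lo = np.minimum(lo, expected)
    hi = np.maximum(hi, expected)
    return CollectorCurve(
        efforts=g,
        expected_richness=expected,
        ci_low=lo,
        ci_high=hi,
        kind=kind,
        n_reads=N,
        s_obs=av.s_obs,
    )


# ---------------------------------------------------------------------------
# saturating-function fits


@dataclass(frozen=True)
class CurveFitResult:
    family: str
    coefficients: tuple[float, ...]
    aicc: float
    asymptote: float


_SATURATING = {
    "michaelis_menten": (
        lambda x, a, b: a * x / (b + x),
        lambda y, x: (1.2 * y.max(), np.median(x)),
        lambda c: c[0],
    ),
    "neg_exponential": (
        lambda x, a, b: a * (1.0 - np.exp(-b * x)),
        lambda y, x: (1.1 * y.max(), 2.0 / np.median(x)),
        lambda c: c[0],
    ),
    "weibull": (
        lambda x, a, b, c: a * (1.0 - np.exp(-((x / b) ** c))),
        lambda y, x: (1.1 * y.max(), np.median(x), 1.0),
        lambda c: c[0],
    ),
    "logistic": (
        lambda x, a, b, c: a / (1.0 + np.exp(-(x - b) / c)),
        lambda y, x: (1.1 * y.max(), np.median(x), np.ptp(x) / 5.0),
        lambda c: c[0],
    ),
    "rational": (  # Hill form: rational in x^c
        lambda x, a, b, c: a * x**c / (b**c + x**c),
        lambda y, x: (1.2 * y.max(), np.median(x), 1.0),
        lambda c: c[0],
    ),
}


def fit_saturating_curves(curve: CollectorCurve) -> list[CurveFitResult]:
    """Least-squares fits of five saturating families to a collector's
    curve, ranked by AICc; the best asymptote is the semiparametric
    richness estimate.  Non-convergent families are dropped with a warning.
    """
    x = np.asarray(curve.efforts, dtype=float)
    y = np.asarray(curve.expected_richness, dtype=float)
    if len(x) < 6:
        raise ValueError("need at least 6 curve points")
    # rescale x to O(1) for conditioning; asymptotes are scale-free
    xs = x / x.max()
    results = []
    for name, (fn, p0fn, asym) in _SATURATING.items():
        p0 = p0fn(y, xs)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    fn, xs, y, p0=p0, maxfev=20000,
                    bounds=(np.zeros(len(p0)), np.full(len(p0), np.inf)),
                )
        except (RuntimeError, ValueError):
            warnings.warn(f"saturating fit failed for {name}; omitted")
            continue
        resid = y - fn(xs, *popt)
        n = len(x)
        k = len(popt) + 1
        rss = max(float(np.dot(resid, resid)), 1e-12 * n)
        aicc = n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        results.append(
            CurveFitResult(name, tuple(popt), float(aicc), float(asym(popt)))
        )
    results.sort(key=lambda r: r.aicc)
    return results
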