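"""Poisson-mixture taxon abundance distributions (TADs).

Four families are supported, each defined as a Poisson kernel mixed over a
positive mixing density g(lambda; theta) for the species' mean read count:

* ``poisson_lognormal`` — lambda ~ LogNormal(mu, sigma); theta = (mu, sigma)
* ``poisson_logstudent`` — log lambda ~ mu + sigma * Student-t(nu);
  theta = (mu, sigma, nu)
* ``poisson_inverse_gaussian`` — lambda ~ GIG(index -1/2, chi, psi);
  theta = (chi, psi)
* ``sichel`` — lambda ~ GIG(gamma, chi, psi); theta = (gamma, chi, psi)

with the generalized inverse Gaussian density
``g(x) ∝ x^(gamma-1) exp(-(psi*x + chi/x)/2)``.  The Poisson inverse
Gaussian is the Sichel special case with index pinned at -1/2.

The Sichel pmf has a closed form through modified Bessel functions of the
second kind,

``p_k = psi^(g/2) chi^(k/2) / ((psi+2)^((k+g)/2) k!)
        * K_{k+g}(sqrt((psi+2) chi)) / K_g(sqrt(psi chi))``,

evaluated here entirely in log space with an upward order ladder for the
Bessel terms.  The log-normal and log-Student mixtures have no closed form
and are integrated adaptively in x = log(lambda) space (the log-normal
integrand is strictly log-concave; the log-Student one is bracketed on a
scanned grid so heavy polynomial tails cannot hide mass).  The k = 0
log-Student term is integrated in probability (CDF) space, which treats
the polynomial tails of the Student mixing density exactly.

Read-depth scaling: the mixing density describes mean *read counts*, so a
fit is tied to its sample's depth N.  ``n_scale`` rescales lambda -> s *
lambda (location shift mu -> mu + log s for the log families, (chi, psi)
-> (s*chi, psi/s) for the GIG families), which makes fits at different
depths comparable and lets one fitted model drive simulations at other
efforts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import gammaln, logsumexp
from scipy.stats import geninvgauss
from scipy.stats import t as student_t

from ._bessel import log_kv, log_kv_ladder
from .data_model import FrequencyCounts
from .errors import QuadratureError, RichnessBelowObservedError

__all__ = [
    "FAMILIES",
    "TADModel",
    "PmfVector",
    "tad_pmf",
    "tad_log_pmf",
    "pmf_vector",
    "sample_community",
    "sample_counts",
    "truncated_loglikelihood",
]

FAMILIES = (
    "poisson_lognormal",
    "poisson_logstudent",
    "poisson_inverse_gaussian",
    "sichel",
)

_N_PARAMS = {
    "poisson_lognormal": 2,
    "poisson_logstudent": 3,
    "poisson_inverse_gaussian": 2,
    "sichel": 3,
}

_PIG_INDEX = -0.5  # the GIG index pinning PIG inside the Sichel family


@dataclass(frozen=True)
class TADModel:
    """A TAD family tag plus its parameter vector theta."""

    family: str
    theta: tuple[float, ...]

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        th = tuple(float(x) for x in self.theta)
        if len(th) != _N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} needs {_N_PARAMS[self.family]} parameters, "
                f"got {len(th)}"
            )
        if self.family == "poisson_lognormal":
            if th[1] <= 0:
                raise ValueError("sigma must be positive")
        elif self.family == "poisson_logstudent":
            if th[1] <= 0 or th[2] <= 0:
                raise ValueError("sigma and nu must be positive")
        else:
            chi, psi = th[-2], th[-1]
            if chi <= 0 or psi <= 0:
                raise ValueError("chi and psi must be positive")
        object.__setattr__(self, "theta", th)

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]

    def gig_params(self) -> tuple[float, float, float]:
        """(gamma, chi, psi) for the GIG families."""
        if self.family == "poisson_inverse_gaussian":
            return (_PIG_INDEX, self.theta[0], self.theta[1])
        if self.family == "sichel":
            return self.theta  # type: ignore[return-value]
        raise ValueError(f"{self.family} is not a GIG mixture")

    def scaled(self, s: float) -> "TADModel":
        """Model of s * lambda (read-depth rescaling)."""
        if s == 1.0:
            return self
        if s <= 0:
            raise ValueError("scale must be positive")
        if self.family == "poisson_lognormal":
            mu, sg = self.theta
            return TADModel(self.family, (mu + np.log(s), sg))
        if self.family == "poisson_logstudent":
            mu, sg, nu = self.theta
            return TADModel(self.family, (mu + np.log(s), sg, nu))
        gamma, chi, psi = self.gig_params()
        th = (chi * s, psi / s)
        if self.family == "sichel":
            return TADModel(self.family, (gamma,) + th)
        return TADModel(self.family, th)

    def to_json(self) -> str:
        return json.dumps({"family": self.family, "theta": list(self.theta)})

    @classmethod
    def from_json(cls, s: str) -> "TADModel":
        d = json.loads(s)
        return cls(d["family"], tuple(d["theta"]))


@dataclass(frozen=True)
class PmfVector:
    """Probabilities for k = 0..k_max plus certified residual tail mass."""

    p: np.ndarray
    tail_mass: float


# ---------------------------------------------------------------------------
# Sichel / PIG closed form


def _sichel_log_pmf(gamma: float, chi: float, psi: float, k: np.ndarray) -> np.ndarray:
    k = np.asarray(k, dtype=np.int64)
    kmax = int(k.max())
    omega = np.sqrt(psi * chi)
    beta = np.sqrt((psi + 2.0) * chi)
    logK = log_kv_ladder(gamma, beta, kmax)
    log_norm = log_kv(gamma, omega)
    return (
        0.5 * gamma * np.log(psi)
        + 0.5 * k * np.log(chi)
        - 0.5 * (k + gamma) * np.log(psi + 2.0)
        - gammaln(k + 1.0)
        + logK[k]
        - log_norm
    )


# ---------------------------------------------------------------------------
# Log-normal / log-Student mixtures: adaptive quadrature in x = log(lambda)


def _log_t_pdf(z: np.ndarray, nu: float) -> np.ndarray:
    return (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - 0.5 * (nu + 1.0) * np.log1p(z * z / nu)
    )


def _poisson_log_kernel(k: np.ndarray, x: np.ndarray) -> np.ndarray:
    # log Pois(k; e^x) as a function of x; k broadcast against x
    return k * x - np.exp(x) - gammaln(k + 1.0)


@lru_cache(maxsize=None)
def _leggauss(n: int):
    u, w = leggauss(n)
    return u, np.log(w)


def _gl_log_integral(g, a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    """log ∫_a^b exp(g(x)) dx by n-node Gauss-Legendre, per row of (a, b)."""
    u, logw = _leggauss(n)
    half = 0.5 * (b - a)[:, None]
    x = 0.5 * (a + b)[:, None] + half * u[None, :]
    vals = g(x) + logw[None, :] + np.log(half)
    return logsumexp(vals, axis=1)


def _adaptive_log_integral(g, a, b, tol, who):
    """Refine node count until successive estimates agree to rel. tol."""
    prev = _gl_log_integral(g, a, b, 64)
    for n in (128, 256, 512, 1024):
        cur = _gl_log_integral(g, a, b, n)
        # |exp(prev - cur) - 1| < tol on every row
        if np.all(np.abs(np.expm1(prev - cur)) < tol):
            return cur
        prev = cur
    if np.all(np.abs(np.expm1(prev - cur)) < 10 * tol):
        return cur
    raise QuadratureError(f"quadrature failed to converge for {who}")


def _bracket_bisect(g, lo, hi, target, increasing):
    """Per-row bisection for g(x) = target on a monotone stretch."""
    lo = lo.copy()
    hi = hi.copy()
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        gm = g(mid[:, None])[:, 0]
        if increasing:  # left flank: g rises towards the mode at hi
            above = gm > target
            hi = np.where(above, mid, hi)
            lo = np.where(above, lo, mid)
        else:  # right flank: g falls away from the mode at lo
            above = gm > target
            lo = np.where(above, mid, lo)
            hi = np.where(above, hi, mid)
    return 0.5 * (lo + hi)


def _pln_log_pmf(mu: float, sigma: float, k: np.ndarray, tol: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)

    def g(x):  # x: (nk, nodes); log integrand
        return (
            _poisson_log_kernel(k[:, None], x)
            - 0.5 * ((x - mu) / sigma) ** 2
            - np.log(sigma)
            - 0.5 * np.log(2.0 * np.pi)
        )

    # mode: k - e^x - (x - mu)/sigma^2 = 0; f is strictly decreasing in x
    lo = np.minimum(mu - 60.0 * sigma, np.log(k + 0.5) - 60.0)
    hi = np.maximum(mu + 60.0 * sigma, np.log(k + 1.0) + 5.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = k - np.exp(mid) - (mid - mu) / sigma**2
        lo = np.where(f > 0, mid, lo)
        hi = np.where(f > 0, hi, mid)
    xhat = 0.5 * (lo + hi)
    gmax = g(xhat[:, None])[:, 0]
    drop = gmax - 46.0  # e^-46 ~ 1e-20 relative: negligible truncation
    # the integrand is log-concave, hence unimodal: bisect each flank
    lo_end = np.minimum(mu - 60.0 * sigma, xhat - 60.0)
    hi_end = np.maximum(mu + 60.0 * sigma, xhat + 60.0)
    a = _bracket_bisect(g, lo_end, xhat, drop, increasing=True)
    b = _bracket_bisect(g, xhat, hi_end, drop, increasing=False)
    return _adaptive_log_integral(g, a, b, tol, f"poisson_lognormal mu={mu} sigma={sigma}")


def _plst_p0(mu: float, sigma: float, nu: float, tol: float) -> float:
    """P(K=0) = E[exp(-lambda)] in CDF space of the Student mixing law.

    The substitution u = T_nu((x - mu)/sigma) maps the full real line onto
    (0, 1), so the polynomial tails contribute exactly.
    """
    # panel knots where the kernel exp(-e^x) transitions
    lam_knots = np.array([1e-12, 1e-6, 1e-3, 1e-1, 1.0, 3.0, 10.0, 60.0])
    u_knots = student_t.cdf((np.log(lam_knots) - mu) / sigma, df=nu)
    knots = np.concatenate([[0.0], u_knots, [1.0]])
    knots = np.unique(np.clip(knots, 0.0, 1.0))

    def panel_sum(n):
        u, w = leggauss(n)
        total = 0.0
        for ua, ub in zip(knots[:-1], knots[1:]):
            if ub <= ua:
                continue
            half = 0.5 * (ub - ua)
            uu = 0.5 * (ua + ub) + half * u
            lam = np.exp(mu + sigma * student_t.ppf(uu, df=nu))
            total += half * np.dot(w, np.exp(-lam))
        return total

    prev = panel_sum(40)
    for n in (80, 160, 320):
        cur = panel_sum(n)
        if abs(cur - prev) <= tol * max(cur, 1e-300):
            return cur
        prev = cur
    raise QuadratureError(
        f"quadrature failed to converge for poisson_logstudent k=0 "
        f"mu={mu} sigma={sigma} nu={nu}"
    )


def _plst_log_pmf(
    mu: float, sigma: float, nu: float, k: np.ndarray, tol: float
) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    out = np.empty(len(k))
    zero = k == 0
    if zero.any():
        out[zero] = np.log(_plst_p0(mu, sigma, nu, tol))
    pos = ~zero
    if not pos.any():
        return out
    kp = k[pos]

    def g(x):
        return _poisson_log_kernel(kp[:, None], x) + _log_t_pdf(
            (x - mu) / sigma, nu
        ) - np.log(sigma)

    # For k >= 1 the e^{kx} factor kills the left tail exponentially, so a
    # scanned grid bracket is safe even though g need not be concave.
    span_lo = np.minimum(mu - 80.0 * sigma, np.log(kp) - 80.0)
    span_hi = np.maximum(mu + 80.0 * sigma, np.log(kp) + 10.0)
    ngrid = 1600
    tgrid = np.linspace(0.0, 1.0, ngrid)
    xg = span_lo[:, None] + (span_hi - span_lo)[:, None] * tgrid[None, :]
    gg = g(xg)
    imax = np.argmax(gg, axis=1)
    gmax = gg[np.arange(len(kp)), imax]
    keep = gg >= (gmax[:, None] - 46.0)
    first = np.argmax(keep, axis=1)
    last = ngrid - 1 - np.argmax(keep[:, ::-1], axis=1)
    step = (span_hi - span_lo) / (ngrid - 1)
    a = span_lo + np.maximum(first - 1, 0) * step
    b = span_lo + np.minimum(last + 1, ngrid - 1) * step
    out[pos] = _adaptive_log_integral(
        g, a, b, tol, f"poisson_logstudent mu={mu} sigma={sigma} nu={nu}"
    )
    return out


# ---------------------------------------------------------------------------
# public pmf API


def tad_log_pmf(
    model: TADModel,
    k: Sequence[int] | np.ndarray | int,
    n_scale: float = 1.0,
    tol: float = 1e-8,
) -> np.ndarray | float:
    """``log P(K = k)`` for the mixed-Poisson count distribution.

    Vectorized over ``k``; deterministic for fixed inputs.  ``tol`` is the
    relative tolerance of the quadrature (ignored by the closed-form GIG
    families).
    """
    if not (0 < tol <= 1e-4):
        raise ValueError("tol must be in (0, 1e-4]")
    scalar = np.isscalar(k)
    karr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    if np.any(karr < 0):
        raise ValueError("k must be non-negative")
    m = model.scaled(n_scale)
    if m.family in ("sichel", "poisson_inverse_gaussian"):
        gamma, chi, psi = m.gig_params()
        out = _sichel_log_pmf(gamma, chi, psi, karr)
    else:
        # quadrature paths allocate (n_k, nodes) work arrays; chunk k to
        # keep memory flat for large vectors
        out = np.empty(len(karr))
        for i in range(0, len(karr), 4096):
            blk = karr[i : i + 4096]
            if m.family == "poisson_lognormal":
                mu, sg = m.theta
                out[i : i + 4096] = _pln_log_pmf(mu, sg, blk, tol)
            else:
                mu, sg, nu = m.theta
                out[i : i + 4096] = _plst_log_pmf(mu, sg, nu, blk, tol)
    return float(out[0]) if scalar else out


def tad_pmf(model, k, n_scale: float = 1.0, tol: float = 1e-8):
    """``P(K = k)``; see :func:`tad_log_pmf`."""
    return np.exp(tad_log_pmf(model, k, n_scale=n_scale, tol=tol))


def pmf_vector(
    model: TADModel,
    k_max: int | None = None,
    n_scale: float = 1.0,
    tol: float = 1e-8,
    tail: float = 1e-10,
    k_cap: int = 1 << 20,
) -> PmfVector:
    """pmf over k = 0..k_max with certified tail mass.

    If ``k_max`` is None it is grown (up to ``k_cap``) until the
    cumulative mass exceeds ``1 - tail``; a heavy-tailed model that does
    not close by then raises :class:`QuadratureError`.
    """
    if k_max is not None:
        p = tad_pmf(model, np.arange(k_max + 1), n_scale=n_scale, tol=tol)
        return PmfVector(p, max(0.0, 1.0 - float(p.sum())))
    km = 256
    while True:
        p = tad_pmf(model, np.arange(km + 1), n_scale=n_scale, tol=tol)
        if p.sum() > 1.0 - tail:
            return PmfVector(p, max(0.0, 1.0 - float(p.sum())))
        if km >= k_cap:
            raise QuadratureError(
                f"pmf tail did not close below {tail} by k={k_cap} for "
                f"{model.family} theta={model.theta}"
            )
        km *= 2


# ---------------------------------------------------------------------------
# sampling


def sample_community(
    model: TADModel, S: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw S i.i.d. mean abundances from the mixing density, normalized
    to relative abundances (strictly positive, summing to 1)."""
    if S < 1:
        raise ValueError("S must be >= 1")
    if model.family == "poisson_lognormal":
        mu, sg = model.theta
        lam = np.exp(mu + sg * rng.standard_normal(S))
    elif model.family == "poisson_logstudent":
        mu, sg, nu = model.theta
        lam = np.exp(mu + sg * rng.standard_t(nu, size=S))
    else:
        gamma, chi, psi = model.gig_params()
        dist = geninvgauss(p=gamma, b=np.sqrt(chi * psi), scale=np.sqrt(chi / psi))
        lam = dist.rvs(size=S, random_state=rng)
    return lam / lam.sum()


def sample_counts(
    abundances: np.ndarray, N: int, rng: np.random.Generator
) -> np.ndarray:
    """One multinomial sequencing draw of N reads; zeros are retained."""
    p = np.asarray(abundances, dtype=float)
    if N < 1:
        raise ValueError("N must be >= 1")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("abundances must sum to 1")
    return rng.multinomial(N, p / p.sum())


# ---------------------------------------------------------------------------
# zero-truncated joint likelihood


def truncated_loglikelihood(
    fc: FrequencyCounts,
    model: TADModel,
    S: int,
    n_scale: float = 1.0,
    tol: float = 1e-8,
) -> float:
    """Joint log-likelihood of the frequency table and total richness S.

    ``log L = log S! - log (S - S_obs)! - sum_k log F_k!
              + (S - S_obs) log p_0 + sum_k F_k log p_k``

    where the S - S_obs unobserved species each contribute the zero-count
    probability p_0.  Returns -inf when p_0 underflows and S > S_obs.
    """
    s_obs = fc.s_obs
    if S < s_obs:
        raise RichnessBelowObservedError(
            f"richness below observed: S={S} < S_obs={s_obs}"
        )
    kv, fv = fc.arrays()
    ks = np.concatenate([[0], kv])
    logp = tad_log_pmf(model, ks, n_scale=n_scale, tol=tol)
    logp0, logpk = logp[0], logp[1:]
    ll = (
        gammaln(S + 1.0)
        - gammaln(S - s_obs + 1.0)
        - np.sum(gammaln(fv + 1.0))
        + float(np.dot(fv, logpk))
    )
    if S > s_obs:
        if not np.isfinite(logp0):
            return -np.inf
        ll += (S - s_obs) * logp0
    return float(ll)
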