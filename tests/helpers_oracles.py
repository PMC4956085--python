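"""Independent oracles used across the test suite.

These deliberately avoid the implementation paths they check: pmf values
come from dense-grid trapezoid integration of the mixing-density
integral, likelihoods from explicit enumeration over species-to-count
assignments, and RSE values from a plain streaming set-scan.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import gammaln
from scipy.stats import t as student_t


def dense_grid_pmf(family: str, theta, k: int, n_nodes: int = 1_000_001) -> float:
    """P(K=k) by trapezoid integration on a dense grid in x = log lambda.

    For the log-Student mixture at k = 0 the integral is taken in CDF
    space instead (u = T_nu((x-mu)/sigma)), because the polynomial tails
    carry mass that no finite x-grid captures.
    """
    if family == "poisson_lognormal":
        mu, sg = theta

        def log_mix(x):
            return (
                -0.5 * ((x - mu) / sg) ** 2
                - np.log(sg)
                - 0.5 * np.log(2 * np.pi)
            )

    elif family == "poisson_logstudent":
        mu, sg, nu = theta
        if k == 0:
            u = np.linspace(1e-10, 1 - 1e-10, n_nodes)
            lam = np.exp(mu + sg * student_t.ppf(u, df=nu))
            return float(np.trapezoid(np.exp(-lam), u))

        def log_mix(x):
            return student_t.logpdf((x - mu) / sg, df=nu) - np.log(sg)

    elif family in ("sichel", "poisson_inverse_gaussian"):
        if family == "poisson_inverse_gaussian":
            gamma, chi, psi = -0.5, theta[0], theta[1]
        else:
            gamma, chi, psi = theta
        from scipy.stats import geninvgauss

        dist = geninvgauss(p=gamma, b=math.sqrt(chi * psi), scale=math.sqrt(chi / psi))

        def log_mix(x):
            return dist.logpdf(np.exp(x)) + x  # density in x = log lambda

    else:
        raise ValueError(family)
    x = np.linspace(-45.0, 28.0, n_nodes)
    with np.errstate(over="ignore", invalid="ignore", under="ignore"):
        logf = k * x - np.exp(x) - gammaln(k + 1.0) + log_mix(x)
        f = np.where(np.isfinite(logf), np.exp(logf), 0.0)
    return float(np.trapezoid(f, x))


def enumerate_loglik(fc_entries: dict[int, int], pmf, S: int) -> float:
    """Log-likelihood of a tiny frequency table by explicit enumeration.

    Sums the multinomial-mixture likelihood over every distinct
    assignment of the observed counts (padded with zeros) to S labeled
    species; pmf(k) supplies the per-species count probabilities.
    """
    counts = []
    for k, f in fc_entries.items():
        counts.extend([k] * f)
    counts.extend([0] * (S - len(counts)))
    total = 0.0
    for perm in set(itertools.permutations(counts)):
        total += math.exp(sum(math.log(pmf(c)) for c in perm))
    return math.log(total)


def scan_required_effort(sequence, q: float, S_sim: int):
    """Reference RSE scan: walk the sequence with a set."""
    seen = set()
    target = q * S_sim
    for i, label in enumerate(sequence, start=1):
        seen.add(label)
        if len(seen) > target:
            return i
    return None
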