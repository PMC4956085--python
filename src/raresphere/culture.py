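"""Culture-vs-sequencing retrieval comparison.

Isolated (cultured) species and deep-sequencing OTUs are matched by
reciprocal alignment searches; the retained isolate-OTU pairs are the
cultured species "found" by sequencing.  Three significance analyses ask
whether the cultured species are under-retrieved:

* a binomial test: if a random species from the total inventory is
  sequenced with probability S_obs / S, how surprising is retrieving only
  k of n cultured species (one-sided, lower tail);
* a posterior simulation test propagating the uncertainty in S through
  the same binomial draw;
* a bootstrap test of whether the read counts of the matched OTUs are low
  relative to random draws from the observed count distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .bayes_fit import PosteriorChain
from .data_model import AbundanceVector
from .errors import CoverageLengthError, TableParseError

__all__ = [
    "MatchRecord",
    "RetrievalTestResult",
    "OUTFMT6_COLUMNS",
    "read_match_table",
    "read_query_lengths",
    "reciprocal_filter",
    "binomial_retrieval_test",
    "posterior_retrieval_test",
    "matched_abundance_test",
]

OUTFMT6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class MatchRecord:
    query: str
    subject: str
    identity: float  # percent
    length: int  # alignment length
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class RetrievalTestResult:
    test: str
    statistic: float
    p_value: float
    n_trials: int
    inputs: dict


def read_match_table(path: str | Path) -> pd.DataFrame:
    """Read a tabular alignment result in outfmt-6-like column order."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < len(OUTFMT6_COLUMNS):
        raise TableParseError(
            f"{path}: expected >= {len(OUTFMT6_COLUMNS)} columns, got {df.shape[1]}"
        )
    df = df.iloc[:, : len(OUTFMT6_COLUMNS)]
    df.columns = list(OUTFMT6_COLUMNS)
    return df


def read_query_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of sequence id -> length."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    return {str(r[0]): int(r[1]) for r in df.itertuples(index=False)}


def _passes(
    rec: pd.Series,
    isolate: str,
    isolate_lengths: Mapping[str, int],
    min_identity: float,
    min_coverage: float,
    min_bitscore: float,
    max_evalue: float,
) -> bool:
    if isolate not in isolate_lengths:
        raise CoverageLengthError(
            f"missing isolate length for coverage: record "
            f"{rec['qseqid']} -> {rec['sseqid']}"
        )
    coverage = rec["length"] / isolate_lengths[isolate]
    return (
        rec["pident"] >= min_identity
        and coverage >= min_coverage
        and rec["bitscore"] > min_bitscore
        and rec["evalue"] < max_evalue
    )


def reciprocal_filter(
    fwd: pd.DataFrame,
    rev: pd.DataFrame,
    isolate_lengths: Mapping[str, int],
    min_identity: float = 99.0,
    min_coverage: float = 0.75,
    min_bitscore: float = 100.0,
    max_evalue: float = 1e-4,
) -> pd.DataFrame:
    """Reciprocal-best filtering of isolate->OTU and OTU->isolate searches.

    A pair (isolate, OTU) is retained iff a forward record isolate->OTU
    and a reverse record OTU->isolate both pass: identity >=
    ``min_identity``, alignment length / isolate length >=
    ``min_coverage`` (the coverage denominator is always the isolate
    sequence), bit-score strictly > ``min_bitscore`` and e-value <
    ``max_evalue``.  The output keeps the best (highest forward
    bit-score) OTU per isolate; rows are sorted by isolate id, so the
    result is invariant to input row order.
    """
    fwd_mask = np.array(
        [
            _passes(r, r["qseqid"], isolate_lengths, min_identity,
                    min_coverage, min_bitscore, max_evalue)
            for _, r in fwd.iterrows()
        ],
        dtype=bool,
    )
    rev_mask = np.array(
        [
            _passes(r, r["sseqid"], isolate_lengths, min_identity,
                    min_coverage, min_bitscore, max_evalue)
            for _, r in rev.iterrows()
        ],
        dtype=bool,
    )
    fwd_ok = fwd.loc[fwd_mask]
    rev_ok = rev.loc[rev_mask]
    fwd_pairs = fwd_ok[["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"]]
    fwd_pairs = fwd_pairs.rename(columns={"qseqid": "isolate", "sseqid": "otu"})
    rev_pairs = set(zip(rev_ok["sseqid"], rev_ok["qseqid"]))
    keep = np.array(
        [
            (iso, otu) in rev_pairs
            for iso, otu in zip(fwd_pairs["isolate"], fwd_pairs["otu"])
        ],
        dtype=bool,
    )
    out = fwd_pairs.loc[keep]
    out = (
        out.sort_values(["bitscore", "otu"], ascending=[False, True])
        .drop_duplicates("isolate", keep="first")
        .sort_values("isolate")
        .reset_index(drop=True)
    )
    return out


def binomial_retrieval_test(
    n_cultured: int, n_found: int, s_obs: int, s_total: float
) -> RetrievalTestResult:
    """One-sided lower-tail binomial test of the retrieval deficit.

    The retrieval probability of a random species is p = S_obs / S; the
    p-value is P(X <= n_found) for X ~ Binomial(n_cultured, p).  The
    result also carries the expected retrieved count round(n * p).
    """
    if not 0 <= n_found <= n_cultured:
        raise ValueError("need 0 <= n_found <= n_cultured")
    if s_total < s_obs:
        raise ValueError("s_total must be >= s_obs")
    p = s_obs / s_total
    pval = float(binom.cdf(n_found, n_cultured, p))
    return RetrievalTestResult(
        test="binomial_retrieval",
        statistic=float(n_found),
        p_value=pval,
        n_trials=n_cultured,
        inputs={
            "retrieval_probability": p,
            "expected_found": int(round(n_cultured * p)),
            "s_obs": s_obs,
            "s_total": s_total,
        },
    )


def posterior_retrieval_test(
    chain: PosteriorChain,
    n_cultured: int,
    n_found: int,
    n_sim: int = 3000,
    rng: np.random.Generator | None = None,
) -> RetrievalTestResult:
    """Simulation test propagating posterior uncertainty in S.

    Each of ``n_sim`` draws samples S from the posterior chain, sets p =
    S_obs / S and draws k ~ Binomial(n_cultured, p); the p-value is the
    add-one fraction (#{k <= n_found} + 1) / (n_sim + 1).
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    rng = rng if rng is not None else np.random.default_rng(0)
    idx = rng.integers(len(chain), size=n_sim)
    p = chain.s_obs / chain.S[idx].astype(float)
    k = rng.binomial(n_cultured, np.clip(p, 0.0, 1.0))
    hits = int(np.sum(k <= n_found))
    return RetrievalTestResult(
        test="posterior_retrieval",
        statistic=float(n_found),
        p_value=(hits + 1) / (n_sim + 1),
        n_trials=n_sim,
        inputs={"n_cultured": n_cultured, "s_obs": chain.s_obs},
    )


def matched_abundance_test(
    matched_counts: Sequence[int],
    av: AbundanceVector,
    statistic: str = "mean",
    n_boot: int = 10000,
    rng: np.random.Generator | None = None,
) -> RetrievalTestResult:
    """Are the matched OTUs' read counts low for a random species sample?

    The null draws ``len(matched_counts)`` counts without replacement
    from the observed abundance vector; the p-value is the lower-tail
    add-one fraction of null statistics <= the observed statistic.
    """
    stats = {"mean": np.mean, "median": np.median, "max": np.max}
    if statistic not in stats:
        raise ValueError("statistic must be one of mean|median|max")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    matched = np.asarray(matched_counts, dtype=np.int64)
    m = len(matched)
    if m > av.s_obs:
        raise ValueError("more matched counts than observed OTUs")
    fn = stats[statistic]
    obs = float(fn(matched))
    rng = rng if rng is not None else np.random.default_rng(0)
    null = np.empty(n_boot)
    counts = av.counts
    for b in range(n_boot):
        null[b] = fn(rng.choice(counts, size=m, replace=False))
    hits = int(np.sum(null <= obs))
    return RetrievalTestResult(
        test=f"matched_abundance_{statistic}",
        statistic=obs,
        p_value=(hits + 1) / (n_boot + 1),
        n_trials=n_boot,
        inputs={"n_matched": m},
    )
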