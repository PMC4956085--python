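"""Core sample containers, file I/O and per-sample summaries.

The raw pipeline input is a per-sample OTU abundance table (one row per
OTU: id and read count).  Everything downstream of the raw table works on
the frequency-of-frequencies representation ``k -> F_k`` (number of OTUs
seen exactly ``k`` times), which is the sufficient statistic for every
richness estimator in this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DuplicateOTUError, NonPositiveCountError, TableParseError

__all__ = [
    "AbundanceVector",
    "FrequencyCounts",
    "SampleSummary",
    "read_abundance_table",
    "write_abundance_table",
    "read_frequency_table",
    "write_frequency_table",
    "to_frequency_counts",
    "summarize_sample",
    "rank_abundance",
]


@dataclass(frozen=True)
class AbundanceVector:
    """Per-OTU read counts for one sample, sorted by descending count.

    Ties in count are broken lexicographically on the OTU id, so the
    ordering (and any file written from it) is a pure function of the
    multiset of (id, count) pairs.
    """

    otu_ids: tuple[str, ...]
    counts: np.ndarray  # positive int64, same length as otu_ids

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        ids = tuple(str(i) for i in self.otu_ids)
        if len(ids) != len(counts):
            raise TableParseError("otu_ids and counts differ in length")
        if len(ids) == 0:
            raise TableParseError("empty abundance vector")
        if np.any(counts <= 0):
            bad = ids[int(np.argmax(counts <= 0))]
            raise NonPositiveCountError(f"nonpositive count for OTU {bad!r}")
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise DuplicateOTUError(f"duplicate id {dup!r}")
        order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
        object.__setattr__(self, "otu_ids", tuple(ids[i] for i in order))
        arr = counts[order]
        arr.flags.writeable = False
        object.__setattr__(self, "counts", arr)

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class FrequencyCounts:
    """Map ``k -> F_k``: number of OTUs observed exactly ``k`` times.

    Zero-valued entries are omitted.  ``sum(F_k) == S_obs`` and
    ``sum(k * F_k) == N`` by construction.
    """

    entries: Mapping[int, int]

    def __post_init__(self):
        ent = {int(k): int(f) for k, f in self.entries.items() if int(f) != 0}
        if not ent:
            raise TableParseError("empty frequency table")
        if any(k <= 0 for k in ent):
            raise NonPositiveCountError("count value k must be positive")
        if any(f < 0 for f in ent.values()):
            raise TableParseError("negative frequency F_k")
        object.__setattr__(self, "entries", dict(sorted(ent.items())))

    @property
    def s_obs(self) -> int:
        return sum(self.entries.values())

    @property
    def n_reads(self) -> int:
        return sum(k * f for k, f in self.entries.items())

    def f(self, k: int) -> int:
        """F_k, zero if absent."""
        return self.entries.get(int(k), 0)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(k values, F_k values) as aligned int64 arrays, k ascending."""
        k = np.fromiter(self.entries.keys(), dtype=np.int64)
        f = np.fromiter(self.entries.values(), dtype=np.int64)
        return k, f


@dataclass(frozen=True)
class SampleSummary:
    s_obs: int
    n_reads: int
    singleton_pct: float  # 100 * F1 / S_obs, 2 decimals, half-up
    top_otu_share: float  # max(count) / N

    def to_json(self) -> str:
        return json.dumps(
            {
                "s_obs": self.s_obs,
                "n_reads": self.n_reads,
                "singleton_pct": self.singleton_pct,
                "top_otu_share": self.top_otu_share,
            },
            indent=2,
        )


def _parse_two_column(path: str | Path, what: str) -> list[tuple[str, str]]:
    """Tab-separated rows, '#' comments ignored, header auto-detected by a
    non-integer second field on the first data row."""
    p = Path(path)
    rows: list[tuple[str, str]] = []
    with open(p) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TableParseError(f"{what} {p}: line {ln} has <2 columns")
            rows.append((parts[0].strip(), parts[1].strip()))
    if not rows:
        raise TableParseError(f"{what} {p}: no data rows")
    # header detection: second field of first row not an integer
    try:
        int(rows[0][1])
    except ValueError:
        rows = rows[1:]
        if not rows:
            raise TableParseError(f"{what} {p}: header only, no data rows")
    return rows


def read_abundance_table(path: str | Path) -> AbundanceVector:
    """Read an OTU abundance TSV (otu_id, count).

    Raises :class:`FileNotFoundError`, :class:`TableParseError`,
    :class:`NonPositiveCountError` or :class:`DuplicateOTUError`.
    """
    rows = _parse_two_column(path, "abundance table")
    ids, counts = [], []
    for otu, val in rows:
        try:
            c = int(val)
        except ValueError:
            raise TableParseError(f"non-integer count {val!r} for OTU {otu!r}")
        if c <= 0:
            raise NonPositiveCountError(f"nonpositive count {c} for OTU {otu!r}")
        ids.append(otu)
        counts.append(c)
    return AbundanceVector(tuple(ids), np.array(counts, dtype=np.int64))


def write_abundance_table(av: AbundanceVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        for otu, c in zip(av.otu_ids, av.counts):
            fh.write(f"{otu}\t{int(c)}\n")


def read_frequency_table(path: str | Path) -> FrequencyCounts:
    """Read a frequency-of-frequencies TSV (k, F_k)."""
    rows = _parse_two_column(path, "frequency table")
    ent: dict[int, int] = {}
    for kstr, fstr in rows:
        try:
            k, f = int(kstr), int(fstr)
        except ValueError:
            raise TableParseError(f"non-integer entry ({kstr!r}, {fstr!r})")
        if k in ent:
            raise DuplicateOTUError(f"duplicate count value k={k}")
        ent[k] = f
    return FrequencyCounts(ent)


def write_frequency_table(fc: FrequencyCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, f in fc.entries.items():
            fh.write(f"{k}\t{f}\n")


def to_frequency_counts(av: AbundanceVector) -> FrequencyCounts:
    """Tabulate counts into the frequency-of-frequencies sufficient statistic."""
    vals, freqs = np.unique(av.counts, return_counts=True)
    return FrequencyCounts({int(k): int(f) for k, f in zip(vals, freqs)})


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_sample(av: AbundanceVector) -> SampleSummary:
    """Observed richness, depth, singleton percentage and dominance."""
    fc = to_frequency_counts(av)
    singleton_pct = _round_half_up(100.0 * fc.f(1) / av.s_obs)
    return SampleSummary(
        s_obs=av.s_obs,
        n_reads=av.n_reads,
        singleton_pct=singleton_pct,
        top_otu_share=float(av.counts[0]) / av.n_reads,
    )


def rank_abundance(av: AbundanceVector) -> pd.DataFrame:
    """Rank-abundance table: rank, otu_id, count, relative_abundance."""
    n = av.n_reads
    return pd.DataFrame(
        {
            "rank": np.arange(1, av.s_obs + 1),
            "otu_id": list(av.otu_ids),
            "count": av.counts,
            "relative_abundance": av.counts / n,
        }
    )
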