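"""Ground-truth synthetic communities and culture experiments.

Every pipeline stage is testable against data with known truth: a
scenario fixes a TAD family and parameters, a true richness S, a
sequencing depth N and a seed; generation draws relative abundances from
the mixing density, optionally pins one dominant species at a fixed share
of the community (deep-sequenced marine samples can have a single OTU
holding over a third of all reads), and performs one multinomial
sequencing draw.  A companion generator emulates a culture experiment
whose isolates are picked with an abundance-decoupled bias and emits
alignment tables wired so that exactly the isolates present in the
observed OTU table pass the reciprocal filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance_models import TADModel, sample_community, sample_counts
from .culture import OUTFMT6_COLUMNS
from .data_model import AbundanceVector, write_abundance_table

__all__ = [
    "Scenario",
    "generate_dataset",
    "generate_culture_experiment",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class Scenario:
    family: str
    theta: tuple[float, ...]
    s_true: int
    n_reads: int
    seed: int = 0
    dominant_fraction: float | None = None  # pin species 0 at this share
    n_isolates: int | None = None
    culture_bias: float = 0.0  # isolate picking weight ∝ proportion^bias

    def __post_init__(self):
        if self.s_true < 1 or self.n_reads < 1:
            raise ValueError("s_true and n_reads must be >= 1")
        if self.dominant_fraction is not None and not (
            0.0 < self.dominant_fraction < 1.0
        ):
            raise ValueError("dominant_fraction must be in (0, 1)")


def _species_id(i: int) -> str:
    return f"otu{i:05d}"


def true_proportions(scenario: Scenario, rng: np.random.Generator) -> np.ndarray:
    model = TADModel(scenario.family, scenario.theta)
    p = sample_community(model, scenario.s_true, rng)
    if scenario.dominant_fraction is not None and scenario.s_true > 1:
        df = scenario.dominant_fraction
        p = np.concatenate([[df], p[1:] / p[1:].sum() * (1.0 - df)])
    return p


def generate_dataset(
    scenario: Scenario, out_dir: str | Path | None = None
) -> tuple[AbundanceVector, dict]:
    """One synthetic sample: observed OTU table plus the truth record.

    Deterministic per scenario seed.  If ``out_dir`` is given, writes
    ``abundance.tsv`` (observed, nonzero OTUs only) and ``truth.json``
    (S_true, theta, per-species true proportions).
    """
    rng = np.random.default_rng(scenario.seed)
    p = true_proportions(scenario, rng)
    counts = sample_counts(p, scenario.n_reads, rng)
    observed = counts > 0
    av = AbundanceVector(
        tuple(_species_id(i) for i in np.flatnonzero(observed)),
        counts[observed].astype(np.int64),
    )
    truth = {
        "family": scenario.family,
        "theta": list(scenario.theta),
        "s_true": scenario.s_true,
        "n_reads": scenario.n_reads,
        "seed": scenario.seed,
        "dominant_fraction": scenario.dominant_fraction,
        "proportions": {_species_id(i): float(p[i]) for i in range(len(p))},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_abundance_table(av, out / "abundance.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return av, truth


def generate_culture_experiment(
    proportions: np.ndarray,
    n_isolates: int,
    bias: float,
    rng: np.random.Generator,
    observed_species: set[int] | None = None,
) -> dict:
    """Synthetic culture experiment plus reciprocal alignment tables.

    Isolate species are drawn without replacement with probability
    proportional to ``proportion**bias`` (bias 0: uniform; bias < 0:
    rare-favouring, culturing "selecting for the losers").  The emitted
    forward/reverse tables are constructed so that isolates whose species
    is in ``observed_species`` pass every reciprocal-filter threshold and
    all other isolates fail (low identity, no reverse counterpart).

    Returns a dict with ``isolates`` (species indices), ``fwd``/``rev``
    DataFrames in outfmt-6 column order, and ``isolate_lengths``.
    """
    p = np.asarray(proportions, dtype=float)
    S = len(p)
    if n_isolates > S:
        raise ValueError("n_isolates exceeds the number of species")
    w = p**bias
    species = rng.choice(S, size=n_isolates, replace=False, p=w / w.sum())
    observed_species = observed_species or set()
    iso_len = 1300  # typical near-full-length 16S Sanger product
    fwd_rows, rev_rows, lengths = [], [], {}
    for j, sp in enumerate(species):
        iso = f"iso{j:03d}"
        otu = _species_id(int(sp))
        lengths[iso] = iso_len
        if int(sp) in observed_species:
            aln = int(0.85 * iso_len)
            fwd_rows.append(
                (iso, otu, 99.8, aln, 2, 0, 1, aln, 1, aln, 1e-150, 1800.0)
            )
            rev_rows.append(
                (otu, iso, 99.8, aln, 2, 0, 1, aln, 1, aln, 1e-150, 1800.0)
            )
        else:
            # a sub-threshold hit against some sequenced OTU, no reciprocal
            decoy = _species_id(int(sp))
            aln = int(0.80 * iso_len)
            fwd_rows.append(
                (iso, decoy, 92.0, aln, 80, 5, 1, aln, 1, aln, 1e-30, 600.0)
            )
    fwd = pd.DataFrame(fwd_rows, columns=list(OUTFMT6_COLUMNS))
    rev = pd.DataFrame(rev_rows, columns=list(OUTFMT6_COLUMNS))
    return {
        "isolates": species,
        "fwd": fwd,
        "rev": rev,
        "isolate_lengths": lengths,
    }


# ---------------------------------------------------------------------------
# presets emulating the two deeply sequenced marine samples

# Sichel parameters tuned (scripts/tune_presets.py) so that at the preset
# depth ~87% of species are observed and ~17% of observed OTUs are
# singletons; the surface preset additionally pins one dominant OTU at
# 36% of reads.
PRESETS: dict[str, Scenario] = {
    "surface_like": Scenario(
        family="sichel",
        theta=(-0.2, 0.7348427477230167, 0.00048758248565201873),
        s_true=1600,
        n_reads=500_262,
        dominant_fraction=0.36,
        n_isolates=38,
        culture_bias=-0.25,
    ),
    "bottom_like": Scenario(
        family="sichel",
        theta=(-0.6, 2.5758274621614676, 5.5376530228389515e-05),
        s_true=5100,
        n_reads=574_960,
    ),
}

# Desk-scale shrink factors for iteration-heavy suites (coverage checks):
# a tenth of the reads over a third of the species keeps the per-species
# depth within a factor ~3 of the full preset.
_DESK_N = 10
_DESK_S = 3


def preset(name: str, scale: str = "full", seed: int = 0) -> Scenario:
    """A named scenario, at ``full`` or ``desk`` scale.

    Desk scale divides N by 10 and S by 3, rescaling the mixing density's
    mean read count (chi, psi are a scale family) so the count
    distribution keeps its shape at the reduced depth.
    """
    sc = PRESETS[name]
    if scale == "full":
        return replace(sc, seed=seed)
    if scale != "desk":
        raise ValueError("scale must be 'full' or 'desk'")
    s_true = max(sc.s_true // _DESK_S, 2)
    n_reads = max(sc.n_reads // _DESK_N, 1)
    # mean count ratio between desk and full conditions
    ratio = (n_reads / s_true) / (sc.n_reads / sc.s_true)
    model = TADModel(sc.family, sc.theta).scaled(ratio)
    return replace(
        sc, theta=model.theta, s_true=s_true, n_reads=n_reads, seed=seed
    )
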