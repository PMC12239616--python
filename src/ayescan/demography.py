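"""Piecewise-constant demographic history and neutral baseline replicates.

The aye-aye population considered here has an ancestral effective size of
23,706 diploids, an ancient size reduction plausibly tied to human
colonization of Madagascar (3,000-5,000 years ago), and a recent decline tied
to habitat loss over the last few decades.  The exact sizes and times of the
two declines were fitted elsewhere and are NOT reproduced here: the default
non-ancestral epochs below are configuration values chosen to match that
qualitative history, not fitted quantities.

Neutral chromosome replicates are generated with msprime under the piecewise
model and reduced to folded, polymorphic-only allele-frequency records; these
replicates are the raw material for the scans' conservative null thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .io_formats import AlleleFrequencyRecord
from .sfs_stats import fold

__all__ = [
    "Epoch",
    "PiecewiseDemography",
    "NeutralReplicate",
    "ANCESTRAL_SIZE",
    "DEFAULT_GENERATION_TIME_YEARS",
    "neutral_chromosome_replicate",
]

#: Ancestral diploid effective population size.
ANCESTRAL_SIZE = 23_706

#: Years per generation used to convert calendar times (config value; the
#: source analyses do not print one).
DEFAULT_GENERATION_TIME_YEARS = 20.0


@dataclass(frozen=True)
class Epoch:
    """A constant-size epoch: diploid size, start time (generations ago)."""

    size: int
    start: int


@dataclass(frozen=True)
class PiecewiseDemography:
    """Piecewise-constant diploid population-size history.

    Epochs are ordered from the present backward; the first epoch must start
    at generation 0 and start times must strictly increase into the past.
    """

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("demography needs at least one epoch")
        if self.epochs[0].start != 0:
            raise ValueError("most recent epoch must start at generation 0")
        starts = [e.start for e in self.epochs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must strictly increase backward")
        if any(e.size <= 0 for e in self.epochs):
            raise ValueError("epoch sizes must be positive")

    @classmethod
    def constant(cls, size: int) -> "PiecewiseDemography":
        return cls((Epoch(size, 0),))

    @classmethod
    def default_aye_aye(cls) -> "PiecewiseDemography":
        """Three-epoch default: ancestral 23,706; ancient reduction to 3,000 at
        200 generations ago (~4,000 years at 20 y/generation); recent decline
        to 1,000 at 3 generations ago.  Non-ancestral values are placeholders
        for the externally fitted model (see module docstring)."""
        return cls(
            (
                Epoch(1_000, 0),
                Epoch(3_000, 3),
                Epoch(ANCESTRAL_SIZE, 200),
            )
        )

    @classmethod
    def from_json(cls, path) -> "PiecewiseDemography":
        """Load epochs from a JSON config: {"epochs": [[size, start], ...]},
        ordered from the present backward."""
        import json
        from pathlib import Path

        data = json.loads(Path(path).read_text())
        return cls(tuple(Epoch(int(s), int(t)) for s, t in data["epochs"]))

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(
            json.dumps({"epochs": [[e.size, e.start] for e in self.epochs]}) + "\n"
        )

    @property
    def ancestral_size(self) -> int:
        return self.epochs[-1].size

    def size_at(self, generations_ago: float) -> int:
        current = self.epochs[0].size
        for epoch in self.epochs:
            if generations_ago >= epoch.start:
                current = epoch.size
        return current

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name="pop0", initial_size=self.epochs[0].size)
        for epoch in self.epochs[1:]:
            dem.add_population_parameters_change(
                time=epoch.start, initial_size=epoch.size, population="pop0"
            )
        return dem


@dataclass(frozen=True)
class NeutralReplicate:
    """One simulated neutral chromosome: folded polymorphic sites + haplotypes."""

    chrom: str
    length: int
    mu: float
    rec: float
    records: tuple[AlleleFrequencyRecord, ...]
    seed: int
    #: 0/1 haplotype matrix, shape (n_chrom, n_sites), columns matching records.
    haplotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for r in self.records:
            if not 1 <= r.position <= self.length:
                raise ValueError(f"record position {r.position} outside [1, {self.length}]")


def neutral_chromosome_replicate(
    model: PiecewiseDemography,
    L: int,
    mu: float,
    rec: float,
    n_chrom: int = 10,
    *,
    seed: int,
    chrom: str = "chr",
) -> NeutralReplicate:
    """Simulate one neutral chromosome under the piecewise model.

    Coalescent sample of ``n_chrom`` chromosomes (``n_chrom`` must be even;
    sampled as diploids), biallelic infinite-sites-style variants on a
    discrete physical map, folded and restricted to polymorphic sites.
    """
    if L < 1:
        raise ValueError("chromosome length must be >= 1 bp")
    if mu < 0 or rec < 0:
        raise ValueError("rates must be non-negative")
    if n_chrom < 2 or n_chrom % 2:
        raise ValueError("n_chrom must be an even integer >= 2")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    seed = int(seed) % (2**31 - 2) + 1

    ts = msprime.sim_ancestry(
        samples=n_chrom // 2,
        demography=model.to_msprime(),
        sequence_length=L,
        recombination_rate=rec,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=mu,
        random_seed=seed,
        model=msprime.BinaryMutationModel(),
        discrete_genome=True,
    )

    records: list[AlleleFrequencyRecord] = []
    haps: list[np.ndarray] = []
    for var in mts.variants():
        if len(var.alleles) != 2:
            continue  # recurrent mutation created a non-biallelic site
        genotypes = var.genotypes
        c = int(genotypes.sum())
        x = fold(c, n_chrom)
        if x == 0:
            continue
        pos = int(var.site.position) + 1  # tskit is 0-based
        if records and records[-1].position == pos:
            continue  # collision after discretization; keep first
        records.append(AlleleFrequencyRecord(pos, x, n_chrom))
        haps.append(genotypes.astype(np.int8))

    hap_matrix = (
        np.array(haps, dtype=np.int8).T
        if haps
        else np.zeros((n_chrom, 0), dtype=np.int8)
    )
    return NeutralReplicate(
        chrom=chrom,
        length=L,
        mu=mu,
        rec=rec,
        records=tuple(records),
        seed=seed,
        haplotypes=hap_matrix,
    )
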