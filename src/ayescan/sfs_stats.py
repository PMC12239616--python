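"""Folded site-frequency-spectrum utilities.

The genome scans in this package are built on the folded SFS of a sample of
``n`` chromosomes: the distribution of minor-allele counts ``k = 1..n//2``
across polymorphic sites.  This module provides folding, estimation of the
genome-wide background spectrum (the scans' null model), hypergeometric
projection to smaller sample sizes (needed by the sweep model, which reasons
about the ancestral lineages that survive a sweep), and SNP-count windowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .io_formats import AlleleFrequencyRecord

__all__ = [
    "FoldedSFS",
    "SNPWindow",
    "fold",
    "background_spectrum",
    "symmetrize_folded",
    "refold",
    "project_spectrum",
    "snp_windows",
]

_TOL = 1e-12


@dataclass(frozen=True)
class FoldedSFS:
    """Probability distribution over folded frequency classes 1..n//2.

    ``probs[k-1]`` is the probability that a polymorphic site has minor-allele
    count ``k`` in a sample of ``n`` chromosomes.
    """

    n: int
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if self.n < 2:
            raise ValueError(f"sample size must be >= 2, got {self.n}")
        if p.shape != (self.n // 2,):
            raise ValueError(
                f"expected {self.n // 2} folded classes for n={self.n}, got {p.shape}"
            )
        if np.any(p < -_TOL):
            raise ValueError("negative probability in folded SFS")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"folded SFS must sum to 1, got {p.sum()!r}")

    @classmethod
    def from_counts(cls, n: int, counts: np.ndarray) -> "FoldedSFS":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("cannot normalize an empty class-count vector")
        return cls(n, counts / total)

    def prob(self, k: int) -> float:
        return float(self.probs[k - 1])


@dataclass(frozen=True)
class SNPWindow:
    """A window of W consecutive SNPs, positioned at its physical midpoint."""

    records: tuple[AlleleFrequencyRecord, ...]
    center: float

    @property
    def start(self) -> int:
        return self.records[0].position

    @property
    def end(self) -> int:
        return self.records[-1].position


def fold(k: int, n: int) -> int:
    """Minor-allele count for derived count ``k`` in a sample of ``n``."""
    if not 0 <= k <= n:
        raise ValueError(f"allele count {k} outside [0, {n}]")
    return min(k, n - k)


def background_spectrum(
    records: Sequence[AlleleFrequencyRecord], *, pseudocount: float = 0.0
) -> FoldedSFS:
    """Estimate the empirical folded background spectrum from pooled records.

    This is the model-free null ("SpectFile") used by both scan statistics:
    G(k) = #{sites with minor count k} / #sites.  A small ``pseudocount``
    added to every class keeps the spectrum complete when the pooled data are
    sparse (the scans require G(k) > 0 for every observed class).
    """
    if len(records) == 0:
        raise ValueError("cannot estimate a spectrum from zero records")
    sizes = {r.n for r in records}
    if len(sizes) != 1:
        raise ValueError(f"mixed sample sizes in records: {sorted(sizes)}")
    n = sizes.pop()
    counts = np.full(n // 2, float(pseudocount))
    for r in records:
        counts[r.x - 1] += 1
    return FoldedSFS.from_counts(n, counts)


def symmetrize_folded(sfs: FoldedSFS) -> np.ndarray:
    """Spread folded mass onto an unfolded vector over derived counts 0..n.

    Mass G(k) is split equally between derived counts k and n-k; the
    self-symmetric class k = n/2 (even n) keeps its full mass.  Monomorphic
    classes 0 and n carry zero mass.
    """
    n = sfs.n
    g = np.zeros(n + 1)
    for k in range(1, n // 2 + 1):
        if 2 * k == n:
            g[k] = sfs.probs[k - 1]
        else:
            g[k] += sfs.probs[k - 1] / 2.0
            g[n - k] += sfs.probs[k - 1] / 2.0
    return g


def refold(unfolded: np.ndarray, *, min_mass: float = 1e-300) -> FoldedSFS:
    """Fold an unfolded probability vector over 0..n, conditioning on polymorphism."""
    unfolded = np.asarray(unfolded, dtype=float)
    n = len(unfolded) - 1
    counts = np.zeros(n // 2)
    for k in range(1, n):
        counts[fold(k, n) - 1] += unfolded[k]
    total = counts.sum()
    if total < min_mass:
        raise ValueError(
            "polymorphic mass below numerical floor while refolding "
            "(degenerate spectrum)"
        )
    return FoldedSFS(n, counts / total)


def project_spectrum(p: np.ndarray, j: int) -> np.ndarray:
    """Project an unfolded spectrum from sample size n down to size j.

    ``p`` is a probability vector over derived counts 0..n.  The returned
    vector over 0..j is the distribution of the derived count in a
    hypergeometric subsample of j of the n chromosomes:

        P_j(a) = sum_k p(k) C(k,a) C(n-k, j-a) / C(n,j)
    """
    p = np.asarray(p, dtype=float)
    n = len(p) - 1
    if not 1 <= j <= n:
        raise ValueError(f"subsample size {j} outside [1, {n}]")
    if j == n:
        return p.copy()
    # hypergeom.pmf(a; M=n, n=k, N=j) = C(k,a) C(n-k, j-a) / C(n,j)
    a = np.arange(j + 1)
    k = np.arange(n + 1)
    weights = hypergeom.pmf(a[:, None], n, k[None, :], j)
    return weights @ p


def snp_windows(
    records: Sequence[AlleleFrequencyRecord], W: int, S: int
) -> list[SNPWindow]:
    """Slide a window of W SNPs with step S SNPs; only full windows are kept.

    Window position is the physical midpoint of its first and last SNP.
    """
    if W < 2:
        raise ValueError(f"window size must be >= 2 SNPs, got {W}")
    if not 1 <= S <= W:
        raise ValueError(f"step must be in [1, W={W}], got {S}")
    out: list[SNPWindow] = []
    for start in range(0, len(records) - W + 1, S):
        members = tuple(records[start : start + W])
        center = (members[0].position + members[-1].position) / 2.0
        out.append(SNPWindow(members, center))
    return out
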