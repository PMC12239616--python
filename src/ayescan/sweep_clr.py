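"""Composite likelihood ratio scan for completed selective sweeps.

At each test position t the composite likelihood of all sites on the
chromosome is maximized over a sweep-intensity parameter alpha and compared
with the likelihood under the genome-wide background spectrum G.  A site at
physical distance d from the sweep has escape probability

    p_e = 1 - exp(-alpha * d)

per lineage: lineages that fail to escape coalesce into the single sweeping
haplotype, which skews the SFS toward rare and high-frequency alleles near
the sweep.  The sweep-perturbed spectrum is built from G itself (folded data:
G is symmetrized onto derived counts, perturbed, and re-folded), so the null
is nested in the alternative and CLR >= 0.

    CLR(t) = 2 [ max_alpha sum_i log P_{alpha,|pos_i - t|}(x_i)
                 - sum_i log G(x_i) ]
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import binom

from .io_formats import AlleleFrequencyRecord
from .sfs_stats import FoldedSFS, fold, project_spectrum, refold, symmetrize_folded

__all__ = [
    "ScanRecord",
    "escape_probability",
    "sweep_spectrum",
    "SweepScanTable",
    "sweep_clr_at",
    "scan_sweep",
    "default_alpha_grid",
]

_PE_FLOOR = 1e-12


@dataclass(frozen=True)
class ScanRecord:
    """One scan result: a CLR value with its maximizing parameters.

    ``position`` is a SNP position (sweep scan) or a window center (balancing
    scan); window records also carry the window span [start, end].
    """

    position: float
    clr: float
    alpha_hat: float | None = None
    x_hat: float | None = None
    a_hat: float | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.clr < -1e-9:
            raise ValueError(f"CLR must be non-negative, got {self.clr}")


def default_alpha_grid(n_points: int = 48) -> np.ndarray:
    """Log-spaced sweep-intensity grid, weak to strong, per-bp scale."""
    return np.geomspace(1e-8, 1e-1, n_points)


def escape_probability(alpha: float, d: float) -> float:
    """Per-lineage probability of recombining off the sweep at distance d bp."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    return float(np.clip(-np.expm1(-alpha * d), _PE_FLOOR, 1.0))


def sweep_spectrum(G: FoldedSFS, p_e: float) -> FoldedSFS:
    """Sweep-perturbed folded spectrum at escape probability p_e.

    Generative model: each of the n sampled lineages escapes the sweep
    independently with probability p_e.  The e escapees plus the single
    sweeping haplotype form j = e + 1 ancestral lineages whose derived count
    a is drawn from the (symmetrized) background projected to size j; the
    sweeping ancestor is one of the j uniformly, and the n - e hitchhiking
    lineages copy its allele.  The result is folded, conditioned on
    polymorphism, and renormalized.
    """
    if not 0 < p_e <= 1:
        raise ValueError(f"escape probability must be in (0, 1], got {p_e}")
    n = G.n
    g = symmetrize_folded(G)
    acc = np.zeros(n + 1)
    e_weights = binom.pmf(np.arange(n + 1), n, p_e)
    for e in range(n + 1):
        w = e_weights[e]
        if w == 0.0:
            continue
        if e == n:
            acc += w * g
            continue
        j = e + 1
        Pj = project_spectrum(g, j)
        for a in range(j + 1):
            pa = Pj[a]
            if pa == 0.0:
                continue
            # sweeping ancestor derived (prob a/j): hitchhikers add n - e copies
            if a > 0:
                acc[a - 1 + n - e] += w * pa * a / j
            # sweeping ancestor ancestral (prob (j-a)/j)
            if a < j:
                acc[a] += w * pa * (j - a) / j
    return refold(acc)


class SweepScanTable:
    """Precomputed per-class log-likelihood table over a grid of alpha*d.

    The product q = alpha * d fully determines p_e, so spectra are tabulated
    once on a log-spaced q grid; bin nbins holds q >= q_max, where p_e is
    treated as exactly 1 and the spectrum equals the background (sites beyond
    this cutoff contribute exactly their null likelihood).
    """

    def __init__(
        self,
        G: FoldedSFS,
        *,
        q_min: float = 1e-9,
        q_max: float = 30.0,
        n_bins: int = 160,
    ) -> None:
        if np.any(G.probs <= 0):
            raise ValueError(
                "background spectrum has an empty class; smooth or pool more data"
            )
        self.G = G
        self.q_min = q_min
        self.q_max = q_max
        self.n_bins = n_bins
        self.step = math.log(q_max / q_min) / n_bins
        K = G.n // 2
        self.log_table = np.empty((n_bins + 1, K))
        for i in range(n_bins):
            q = q_min * math.exp((i + 0.5) * self.step)
            p_e = float(np.clip(-np.expm1(-q), _PE_FLOOR, 1.0))
            self.log_table[i] = np.log(sweep_spectrum(G, p_e).probs)
        self.log_table[n_bins] = np.log(G.probs)  # unlinked limit: background
        self.log_G = np.log(G.probs)

    def alpha_offsets(self, alpha_grid: np.ndarray) -> np.ndarray:
        """Per-alpha additive offsets so bin(q) = floor(ln(d)/step + offset)."""
        return (np.log(alpha_grid) - math.log(self.q_min)) / self.step


@njit(cache=True)
def _sweep_scan_core(positions, classes, tgrid, offsets, inv_step, log_table, log_G):
    n_sites = positions.shape[0]
    n_alpha = offsets.shape[0]
    n_bins = log_table.shape[0] - 1
    null_sum = 0.0
    for i in range(n_sites):
        null_sum += log_G[classes[i]]
    clr = np.empty(tgrid.shape[0])
    ahat = np.empty(tgrid.shape[0], dtype=np.int64)
    base = np.empty(n_sites)
    for ti in range(tgrid.shape[0]):
        t = tgrid[ti]
        for i in range(n_sites):
            d = abs(positions[i] - t)
            base[i] = math.log(d) * inv_step if d > 0 else -1e18
        best = -1e300
        best_a = -1
        for ai in range(n_alpha):
            off = offsets[ai]
            s = 0.0
            for i in range(n_sites):
                idx = int(math.floor(base[i] + off))
                if idx < 0:
                    idx = 0
                elif idx > n_bins:
                    idx = n_bins
                s += log_table[idx, classes[i]]
            if s > best:
                best = s
                best_a = ai
        value = 2.0 * (best - null_sum)
        if value <= 0.0:  # the neutral limit (no sweep) is always available
            value = 0.0
            best_a = -1
        clr[ti] = value
        ahat[ti] = best_a
    return clr, ahat


def _as_arrays(records: list[AlleleFrequencyRecord]) -> tuple[np.ndarray, np.ndarray]:
    records = sorted(records, key=lambda r: r.position)
    positions = np.array([r.position for r in records], dtype=np.float64)
    classes = np.array([r.x - 1 for r in records], dtype=np.int64)
    return positions, classes


def scan_sweep(
    records: list[AlleleFrequencyRecord],
    G: FoldedSFS,
    *,
    grid: np.ndarray | None = None,
    alpha_grid: np.ndarray | None = None,
    table: SweepScanTable | None = None,
) -> list[ScanRecord]:
    """Sweep CLR at every SNP position (or at an explicit position grid).

    The neutral limit is always included alongside the alpha grid, so
    CLR >= 0 everywhere.  Output is deterministic and invariant to the input
    ordering of records.
    """
    if not records:
        raise ValueError("cannot scan zero records")
    positions, classes = _as_arrays(records)
    if grid is None:
        tgrid = positions.copy()
    else:
        tgrid = np.asarray(grid, dtype=np.float64)
        if tgrid.size == 0:
            raise ValueError("empty test-position grid")
    if table is None:
        table = SweepScanTable(G)
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    offsets = table.alpha_offsets(alpha_grid)
    clr, ahat = _sweep_scan_core(
        positions, classes, tgrid, offsets, 1.0 / table.step, table.log_table, table.log_G
    )
    return [
        ScanRecord(
            position=float(t),
            clr=float(c),
            alpha_hat=float(alpha_grid[a]) if a >= 0 else None,
        )
        for t, c, a in zip(tgrid, clr, ahat)
    ]


def sweep_clr_at(
    t: float,
    records: list[AlleleFrequencyRecord],
    G: FoldedSFS,
    alpha_grid: np.ndarray | None = None,
    *,
    table: SweepScanTable | None = None,
) -> ScanRecord:
    """Sweep CLR at a single test position."""
    return scan_sweep(
        records, G, grid=np.array([t], dtype=float), alpha_grid=alpha_grid, table=table
    )[0]
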