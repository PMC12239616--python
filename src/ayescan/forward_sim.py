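"""Forward Wright-Fisher simulation with selection, used for power analysis.

The simulated region mimics a common stretch of aye-aye genomic architecture:
3 genes, each of 9 exons of 130 bp separated by 8 introns of 1,591 bp, each
gene followed by 16,489 bp of intergenic DNA — 91,161 bp in total.  Exonic
mutations draw selection coefficients from a 4-class DFE in 2Ns bins
[0,1), [1,10), [10,100), [100, 2N) (uniform within each bin, reference
N = 23,706); intronic and intergenic mutations are neutral.  Mutation and
recombination rates vary per 1-kb block.

Scenarios: a selective sweep (beneficial mutation with population-scaled
strength 2Ns introduced tau*N generations before sampling; replicates are
retained only if it fixes) or long-term balancing selection (negative
frequency dependence, S_bp = F_eq - F_bp recomputed every generation;
replicates are retained only if the balanced allele is still segregating).
On loss, non-fixation (sweep), or fixation of the balanced allele, the
simulation restarts from its state at the introduction time.

Runs have a 10N-generation burn-in; sweeps then run for 10N generations and
balancing scenarios for 85N.  A rescaling factor Q divides population sizes
and durations and multiplies rates and selection coefficients, preserving
population-scaled parameters; Q = 1 reproduces the full scale (cluster
budget), Q = 100 is the desk-scale default used by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit

from .demography import ANCESTRAL_SIZE, PiecewiseDemography
from .io_formats import AlleleFrequencyRecord
from .sfs_stats import fold

__all__ = [
    "GenomeArchitecture",
    "build_architecture",
    "DFEConfig",
    "sample_dfe",
    "assign_rate_map",
    "frequency_dependent_coefficient",
    "frequency_dependent_trajectory",
    "SelectionScenario",
    "SimulationResult",
    "RestartLimitError",
    "ForwardSimulator",
    "run_forward",
    "MU_FIXED",
    "REC_FIXED",
    "MU_BOUNDS",
    "REC_BOUNDS",
]

#: Fixed per-bp per-generation mutation rate (lemur pedigree estimate).
MU_FIXED = 1.52e-8
#: Fixed per-bp per-generation recombination rate (1 cM/Mb).
REC_FIXED = 1e-8
#: Uniform bounds for heterogeneous mutation rates (0.5x and 2.5x fixed).
MU_BOUNDS = (0.61e-8, 3.8e-8)
#: Uniform bounds for heterogeneous recombination rates (0.01 and 10 cM/Mb).
REC_BOUNDS = (1e-10, 1e-7)

_EXON, _INTRON, _INTERGENIC = 2, 1, 0


class RestartLimitError(RuntimeError):
    """The scenario exceeded its restart cap (e.g. a sweep that cannot fix)."""


# ---------------------------------------------------------------------------
# Genomic architecture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeArchitecture:
    """Ordered exon/intron/intergenic elements tiling [1, L] (1-based closed)."""

    elements: tuple[tuple[str, int, int], ...]
    length: int

    def __post_init__(self) -> None:
        expected = 1
        for cls, start, end in self.elements:
            if cls not in ("exon", "intron", "intergenic"):
                raise ValueError(f"unknown element class {cls!r}")
            if start != expected or end < start:
                raise ValueError("elements must tile [1, L] without gaps or overlaps")
            expected = end + 1
        if expected != self.length + 1:
            raise ValueError(f"elements cover {expected - 1} bp, expected {self.length}")

    def site_classes(self) -> np.ndarray:
        """Per-bp class codes (0 intergenic, 1 intron, 2 exon), length L."""
        codes = {"intergenic": _INTERGENIC, "intron": _INTRON, "exon": _EXON}
        out = np.empty(self.length, dtype=np.uint8)
        for cls, start, end in self.elements:
            out[start - 1 : end] = codes[cls]
        return out

    def exons(self) -> list[tuple[int, int]]:
        return [(s, e) for cls, s, e in self.elements if cls == "exon"]

    def default_selected_position(self) -> int:
        """Center of the middle gene's middle exon (configurable convention)."""
        exons = self.exons()
        mid = exons[len(exons) // 2]
        return (mid[0] + mid[1]) // 2


def build_architecture(
    n_genes: int = 3,
    exons_per_gene: int = 9,
    exon_len: int = 130,
    intron_len: int = 1591,
    intergenic_len: int = 16489,
) -> GenomeArchitecture:
    """Build the alternating gene/intergenic tiling (defaults: 91,161 bp)."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if min(exons_per_gene, exon_len, intron_len) < 1 or intergenic_len < 0:
        raise ValueError("element counts/lengths must be positive")
    elements: list[tuple[str, int, int]] = []
    pos = 1
    for _ in range(n_genes):
        for e in range(exons_per_gene):
            elements.append(("exon", pos, pos + exon_len - 1))
            pos += exon_len
            if e < exons_per_gene - 1:
                elements.append(("intron", pos, pos + intron_len - 1))
                pos += intron_len
        if intergenic_len > 0:
            elements.append(("intergenic", pos, pos + intergenic_len - 1))
            pos += intergenic_len
    return GenomeArchitecture(tuple(elements), pos - 1)


# ---------------------------------------------------------------------------
# DFE and rate maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DFEConfig:
    """4-class DFE over population-scaled strengths 2Ns.

    Bins: [0,1) effectively neutral, [1,10) weak, [10,100) moderate,
    [100, 2N) strong; s is uniform within each bin and measures the fitness
    reduction of the mutant homozygote.  The default class proportions follow
    published human/aye-aye DFE estimates (external defaults, configurable).
    """

    proportions: tuple[float, float, float, float] = (0.25, 0.49, 0.04, 0.22)
    reference_N: int = ANCESTRAL_SIZE
    dominance: float = 0.5

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0):
            raise ValueError(f"DFE proportions must be non-negative: {self.proportions}")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"DFE proportions must sum to 1, got {p.sum()!r}")

    @property
    def bin_bounds(self) -> np.ndarray:
        """(4, 2) array of [lo, hi) bounds in 2Ns units."""
        return np.array(
            [[0.0, 1.0], [1.0, 10.0], [10.0, 100.0], [100.0, 2.0 * self.reference_N]]
        )


def sample_dfe(config: DFEConfig, rng: np.random.Generator) -> float:
    """Draw one selection coefficient s >= 0 (deleterious sign applied by caller)."""
    cls = rng.choice(4, p=np.asarray(config.proportions, dtype=float))
    lo, hi = config.bin_bounds[cls]
    two_ns = rng.uniform(lo, hi)
    return two_ns / (2.0 * config.reference_N)


def assign_rate_map(
    L: int,
    block: int = 1000,
    *,
    target_mean: float,
    lo: float,
    hi: float,
    mode: Literal["uniform", "mean_matched"] = "mean_matched",
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-block rates within [lo, hi], one value per 1-kb block.

    "uniform" draws literally from U(lo, hi); "mean_matched" rescales the
    draws so the chromosome-wide average matches ``target_mean`` within 1%
    (the bins' midpoint does not equal the fixed genome-wide rates, so a
    literal uniform draw would not average to them).
    """
    if lo > hi:
        raise ValueError(f"lo {lo} > hi {hi}")
    n_blocks = -(-L // block)
    rates = rng.uniform(lo, hi, size=n_blocks)
    if mode == "uniform":
        return rates
    if mode != "mean_matched":
        raise ValueError(f"unknown rate-map mode {mode!r}")
    if not lo <= target_mean <= hi:
        raise ValueError(f"target mean {target_mean} outside [{lo}, {hi}]")
    for _ in range(64):
        current = rates.mean()
        if abs(current - target_mean) <= 0.01 * target_mean:
            return rates
        rates = np.clip(rates * (target_mean / current), lo, hi)
    raise RuntimeError("mean-matched rate map failed to converge")


def frequency_dependent_coefficient(F_eq: float, F_bp: float) -> float:
    """Per-generation selection coefficient of the balanced allele: F_eq - F_bp."""
    if not (0.0 <= F_eq <= 1.0 and 0.0 <= F_bp <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    return F_eq - F_bp


def frequency_dependent_trajectory(
    n_diploid: int,
    n_gen: int,
    *,
    F_eq: float = 0.5,
    h: float = 0.5,
    p0: float = 0.05,
    seed: int,
    restart_cap: int = 1000,
) -> np.ndarray:
    """Single-locus Wright-Fisher trajectory under negative frequency dependence.

    Genotype fitnesses are 1, 1 + h*S, 1 + S with S = F_eq - F_bp recomputed
    each generation from the current frequency F_bp.  On loss or fixation the
    run restarts from the introduction frequency ``p0`` at generation 0.
    Returns the allele-frequency series, length ``n_gen``.
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * n_diploid
    freqs = np.empty(n_gen)
    restarts = 0
    g = 0
    p = p0
    while g < n_gen:
        S = frequency_dependent_coefficient(F_eq, p)
        w_bb, w_het, w_hom = 1.0, 1.0 + h * S, 1.0 + S
        mean_w = p * p * w_hom + 2 * p * (1 - p) * w_het + (1 - p) ** 2 * w_bb
        p_sel = (p * p * w_hom + p * (1 - p) * w_het) / mean_w
        p = rng.binomial(two_n, p_sel) / two_n
        if p <= 0.0 or p >= 1.0:
            restarts += 1
            if restarts > restart_cap:
                raise RestartLimitError("balanced allele repeatedly absorbed")
            g = 0
            p = p0
            continue
        freqs[g] = p
        g += 1
    return freqs


# ---------------------------------------------------------------------------
# Scenario / result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionScenario:
    """Parameters of the (single) selected mutation, or a neutral run.

    ``tau`` is the introduction time in units of N generations before
    sampling: typical sweep values {0.1, 0.2, 0.5, 1, 2}; balancing values
    {10, 50, 75}.  ``s2N`` is the beneficial strength 2Ns for sweeps;
    ``f_eq`` the equilibrium frequency for balancing.
    """

    mode: Literal["neutral", "sweep", "balancing"]
    tau: float | None = None
    s2N: float | None = None
    f_eq: float | None = None
    selected_pos: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "neutral":
            if self.tau is not None or self.s2N is not None or self.f_eq is not None:
                raise ValueError("neutral scenario takes no selection parameters")
            return
        if self.tau is None or self.tau <= 0:
            raise ValueError("non-neutral scenario needs an introduction time tau > 0")
        if self.mode == "sweep":
            if self.s2N is None or self.s2N <= 0:
                raise ValueError("sweep scenario needs 2Ns > 0")
            if self.tau > 10:
                raise ValueError("sweep tau exceeds the 10N post-burn-in span")
        elif self.mode == "balancing":
            if self.f_eq is None or not 0 < self.f_eq <= 0.5:
                raise ValueError("balancing scenario needs f_eq in (0, 0.5]")
            if self.tau > 85:
                raise ValueError("balancing tau exceeds the 85N post-burn-in span")
        else:
            raise ValueError(f"unknown scenario mode {self.mode!r}")

    @property
    def span_N(self) -> float:
        """Post-burn-in duration in units of N generations."""
        return 10.0 if self.mode in ("neutral", "sweep") else 85.0


@dataclass(frozen=True)
class SimulationResult:
    """Sampled output of one retained forward replicate."""

    records: tuple[AlleleFrequencyRecord, ...]
    haplotypes: np.ndarray = field(repr=False)
    scenario: SelectionScenario
    selected_pos: int | None
    final_state: str | None  # "fixed" | "segregating" | None
    final_freq: float | None
    n_restarts: int
    seed: int
    Q: float


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _invert_map(cum, block_len, L, u):
    """Map u in [0, cum[-1]) to a 1-based bp position via the block map."""
    b = np.searchsorted(cum, u, side="right") - 1
    if b < 0:
        b = 0
    if b >= cum.shape[0] - 1:
        b = cum.shape[0] - 2
    width = cum[b + 1] - cum[b]
    frac = (u - cum[b]) / width if width > 0 else 0.0
    blk_bp = min(block_len, L - b * block_len)
    off = int(frac * blk_bp)
    if off >= blk_bp:
        off = blk_bp - 1
    return b * block_len + off + 1


@njit(cache=True)
def _generation(
    cur,
    nxt,
    pos,
    scoef,
    occ,
    nsites,
    n_par,
    n_child,
    mut_cum,
    rec_cum,
    block_len,
    L,
    site_class,
    dfe_cum,
    dfe_lo,
    dfe_hi,
    two_n_ref,
    q_scale,
    h,
    focal_col,
    focal_mode,
    focal_s,
    f_eq,
    cap,
):
    """One WF generation: selection, recombination, mutation, focal checks.

    Returns (nsites, focal_col, status); status 0 = ok, 1 = focal lost,
    2 = balanced focal fixed, 3 = site capacity exceeded.
    """
    two_n_par = 2 * n_par
    two_n_child = 2 * n_child

    # --- viability/fertility weights (multiplicative across sites) ---
    w = np.ones(n_par)
    for j in range(nsites):
        s = scoef[j]
        if j == focal_col:
            if focal_mode == 1:
                s = focal_s
            else:
                cnt = 0
                for i in range(two_n_par):
                    cnt += cur[i, j]
                # S_bp = F_eq - F_bp is already O(1): multiplying by Q
                # would leave the model's domain (negative fitnesses), so
                # the frequency-dependent coefficient is not rescaled
                s = f_eq - cnt / two_n_par
        if s != 0.0:
            w_het = 1.0 + h * s
            w_hom = 1.0 + s
            if w_het < 0.0:
                w_het = 0.0
            if w_hom < 0.0:
                w_hom = 0.0
            for i in range(n_par):
                c = cur[2 * i, j] + cur[2 * i + 1, j]
                if c == 1:
                    w[i] *= w_het
                elif c == 2:
                    w[i] *= w_hom
    cw = np.cumsum(w)
    total_w = cw[-1]
    if total_w <= 0.0:
        for i in range(n_par):
            cw[i] = i + 1.0
        total_w = float(n_par)

    # --- reproduction with recombination ---
    R_total = rec_cum[-1]
    cx = np.empty(8, dtype=np.int64)
    for child in range(n_child):
        for slot in range(2):
            row = 2 * child + slot
            u = np.random.random() * total_w
            par = np.searchsorted(cw, u)
            if par >= n_par:
                par = n_par - 1
            n_cx = np.random.poisson(R_total)
            h0 = 2 * par + (1 if np.random.random() < 0.5 else 0)
            if n_cx == 0:
                src = cur[h0]
                dst = nxt[row]
                for j in range(nsites):
                    dst[j] = src[j]
            else:
                if n_cx > 8:
                    n_cx = 8
                for k in range(n_cx):
                    cx[k] = _invert_map(rec_cum, block_len, L, np.random.random() * R_total)
                h1 = 2 * par + (1 - (h0 - 2 * par))
                src0 = cur[h0]
                src1 = cur[h1]
                dst = nxt[row]
                if n_cx == 1:
                    c0 = cx[0]
                    for j in range(nsites):
                        dst[j] = src0[j] if pos[j] < c0 else src1[j]
                else:
                    for j in range(nsites):
                        switches = 0
                        for k in range(n_cx):
                            if cx[k] < pos[j]:
                                switches += 1
                        dst[j] = src0[j] if switches % 2 == 0 else src1[j]

    # --- new mutations in the offspring ---
    U_pop = mut_cum[-1] * two_n_child
    n_mut = np.random.poisson(U_pop)
    if n_mut > 0:
        if nsites + n_mut > cap:
            return nsites, focal_col, 3
        # clear the new-column region row-wise (cache-friendly), then set bits
        for i in range(two_n_child):
            for j in range(nsites, nsites + n_mut):
                nxt[i, j] = 0
        n_placed = 0
        for m in range(n_mut):
            bp = _invert_map(mut_cum, block_len, L, np.random.random() * mut_cum[-1])
            if occ[bp - 1] != 0:
                continue
            occ[bp - 1] = 1
            row = int(np.random.random() * two_n_child)
            if row >= two_n_child:
                row = two_n_child - 1
            col = nsites + n_placed
            nxt[row, col] = 1
            pos[col] = bp
            s_new = 0.0
            if site_class[bp - 1] == 2:
                u2 = np.random.random()
                cls = np.searchsorted(dfe_cum, u2, side="right")
                if cls > 3:
                    cls = 3
                two_ns = dfe_lo[cls] + np.random.random() * (dfe_hi[cls] - dfe_lo[cls])
                s_new = -(two_ns / two_n_ref) * q_scale
            scoef[col] = s_new
            n_placed += 1
        nsites += n_placed

    # --- focal-allele bookkeeping ---
    status = 0
    if focal_col >= 0:
        cnt = 0
        for i in range(two_n_child):
            cnt += nxt[i, focal_col]
        if cnt == 0:
            status = 1
        elif cnt == two_n_child:
            if focal_mode == 1:
                focal_col = -2  # sweep completed; column pruned as monomorphic
            else:
                status = 2
    return nsites, focal_col, status


@njit(cache=True)
def _prune(cur, pos, scoef, occ, nsites, two_n, focal_col):
    """Drop monomorphic columns in place; returns (nsites, focal_col).

    Column sums and compaction run row-wise to keep memory access sequential.
    """
    counts = np.zeros(nsites, dtype=np.int64)
    for i in range(two_n):
        row = cur[i]
        for j in range(nsites):
            counts[j] += row[j]
    keep = np.empty(nsites, dtype=np.int64)
    n_keep = 0
    new_focal = focal_col if focal_col < 0 else -1
    for j in range(nsites):
        if 0 < counts[j] < two_n:
            if j == focal_col:
                new_focal = n_keep
            keep[n_keep] = j
            n_keep += 1
        else:
            occ[pos[j] - 1] = 0
    if n_keep == nsites:
        return nsites, focal_col
    for i in range(two_n):
        row = cur[i]
        for w in range(n_keep):
            row[w] = row[keep[w]]
    for w in range(n_keep):
        pos[w] = pos[keep[w]]
        scoef[w] = scoef[keep[w]]
    return n_keep, new_focal


@njit(cache=True)
def _evolve(
    geno,
    buf,
    pos,
    scoef,
    occ,
    nsites,
    n_dip,
    ngen,
    prune_every,
    mut_cum,
    rec_cum,
    block_len,
    L,
    site_class,
    dfe_cum,
    dfe_lo,
    dfe_hi,
    two_n_ref,
    q_scale,
    h,
    focal_col,
    focal_mode,
    focal_s,
    f_eq,
    cap,
):
    """Run ngen constant-size generations; state ends in ``geno``.

    Returns (nsites, focal_col, status, gens_done).
    """
    parity = 0
    gens_done = 0
    status = 0
    two_n = 2 * n_dip
    for g in range(ngen):
        if parity == 0:
            nsites, focal_col, status = _generation(
                geno, buf, pos, scoef, occ, nsites, n_dip, n_dip,
                mut_cum, rec_cum, block_len, L, site_class,
                dfe_cum, dfe_lo, dfe_hi, two_n_ref, q_scale, h,
                focal_col, focal_mode, focal_s, f_eq, cap,
            )
        else:
            nsites, focal_col, status = _generation(
                buf, geno, pos, scoef, occ, nsites, n_dip, n_dip,
                mut_cum, rec_cum, block_len, L, site_class,
                dfe_cum, dfe_lo, dfe_hi, two_n_ref, q_scale, h,
                focal_col, focal_mode, focal_s, f_eq, cap,
            )
        parity = 1 - parity
        gens_done = g + 1
        if status != 0:
            break
        if (g + 1) % prune_every == 0 or nsites > cap - 256:
            if parity == 0:
                nsites, focal_col = _prune(geno, pos, scoef, occ, nsites, two_n, focal_col)
            else:
                nsites, focal_col = _prune(buf, pos, scoef, occ, nsites, two_n, focal_col)
    if parity == 1:
        for i in range(two_n):
            src = buf[i]
            dst = geno[i]
            for j in range(nsites):
                dst[j] = src[j]
    nsites, focal_col = _prune(geno, pos, scoef, occ, nsites, two_n, focal_col)
    return nsites, focal_col, status, gens_done


@njit(cache=True)
def _resize_step(
    geno,
    buf,
    pos,
    scoef,
    occ,
    nsites,
    n_par,
    n_child,
    mut_cum,
    rec_cum,
    block_len,
    L,
    site_class,
    dfe_cum,
    dfe_lo,
    dfe_hi,
    two_n_ref,
    q_scale,
    h,
    focal_col,
    focal_mode,
    focal_s,
    f_eq,
    cap,
):
    """One generation across a population-size change; state ends in ``geno``."""
    nsites, focal_col, status = _generation(
        geno, buf, pos, scoef, occ, nsites, n_par, n_child,
        mut_cum, rec_cum, block_len, L, site_class,
        dfe_cum, dfe_lo, dfe_hi, two_n_ref, q_scale, h,
        focal_col, focal_mode, focal_s, f_eq, cap,
    )
    two_n = 2 * n_child
    if status == 0 or status == 2:
        nsites, focal_col = _prune(buf, pos, scoef, occ, nsites, two_n, focal_col)
    for i in range(two_n):
        src = buf[i]
        dst = geno[i]
        for j in range(nsites):
            dst[j] = src[j]
    return nsites, focal_col, status


# ---------------------------------------------------------------------------
# Python driver
# ---------------------------------------------------------------------------


class ForwardSimulator:
    """Stateful driver around the numba WF kernels.

    Tracks a clock ``t`` in scaled generations before sampling and applies the
    piecewise demography as it advances.  Supports snapshot/restore (for the
    restart-at-introduction rule) and sampling of diploid individuals.
    """

    def __init__(
        self,
        demography: PiecewiseDemography,
        arch: GenomeArchitecture,
        dfe: DFEConfig,
        *,
        mu_rates: np.ndarray | None = None,
        rec_rates: np.ndarray | None = None,
        block: int = 1000,
        Q: float = 100.0,
        seed: int,
        capacity: int | None = None,
        prune_every: int = 8,
    ) -> None:
        if Q < 1:
            raise ValueError("rescaling factor Q must be >= 1")
        self.demography = demography
        self.arch = arch
        self.dfe = dfe
        self.Q = float(Q)
        self.L = arch.length
        self.block = block
        self.capacity = capacity
        self.prune_every = prune_every
        self.seed = int(seed) % (2**31 - 1)

        n_blocks = -(-self.L // block)
        if mu_rates is None:
            mu_rates = np.full(n_blocks, MU_FIXED)
        if rec_rates is None:
            rec_rates = np.full(n_blocks, REC_FIXED)
        if len(mu_rates) != n_blocks or len(rec_rates) != n_blocks:
            raise ValueError(f"rate maps must have {n_blocks} blocks")
        blk_bp = np.minimum(block, self.L - np.arange(n_blocks) * block)
        self.mut_cum = np.concatenate([[0.0], np.cumsum(mu_rates * blk_bp * self.Q)])
        self.rec_cum = np.concatenate([[0.0], np.cumsum(rec_rates * blk_bp * self.Q)])
        self.site_class = arch.site_classes()
        if capacity is None:
            # expected segregating sites in the whole population (Watterson at
            # 2N) plus churn headroom between prunes
            n_anc = max(2, round(demography.ancestral_size / Q))
            theta_sites = 4 * n_anc * float(np.mean(mu_rates)) * Q * self.L
            harmonic = math.log(2 * n_anc) + 0.577
            churn = prune_every * 2 * n_anc * float(np.mean(mu_rates)) * Q * self.L
            capacity = int(1.6 * (theta_sites * harmonic + churn)) + 512
        self.capacity = capacity

        p = np.asarray(dfe.proportions, dtype=float)
        self.dfe_cum = np.cumsum(p)
        bounds = dfe.bin_bounds
        self.dfe_lo = bounds[:, 0].copy()
        self.dfe_hi = bounds[:, 1].copy()
        self.two_n_ref = 2.0 * dfe.reference_N

        # scaled demography: sizes max(2, round(N/Q)); start times strictly
        # increasing after division by Q
        sizes = [max(2, round(e.size / Q)) for e in demography.epochs]
        starts = []
        prev = -1
        for e in demography.epochs:
            s = max(prev + 1, round(e.start / Q)) if prev >= 0 else 0
            starts.append(s)
            prev = s
        self.scaled_epochs = list(zip(sizes, starts))
        self.N_anc_scaled = sizes[-1]
        n_max = max(sizes)

        self.geno = np.zeros((2 * n_max, capacity), dtype=np.uint8)
        self.buf = np.zeros((2 * n_max, capacity), dtype=np.uint8)
        self.pos = np.zeros(capacity, dtype=np.int64)
        self.scoef = np.zeros(capacity, dtype=np.float64)
        self.occ = np.zeros(self.L, dtype=np.uint8)
        self.nsites = 0
        self.cur_N = self.N_anc_scaled
        self.t: int | None = None

        self.focal_col = -1
        self.focal_mode = 0
        self.focal_s = 0.0
        self.f_eq = 0.5
        self.focal_pos: int | None = None

        self._py_rng = np.random.default_rng(self.seed ^ 0x5DEECE66)
        _seed_rng(self.seed)

    # -- demography helpers -------------------------------------------------

    def _size_at(self, t_scaled: float) -> int:
        current = self.scaled_epochs[0][0]
        for size, start in self.scaled_epochs:
            if t_scaled >= start:
                current = size
        return current

    # -- evolution ----------------------------------------------------------

    def _run(self, ngen: int) -> tuple[int, int]:
        """Run ngen generations at the current size; returns (status, gens_done)."""
        self.nsites, self.focal_col, status, gens = _evolve(
            self.geno, self.buf, self.pos, self.scoef, self.occ, self.nsites,
            self.cur_N, ngen, self.prune_every,
            self.mut_cum, self.rec_cum, self.block, self.L, self.site_class,
            self.dfe_cum, self.dfe_lo, self.dfe_hi, self.two_n_ref,
            self.Q, self.dfe.dominance,
            self.focal_col, self.focal_mode, self.focal_s, self.f_eq,
            self.capacity,
        )
        if status == 3:
            raise RuntimeError("segregating-site capacity exceeded; raise `capacity`")
        return status, gens

    def burn_in(self, span_factor: float = 10.0) -> None:
        """Equilibrate at the ancestral size for span_factor * N_anc generations."""
        ngen = max(1, round(span_factor * self.demography.ancestral_size / self.Q))
        self.cur_N = self.N_anc_scaled
        status, _ = self._run(ngen)
        if status != 0:
            raise RuntimeError("focal allele active during burn-in")

    def set_clock(self, total_span_gens: int) -> None:
        self.t = int(total_span_gens)

    def advance_to(self, t_target: int) -> int:
        """Advance the clock down to t_target scaled generations before sampling.

        Applies population-size changes at (scaled) epoch boundaries.  Returns
        a focal status: 0 ok, 1 focal lost, 2 balanced focal fixed.  On a
        non-zero status the clock reflects the generations actually run.
        """
        if self.t is None:
            raise RuntimeError("call set_clock() after burn_in() first")
        while self.t > t_target:
            child_size = self._size_at(self.t - 1)
            if child_size != self.cur_N:
                self.nsites, self.focal_col, status = _resize_step(
                    self.geno, self.buf, self.pos, self.scoef, self.occ, self.nsites,
                    self.cur_N, child_size,
                    self.mut_cum, self.rec_cum, self.block, self.L,
                    self.site_class, self.dfe_cum, self.dfe_lo, self.dfe_hi,
                    self.two_n_ref, self.Q, self.dfe.dominance,
                    self.focal_col, self.focal_mode, self.focal_s, self.f_eq,
                    self.capacity,
                )
                self.cur_N = child_size
                self.t -= 1
                if status == 3:
                    raise RuntimeError("segregating-site capacity exceeded")
                if status != 0:
                    return status
                continue
            stop = t_target
            for _, start in self.scaled_epochs:
                if t_target < start < self.t:
                    stop = max(stop, start)
            status, gens = self._run(self.t - stop)
            self.t -= gens
            if status != 0:
                return status
        return 0

    # -- focal allele -------------------------------------------------------

    def introduce(
        self,
        position: int,
        mode: Literal["sweep", "balancing"],
        *,
        s: float | None = None,
        f_eq: float | None = None,
    ) -> None:
        """Add the selected mutation on one random haplotype at ``position``.

        ``s`` is the unscaled beneficial coefficient for sweeps (multiplied by
        Q internally); ``f_eq`` the equilibrium frequency for balancing.
        """
        if not 1 <= position <= self.L:
            raise ValueError(f"selected position {position} outside [1, {self.L}]")
        if self.focal_col >= 0:
            raise RuntimeError("a focal mutation is already segregating")
        if self.nsites >= self.capacity:
            raise RuntimeError("no capacity for the focal mutation")
        two_n = 2 * self.cur_N
        if self.occ[position - 1]:
            # infinite-sites bookkeeping: displace the standing variant at
            # this position (column order is immaterial)
            j = int(np.nonzero(self.pos[: self.nsites] == position)[0][0])
            last = self.nsites - 1
            self.geno[:two_n, j] = self.geno[:two_n, last]
            self.pos[j] = self.pos[last]
            self.scoef[j] = self.scoef[last]
            self.nsites = last
        col = self.nsites
        self.occ[position - 1] = 1
        self.geno[:two_n, col] = 0
        row = int(self._py_rng.integers(two_n))
        self.geno[row, col] = 1
        self.pos[col] = position
        self.scoef[col] = 0.0  # fitness handled through the focal path
        self.nsites += 1
        self.focal_col = col
        self.focal_pos = position
        if mode == "sweep":
            if s is None or s <= 0:
                raise ValueError("sweep introduction needs s > 0")
            self.focal_mode = 1
            self.focal_s = s * self.Q
        elif mode == "balancing":
            if f_eq is None:
                raise ValueError("balancing introduction needs f_eq")
            self.focal_mode = 2
            self.f_eq = f_eq
        else:
            raise ValueError(f"unknown mode {mode!r}")

    def clear_focal(self) -> None:
        self.focal_col = -1
        self.focal_mode = 0
        self.focal_s = 0.0
        self.focal_pos = None

    @property
    def focal_fixed(self) -> bool:
        return self.focal_col == -2

    def focal_frequency(self) -> float | None:
        if self.focal_col < 0:
            return None
        two_n = 2 * self.cur_N
        return float(self.geno[:two_n, self.focal_col].sum()) / two_n

    # -- snapshot / restore -------------------------------------------------

    def snapshot(self) -> dict:
        two_n = 2 * self.cur_N
        return {
            "geno": self.geno[:two_n, : self.nsites].copy(),
            "occ": self.occ.copy(),
            "pos": self.pos[: self.nsites].copy(),
            "scoef": self.scoef[: self.nsites].copy(),
            "nsites": self.nsites,
            "cur_N": self.cur_N,
            "t": self.t,
            "focal": (self.focal_col, self.focal_mode, self.focal_s,
                      self.f_eq, self.focal_pos),
        }

    def restore(self, state: dict) -> None:
        n = state["nsites"]
        two_n = 2 * state["cur_N"]
        self.geno[:two_n, :n] = state["geno"]
        self.occ[:] = state["occ"]
        self.pos[:n] = state["pos"]
        self.scoef[:n] = state["scoef"]
        self.nsites = n
        self.cur_N = state["cur_N"]
        self.t = state["t"]
        (self.focal_col, self.focal_mode, self.focal_s,
         self.f_eq, self.focal_pos) = state["focal"]

    # -- output -------------------------------------------------------------

    def sample(
        self, n_chrom: int = 10
    ) -> tuple[list[AlleleFrequencyRecord], np.ndarray, np.ndarray]:
        """Sample n_chrom/2 diploids; fold; polymorphic-in-sample sites only.

        Returns (records, haplotype matrix (n_chrom, S), positions (S,)).
        """
        if n_chrom % 2 or n_chrom < 2:
            raise ValueError("n_chrom must be an even integer >= 2")
        if n_chrom > 2 * self.cur_N:
            raise ValueError("sample larger than the population")
        dips = self._py_rng.choice(self.cur_N, size=n_chrom // 2, replace=False)
        rows = np.column_stack([2 * dips, 2 * dips + 1]).ravel()
        haps = self.geno[rows, : self.nsites].astype(np.int8)
        counts = haps.sum(axis=0)
        keep = (counts > 0) & (counts < n_chrom)
        haps = haps[:, keep]
        positions = self.pos[: self.nsites][keep]
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        haps = haps[:, order]
        records = [
            AlleleFrequencyRecord(int(p), fold(int(c), n_chrom), n_chrom)
            for p, c in zip(positions, haps.sum(axis=0))
        ]
        return records, haps, positions


def run_forward(
    model: PiecewiseDemography,
    arch: GenomeArchitecture,
    dfe: DFEConfig,
    scenario: SelectionScenario,
    *,
    mu_rates: np.ndarray | None = None,
    rec_rates: np.ndarray | None = None,
    Q: float = 100.0,
    seed: int,
    n_chrom: int = 10,
    restart_cap: int = 1000,
    burn_in_factor: float = 10.0,
) -> SimulationResult:
    """Run one forward replicate end to end and sample it.

    Sweep replicates are retained only once the beneficial mutation has fixed
    by the sampling time; balancing replicates only while the balanced allele
    still segregates.  Failed attempts restart from the introduction-time
    state, up to ``restart_cap`` restarts.
    """
    sim = ForwardSimulator(
        model, arch, dfe, mu_rates=mu_rates, rec_rates=rec_rates, Q=Q, seed=seed
    )
    N_anc = model.ancestral_size
    sim.burn_in(burn_in_factor)
    total = max(1, round(scenario.span_N * N_anc / Q))
    sim.set_clock(total)

    selected_pos = scenario.selected_pos
    if scenario.mode != "neutral" and selected_pos is None:
        selected_pos = arch.default_selected_position()

    n_restarts = 0
    if scenario.mode == "neutral":
        sim.advance_to(0)
        final_state, final_freq = None, None
    else:
        t_intro = min(total, max(1, round(scenario.tau * N_anc / Q)))
        status = sim.advance_to(t_intro)
        assert status == 0
        snap = sim.snapshot()
        while True:
            if scenario.mode == "sweep":
                sim.introduce(
                    selected_pos, "sweep", s=scenario.s2N / (2.0 * N_anc)
                )
            else:
                sim.introduce(selected_pos, "balancing", f_eq=scenario.f_eq)
            status = sim.advance_to(0)
            if scenario.mode == "sweep":
                ok = status == 0 and sim.focal_fixed
            else:
                ok = status == 0
            if ok:
                break
            n_restarts += 1
            if n_restarts > restart_cap:
                raise RestartLimitError(
                    f"scenario {scenario} exceeded {restart_cap} restarts"
                )
            sim.restore(snap)
        final_freq = sim.focal_frequency()
        final_state = "fixed" if scenario.mode == "sweep" else "segregating"

    records, haps, _ = sim.sample(n_chrom)
    return SimulationResult(
        records=tuple(records),
        haplotypes=haps,
        scenario=scenario,
        selected_pos=selected_pos,
        final_state=final_state,
        final_freq=final_freq,
        n_restarts=n_restarts,
        seed=seed,
        Q=Q,
    )
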