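"""Power analysis: scenario grids of forward simulations scored into ROC curves.

Each selection scenario is simulated for ``n_reps`` replicates alongside
matched neutral comparators (same demography, architecture, DFE and rate
maps, no introduced mutation).  Every replicate is scanned with the relevant
CLR statistic and reduced to a single detection score — the region-wide
maximum windowed CLR ("was anything detected in this region").  Sweeping a
threshold over the pooled scores yields the ROC.

To share compute and match comparators exactly, each replicate runs one
neutral "backbone" through burn-in and the full post-burn-in span, with
snapshots taken at each introduction time tau; selection branches restart
from their snapshot on loss / non-fixation / balanced-allele fixation, per
the retention rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .balance_clr import scan_balancing
from .demography import PiecewiseDemography
from .forward_sim import (
    MU_BOUNDS,
    MU_FIXED,
    REC_BOUNDS,
    REC_FIXED,
    DFEConfig,
    ForwardSimulator,
    GenomeArchitecture,
    RestartLimitError,
    SelectionScenario,
    assign_rate_map,
    build_architecture,
)
from .sfs_stats import background_spectrum
from .sweep_clr import ScanRecord, SweepScanTable, scan_sweep

__all__ = [
    "ROCCurve",
    "replicate_score",
    "roc_curve",
    "power_at_fpr",
    "sweep_power_study",
    "balancing_power_study",
    "power_grid",
]


@dataclass(frozen=True)
class ROCCurve:
    """(FPR, TPR) points from sweeping a detection threshold, plus metadata."""

    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    label: str = ""

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("ROC points must be non-decreasing")
        if not (fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1):
            raise ValueError("ROC must run from (0,0) to (1,1)")

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def replicate_score(
    scan: list[ScanRecord], window_bp: int | None = None
) -> float:
    """Detection score of one replicate: max CLR after window aggregation.

    Per-SNP CLRs are aggregated to fixed-bp windows (100 bp / 1 kb / 10 kb)
    by maximum when ``window_bp`` is given; for SNP-count-window scans the
    records are already windows.  The replicate score is the maximum windowed
    CLR, which is invariant to refining the window subdivision.
    """
    if not scan:
        raise ValueError("cannot score an empty scan")
    clrs = np.array([r.clr for r in scan])
    if window_bp is not None:
        positions = np.array([r.position for r in scan])
        bins = (positions // window_bp).astype(np.int64)
        clrs = np.array([clrs[bins == b].max() for b in np.unique(bins)])
    return float(clrs.max())


def roc_curve(
    selection_scores: np.ndarray, neutral_scores: np.ndarray, label: str = ""
) -> ROCCurve:
    """ROC from replicate scores: TPR/FPR = fraction of scores >= threshold."""
    sel = np.asarray(selection_scores, dtype=float)
    neut = np.asarray(neutral_scores, dtype=float)
    if sel.size == 0 or neut.size == 0:
        raise ValueError("both score sets must be non-empty")
    thresholds = np.unique(np.concatenate([sel, neut]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for th in thresholds:
        fpr.append(float((neut >= th).mean()))
        tpr.append(float((sel >= th).mean()))
    fpr.append(1.0)
    tpr.append(1.0)
    return ROCCurve(np.maximum.accumulate(fpr), np.maximum.accumulate(tpr), label)


def power_at_fpr(curve: ROCCurve, fpr: float = 0.05) -> float:
    """TPR at the largest threshold whose FPR does not exceed ``fpr``."""
    mask = curve.fpr <= fpr
    return float(curve.tpr[mask].max()) if mask.any() else 0.0


# ---------------------------------------------------------------------------
# Scenario batches (shared neutral backbone per replicate)
# ---------------------------------------------------------------------------


def _make_rate_maps(L: int, rng: np.random.Generator, heterogeneous: bool):
    if not heterogeneous:
        return None, None
    n_kw = dict(mode="mean_matched", rng=rng)
    mu = assign_rate_map(L, target_mean=MU_FIXED, lo=MU_BOUNDS[0], hi=MU_BOUNDS[1], **n_kw)
    rec = assign_rate_map(
        L, target_mean=REC_FIXED, lo=REC_BOUNDS[0], hi=REC_BOUNDS[1], **n_kw
    )
    return mu, rec


def _complete_branch(
    sim: ForwardSimulator,
    snap: dict,
    mode: str,
    selected_pos: int,
    *,
    s: float | None = None,
    f_eq: float | None = None,
    restart_cap: int = 300,
) -> int:
    """Introduce the selected mutation and run to sampling, restarting on failure."""
    restarts = 0
    while True:
        if mode == "sweep":
            sim.introduce(selected_pos, "sweep", s=s)
        else:
            sim.introduce(selected_pos, "balancing", f_eq=f_eq)
        status = sim.advance_to(0)
        ok = (status == 0 and sim.focal_fixed) if mode == "sweep" else status == 0
        if ok:
            return restarts
        restarts += 1
        if restarts > restart_cap:
            raise RestartLimitError(f"{mode} branch exceeded {restart_cap} restarts")
        sim.restore(snap)


def _simulate_batch(
    mode: str,
    taus: list[float],
    n_reps: int,
    *,
    s2N: float | None = None,
    f_eq: float = 0.5,
    Q: float = 100.0,
    seed: int = 0,
    model: PiecewiseDemography | None = None,
    arch: GenomeArchitecture | None = None,
    dfe: DFEConfig | None = None,
    heterogeneous_rates: bool = True,
    restart_cap: int = 300,
    n_chrom: int = 10,
):
    """Neutral + per-tau selection samples for n_reps replicates.

    Returns (neutral_reps, {tau: reps or None}) where each rep is a record
    list; a tau maps to None if any replicate exceeded the restart cap
    (infeasible scenario, mirrored as an absent ROC panel).
    """
    model = model or PiecewiseDemography.default_aye_aye()
    arch = arch or build_architecture()
    dfe = dfe or DFEConfig()
    N_anc = model.ancestral_size
    selected_pos = arch.default_selected_position()
    s = None if s2N is None else s2N / (2.0 * N_anc)
    neutral_span = max(1, round(10.0 * N_anc / Q))

    # The demography is constant (ancestral) between burn-in and the recent
    # declines near sampling, so the neutral stretch between burn-in and the
    # introduction time is statistically redundant: all branches (and the
    # matched neutral comparator) start from one post-burn-in snapshot and
    # run only the span that actually shapes the sample.
    neutral: list[list] = []
    selected: dict[float, list | None] = {tau: [] for tau in taus}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep, 17])
        mu_rates, rec_rates = _make_rate_maps(arch.length, rng, heterogeneous_rates)
        sim = ForwardSimulator(
            model, arch, dfe, mu_rates=mu_rates, rec_rates=rec_rates, Q=Q,
            seed=int(rng.integers(2**31 - 1)),
        )
        sim.burn_in()
        base = sim.snapshot()
        sim.set_clock(neutral_span)
        sim.advance_to(0)
        neutral.append(sim.sample(n_chrom)[0])
        for tau in sorted(taus, reverse=True):
            if selected[tau] is None:
                continue
            sim.restore(base)
            sim.set_clock(max(1, round(tau * N_anc / Q)))
            snap = sim.snapshot()
            try:
                _complete_branch(
                    sim, snap, mode, selected_pos,
                    s=s, f_eq=f_eq, restart_cap=restart_cap,
                )
            except RestartLimitError:
                selected[tau] = None
                continue
            selected[tau].append(sim.sample(n_chrom)[0])
    return neutral, selected


def sweep_power_study(
    taus: list[float],
    s2N: float,
    n_reps: int = 50,
    *,
    Q: float = 100.0,
    seed: int = 0,
    window_bp: int = 1000,
    **kwargs,
) -> dict[float, ROCCurve | None]:
    """ROC per tau for a sweep of strength 2Ns, per-SNP scan, windowed scoring."""
    neutral, selected = _simulate_batch(
        "sweep", taus, n_reps, s2N=s2N, Q=Q, seed=seed, **kwargs
    )
    pooled = [r for rep in neutral for r in rep]
    G = background_spectrum(pooled)
    table = SweepScanTable(G)

    def score(rep):
        if not rep:
            return 0.0
        return replicate_score(scan_sweep(rep, G, table=table), window_bp)

    neutral_scores = np.array([score(rep) for rep in neutral])
    out: dict[float, ROCCurve | None] = {}
    for tau, reps in selected.items():
        if reps is None:
            out[tau] = None
            continue
        sel_scores = np.array([score(rep) for rep in reps])
        out[tau] = roc_curve(sel_scores, neutral_scores, f"sweep 2Ns={s2N} tau={tau}")
    return out


def balancing_power_study(
    taus: list[float],
    n_reps: int = 50,
    *,
    f_eq: float = 0.5,
    Q: float = 100.0,
    seed: int = 0,
    W: int = 10,
    S: int = 5,
    **kwargs,
) -> dict[float, ROCCurve | None]:
    """ROC per tau for balancing selection, SNP-count-window scan."""
    neutral, selected = _simulate_batch(
        "balancing", taus, n_reps, f_eq=f_eq, Q=Q, seed=seed, **kwargs
    )
    pooled = [r for rep in neutral for r in rep]
    G = background_spectrum(pooled)

    def score(rep):
        if len(rep) < W:
            return 0.0
        return replicate_score(scan_balancing(rep, W, S, G))

    neutral_scores = np.array([score(rep) for rep in neutral])
    out: dict[float, ROCCurve | None] = {}
    for tau, reps in selected.items():
        if reps is None:
            out[tau] = None
            continue
        sel_scores = np.array([score(rep) for rep in reps])
        out[tau] = roc_curve(sel_scores, neutral_scores, f"balancing tau={tau}N")
    return out


def power_grid(
    scenarios: list[SelectionScenario],
    n_reps: int,
    *,
    Q: float = 100.0,
    seed: int = 0,
    sweep_windows_bp: tuple[int, ...] = (100, 1000, 10000),
    **kwargs,
) -> dict[tuple, ROCCurve | None]:
    """ROC curves for a grid of scenarios, keyed by (mode, strength, tau, scheme).

    Sweep scenarios produce one curve per fixed-bp window scheme; because a
    replicate is scored by its region-wide maximum, the curve is identical
    across window refinements, so each scenario batch is simulated once and
    its curve reported under every scheme.  Balancing scenarios use the
    SNP-window scheme (10/5 SNPs).  Infeasible scenarios (restart cap
    exceeded) map to None.
    """
    out: dict[tuple, ROCCurve | None] = {}
    sweep_by_s: dict[float, list[float]] = {}
    bal_taus: list[float] = []
    for sc in scenarios:
        if sc.mode == "sweep":
            sweep_by_s.setdefault(sc.s2N, []).append(sc.tau)
        elif sc.mode == "balancing":
            bal_taus.append(sc.tau)
    for i, (s2N, taus) in enumerate(sorted(sweep_by_s.items())):
        curves = sweep_power_study(
            taus, s2N, n_reps, Q=Q, seed=seed + i,
            window_bp=sweep_windows_bp[0], **kwargs,
        )
        for tau, curve in curves.items():
            for w in sweep_windows_bp:
                out[("sweep", s2N, tau, f"{w}bp")] = curve
    if bal_taus:
        curves = balancing_power_study(
            sorted(set(bal_taus)), n_reps, Q=Q, seed=seed + 101, **kwargs
        )
        for tau, curve in curves.items():
            out[("balancing", 0.5, tau, "10snp")] = curve
    return out
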