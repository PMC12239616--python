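"""Simulation-calibrated null thresholds, candidate calling, and annotation.

The conservative threshold for each scan scheme is the single highest CLR
observed anywhere across all neutral baseline replicates — the largest value
the baseline model (demography, rate heterogeneity, purifying/background
selection) can produce without episodic selection.  Empirical values strictly
greater than it are candidates.  The conventional 5%-tail outlier comparator
is provided for contrast: on a neutral genome it flags ~5% of positions by
construction, while the calibrated threshold flags none of its training data.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GeneInterval, SVInterval
from .sweep_clr import ScanRecord

__all__ = [
    "null_threshold",
    "null_thresholds",
    "call_candidates",
    "overlap_genes",
    "overlap_svs",
    "empirical_tail_quantile",
]


def null_threshold(replicate_clrs: Iterable[np.ndarray | Sequence[float]]) -> float:
    """Maximum CLR across all neutral replicates (one scan scheme)."""
    best = -np.inf
    seen = False
    for clrs in replicate_clrs:
        arr = np.asarray(clrs, dtype=float)
        if arr.size:
            seen = True
            best = max(best, float(arr.max()))
    if not seen:
        raise ValueError("no CLR values supplied for threshold calibration")
    return best


def null_thresholds(
    replicate_scans: Mapping[str, Iterable[np.ndarray | Sequence[float]]],
) -> dict[str, float]:
    """Per-scheme thresholds, pooled over all replicates and chromosomes."""
    if not replicate_scans:
        raise ValueError("no scan schemes supplied")
    return {scheme: null_threshold(scans) for scheme, scans in replicate_scans.items()}


def call_candidates(
    scan: Sequence[ScanRecord], threshold: float
) -> list[ScanRecord]:
    """Records with CLR strictly greater than the threshold, order preserved."""
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    return [rec for rec in scan if rec.clr > threshold]


def _candidate_span(rec: ScanRecord) -> tuple[int, int]:
    if rec.start is not None and rec.end is not None:
        return rec.start, rec.end
    p = int(rec.position)
    return p, p


def _overlap(
    candidates: Sequence[ScanRecord],
    intervals: Sequence[tuple[int, int, str]],
) -> dict[int, list[str]]:
    # closed intervals: store [start, end+1) in the tree
    tree = IntervalTree()
    for start, end, label in intervals:
        tree[start : end + 1] = label
    hits: dict[int, list[str]] = {}
    for i, rec in enumerate(candidates):
        s, e = _candidate_span(rec)
        found = sorted(iv.data for iv in tree[s : e + 1])
        if found:
            hits[i] = found
    return hits


def overlap_genes(
    candidates: Sequence[ScanRecord], genes: Sequence[GeneInterval]
) -> dict[int, list[str]]:
    """Candidate index -> gene IDs whose (closed) interval intersects it.

    Point candidates (per-SNP sweep scan) hit genes containing the position;
    window candidates hit genes intersecting the window span.
    """
    return _overlap(candidates, [(g.start, g.end, g.gene_id) for g in genes])


def overlap_svs(
    candidates: Sequence[ScanRecord], svs: Sequence[SVInterval]
) -> dict[int, list[str]]:
    """Candidate index -> structural-variant class labels intersecting it."""
    return _overlap(candidates, [(s.start, s.end, s.sv_class) for s in svs])


def empirical_tail_quantile(
    scan: Sequence[ScanRecord] | np.ndarray, q: float = 0.05
) -> tuple[float, int]:
    """Outlier comparator: the (1-q) empirical quantile and the count above it.

    The cutoff uses the linear-interpolation empirical quantile; the count is
    of values strictly above the cutoff.
    """
    if not 0 < q < 1:
        raise ValueError(f"tail fraction must be in (0, 1), got {q}")
    if len(scan) == 0:
        raise ValueError("empty scan")
    if isinstance(scan[0], ScanRecord):
        clrs = np.array([r.clr for r in scan], dtype=float)
    else:
        clrs = np.asarray(scan, dtype=float)
    cutoff = float(np.quantile(clrs, 1.0 - q))
    return cutoff, int((clrs > cutoff).sum())
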