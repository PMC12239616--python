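"""Independent brute-force oracles used to pin expected values.

These deliberately avoid the package's vectorized code paths: projection is
computed by exhaustive enumeration of subsamples, and the sweep-perturbed
spectrum by direct summation over every (escape set, ancestral configuration,
ancestor identity) outcome with probabilities from first principles.
"""

from itertools import combinations
from math import comb

import numpy as np


def project_by_enumeration(p: np.ndarray, j: int) -> np.ndarray:
    """Distribution of derived counts in subsamples of size j, by listing
    every subset of every concrete sample configuration."""
    p = np.asarray(p, dtype=float)
    n = len(p) - 1
    out = np.zeros(j + 1)
    for k in range(n + 1):
        if p[k] == 0:
            continue
        # concrete configuration: chromosomes 0..k-1 derived
        derived = set(range(k))
        total = 0
        counts = np.zeros(j + 1)
        for subset in combinations(range(n), j):
            a = sum(1 for c in subset if c in derived)
            counts[a] += 1
            total += 1
        out += p[k] * counts / total
    return out


def fold_vector(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded vector over 0..n to folded classes 1..n//2,
    conditioning on polymorphism."""
    unfolded = np.asarray(unfolded, dtype=float)
    n = len(unfolded) - 1
    folded = np.zeros(n // 2)
    for k in range(1, n):
        folded[min(k, n - k) - 1] += unfolded[k]
    return folded / folded.sum()


def symmetrize(folded: np.ndarray, n: int) -> np.ndarray:
    g = np.zeros(n + 1)
    for k1, mass in enumerate(folded, start=1):
        if 2 * k1 == n:
            g[k1] = mass
        else:
            g[k1] += mass / 2
            g[n - k1] += mass / 2
    return g


def sweep_spectrum_by_enumeration(
    folded: np.ndarray, n: int, p_e: float
) -> np.ndarray:
    """Sweep-perturbed folded spectrum by direct outcome enumeration.

    For every escape count e (binomial weight), every ancestral derived count
    a among the j = e + 1 pre-sweep lineages (projection by subset
    enumeration), and both identities of the sweeping ancestor (derived with
    probability a/j), accumulate the observed derived count and fold.
    """
    g = symmetrize(folded, n)
    acc = np.zeros(n + 1)
    for e in range(n + 1):
        w_e = comb(n, e) * p_e**e * (1 - p_e) ** (n - e)
        if w_e == 0:
            continue
        if e == n:
            acc += w_e * g
            continue
        j = e + 1
        Pj = project_by_enumeration(g, j)
        for a in range(j + 1):
            if Pj[a] == 0:
                continue
            if a > 0:  # sweeping ancestor carries the derived allele
                acc[(a - 1) + (n - e)] += w_e * Pj[a] * (a / j)
            if a < j:  # sweeping ancestor carries the ancestral allele
                acc[a] += w_e * Pj[a] * ((j - a) / j)
    return fold_vector(acc)


def auc_by_pairwise_comparison(sel: np.ndarray, neut: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (selection, neutral) pairs won, ties 1/2."""
    wins = 0.0
    for s in sel:
        for t in neut:
            if s > t:
                wins += 1.0
            elif s == t:
                wins += 0.5
    return wins / (len(sel) * len(neut))
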