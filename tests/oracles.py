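"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library's code paths (and, where feasible,
scipy's closed forms) so they can vouch for them.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_upper_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) by exact rational summation over the support."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values by the textbook step-up recursion."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


def gsea_running_sum_bruteforce(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> tuple[float, int]:
    """(ES, 0-based peak) by evaluating the running sum position by position."""
    n = len(scores)
    n_hits = int(hit_mask.sum())
    total = sum(abs(scores[i]) ** weight for i in range(n) if hit_mask[i])
    running = 0.0
    best, best_pos = 0.0, 0
    for i in range(n):
        if hit_mask[i]:
            running += (abs(scores[i]) ** weight) / total
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best, best_pos = running, i
    return best, best_pos


def pooled_t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided pooled-variance t test from first principles (scipy only for the CDF)."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return 2.0 * float(t_dist.sf(abs(t), na + nb - 2))


def welch_t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (b.mean() - a.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return 2.0 * float(t_dist.sf(abs(t), df))


def f_gate_is_student(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> bool:
    """Two-sided variance-ratio F test with larger variance on top."""
    from scipy.stats import f as f_dist

    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return True
    if va == 0.0 or vb == 0.0:
        return False
    if vb >= va:
        p = 2.0 * float(f_dist.sf(vb / va, len(b) - 1, len(a) - 1))
    else:
        p = 2.0 * float(f_dist.sf(va / vb, len(a) - 1, len(b) - 1))
    return min(p, 1.0) > alpha


def base_level_overlap(
    start_a: int, end_a: int, start_b: int, end_b: int
) -> bool:
    """>= 1 shared base between two half-open intervals, checked base by base."""
    bases_a = set(range(start_a, end_a))
    return any(pos in bases_a for pos in range(start_b, end_b))


def consistent_bases(peak_sets, chrom: str) -> set[int]:
    """Bases covered by at least one peak of EVERY set on one chromosome."""
    covered = []
    for peaks in peak_sets:
        bases = set()
        for _, p in peaks[peaks["chrom"] == chrom].iterrows():
            bases.update(range(int(p["start"]), int(p["end"])))
        covered.append(bases)
    return set.intersection(*covered) if covered else set()


IUPAC_ORACLE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def motif_offsets_bruteforce(seq: str, pattern: str, max_mm: int = 0) -> set[int]:
    """Forward-strand offsets by per-position symbol-class comparison."""
    seq = seq.upper()
    hits = set()
    for off in range(len(seq) - len(pattern) + 1):
        mm = sum(
            seq[off + j] not in IUPAC_ORACLE[sym] for j, sym in enumerate(pattern)
        )
        if mm <= max_mm:
            hits.add(off)
    return hits


def motif_offsets_both_strands(seq: str, pattern: str, max_mm: int = 0) -> set[int]:
    seq = seq.upper()
    rc_seq = "".join(_RC[b] for b in reversed(seq))
    fwd = motif_offsets_bruteforce(seq, pattern, max_mm)
    rev_on_rc = motif_offsets_bruteforce(rc_seq, pattern, max_mm)
    rev = {len(seq) - off - len(pattern) for off in rev_on_rc}
    return fwd | rev
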