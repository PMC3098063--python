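"""Independent brute-force oracles used to validate the implementation.

Everything here is written for clarity, not speed, and deliberately does
not share code with the package: plain-Python Gotoh dynamic programming
for alignment scores, a dense grid search for the ML distance, and a
cache-free re-derivation of the reciprocal smallest distance decision.
"""

from __future__ import annotations

import numpy as np

from rsdlite.evodist import ml_distance, transition_matrix
from rsdlite.pairwise import alignable_fraction, global_align, local_search
from rsdlite.seqio import AMINO_ACIDS

NEG = float("-inf")


def _score_fn(scheme):
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    def s(x: str, y: str) -> float:
        if x == "X" or y == "X":
            return 0.0
        return float(scheme.matrix[idx[x], idx[y]])

    return s


def gotoh_global_score(a: str, b: str, scheme) -> float:
    """Optimal global alignment score, affine gaps, end gaps penalized.

    A gap of length L costs gap_open + gap_extend * L.
    """
    s = _score_fn(scheme)
    opn = scheme.gap_open + scheme.gap_extend
    ext = scheme.gap_extend
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(scheme.gap_open + ext * i)
    for j in range(1, m + 1):
        Iy[0, j] = -(scheme.gap_open + ext * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = s(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + sub
            Ix[i, j] = max(M[i - 1, j] - opn, Ix[i - 1, j] - ext, Iy[i - 1, j] - opn)
            Iy[i, j] = max(M[i, j - 1] - opn, Iy[i, j - 1] - ext, Ix[i, j - 1] - opn)
    return max(M[n, m], Ix[n, m], Iy[n, m])


def gotoh_local_score(a: str, b: str, scheme) -> float:
    """Optimal Smith-Waterman local alignment score with affine gaps."""
    s = _score_fn(scheme)
    opn = scheme.gap_open + scheme.gap_extend
    ext = scheme.gap_extend
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = s(a[i - 1], b[j - 1])
            M[i, j] = max(
                0.0,
                max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + sub,
            )
            Ix[i, j] = max(M[i - 1, j] - opn, Ix[i - 1, j] - ext, Iy[i - 1, j] - opn)
            Iy[i, j] = max(M[i, j - 1] - opn, Iy[i, j - 1] - ext, Ix[i, j - 1] - opn)
            best = max(best, M[i, j])
    return best


def grid_search_distance(aln, model, t_max: float = 5.0, n_grid: int = 2000):
    """(t, step) maximizing the alignment likelihood on a dense grid."""
    from rsdlite.evodist import _pattern_counts  # reuse the column counting only

    counts = _pattern_counts(aln)
    grid = np.linspace(0.0, t_max, n_grid)
    best_t, best_ll = 0.0, NEG
    for t in grid:
        P = np.zeros((20, 20))
        for r in model.category_rates:
            P += transition_matrix(model, float(t), float(r))
        P /= model.K
        ll = float((counts * np.log(P + 1e-300)).sum())
        if ll > best_ll:
            best_t, best_ll = float(t), ll
    return best_t, grid[1] - grid[0], best_ll


def brute_force_rsd(I, J, setting, scheme, model):
    """The RSD decision recomputing every distance, no caching, no hit cap."""
    confirmed = []
    for qid in sorted(I.records):
        i = I[qid]
        fwd = {}
        for h in local_search(i, J, scheme, setting.evalue, max_hits=None):
            aln = global_align(i, J[h.subject_id], scheme)
            if alignable_fraction(aln) >= setting.divergence:
                fwd[h.subject_id] = ml_distance(aln, model).t_hat
        if not fwd:
            continue
        j_id = min(fwd, key=lambda s_: (fwd[s_], s_))
        rev = {}
        for h in local_search(J[j_id], I, scheme, setting.evalue, max_hits=None):
            aln = global_align(J[j_id], I[h.subject_id], scheme)
            if alignable_fraction(aln) >= setting.divergence:
                rev[h.subject_id] = ml_distance(aln, model).t_hat
        if qid in rev and rev[qid] <= min(rev.values()):
            confirmed.append((qid, j_id))
    return confirmed
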