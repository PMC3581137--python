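"""Independent reference implementations used only as test oracles.

These deliberately avoid the library's code paths: the EM oracle
maximises the multinomial genotype-table likelihood by dense grid
search over the phase proportion, and the imputation oracle evaluates
the haplotype-pair score symbol by symbol from raw counts.
"""

from __future__ import annotations

import itertools

import numpy as np


def freqs_given_x1(n: np.ndarray, x1: float) -> tuple[float, float, float, float]:
    """Haplotype probabilities implied by a fixed phase split x1."""
    two_n = 2.0 * n.sum()
    p_ab = (2 * n[0, 0] + n[0, 1] + n[1, 0] + x1 * n[1, 1]) / two_n
    p_aB = (2 * n[0, 2] + n[0, 1] + n[1, 2] + (1 - x1) * n[1, 1]) / two_n
    p_Ab = (2 * n[2, 0] + n[2, 1] + n[1, 0] + (1 - x1) * n[1, 1]) / two_n
    p_AB = (2 * n[2, 2] + n[2, 1] + n[1, 2] + x1 * n[1, 1]) / two_n
    return p_ab, p_aB, p_Ab, p_AB


def table_log_likelihood(n: np.ndarray, p: tuple[float, float, float, float]) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table under random
    union of haplotypes with probabilities p."""
    p_ab, p_aB, p_Ab, p_AB = p
    cell = np.array(
        [
            [p_ab**2, 2 * p_ab * p_aB, p_aB**2],
            [2 * p_ab * p_Ab, 2 * (p_ab * p_AB + p_aB * p_Ab), 2 * p_aB * p_AB],
            [p_Ab**2, 2 * p_Ab * p_AB, p_AB**2],
        ]
    )
    log_cell = np.where(n > 0, np.log(np.maximum(cell, 1e-300)), 0.0)
    return float((n * log_cell).sum())


def grid_search_freqs(
    n: np.ndarray, grid_points: int = 10001
) -> tuple[tuple[float, float, float, float], float]:
    """Maximum-likelihood haplotype probabilities by dense grid search
    over the phase proportion x1 in [0, 1]."""
    best_p, best_ll, best_x1 = None, -np.inf, 0.5
    for x1 in np.linspace(0.0, 1.0, grid_points):
        p = freqs_given_x1(n, x1)
        ll = table_log_likelihood(n, p)
        if ll > best_ll:
            best_ll, best_p, best_x1 = ll, p, x1
    return best_p, best_x1


_HAPS = tuple(itertools.product((0, 1), repeat=3))


def brute_force_entry(
    n_pq: np.ndarray,
    n_qr: np.ndarray,
    n_pr: np.ndarray,
    f_pq: np.ndarray,
    f_qr: np.ndarray,
    f_pr: np.ndarray,
    r2_pq: float,
    r2_qr: float,
    r2_pr: float,
    g_p: int,
    g_r: int,
    rel_tol: float = 1e-9,
):
    """Enumerate all 36 unordered haplotype pairs and score them from
    the printed formulas, independently of the library.

    f_xy are 2x2 arrays of pairwise haplotype probabilities indexed by
    allele. Returns (max score, set of Q genotypes attaining it within
    rel_tol, modal Q genotype fallback).
    """

    def weight(n: np.ndarray, g1: int, g2: int) -> float:
        big_n = float(n.sum())
        w = 1.0 - abs(
            n[g1, :].sum() * n[:, g2].sum() / (big_n * big_n) - n[g1, g2] / big_n
        )
        return max(w, 1e-5)

    def prob3(h) -> float:
        return (
            f_pq[h[0], h[1]] * r2_pq
            * f_qr[h[1], h[2]] * r2_qr
            * f_pr[h[0], h[2]] * r2_pr
        )

    results = []
    for i, h1 in enumerate(_HAPS):
        for h2 in _HAPS[i:]:
            if h1[0] + h2[0] != g_p or h1[2] + h2[2] != g_r:
                continue
            g_q = h1[1] + h2[1]
            denom = n_pq[g_p, :].sum() * n_pr[:, g_r].sum() * n_qr[g_q, :].sum()
            if denom == 0:
                score = 0.0
            else:
                numer = n_pq[g_p, g_q] * n_pr[g_p, g_r] * n_qr[g_q, g_r]
                score = (
                    (prob3(h1) + prob3(h2))
                    * (numer / denom)
                    * weight(n_pq, g_p, g_q)
                    * weight(n_pr, g_p, g_r)
                    * weight(n_qr, g_q, g_r)
                )
            results.append((score, g_q))

    max_score = max(s for s, _ in results)
    top_genotypes = {
        g for s, g in results if s >= max_score * (1.0 - rel_tol)
    } if max_score > 0 else set()
    modal_q = int(np.argmax(n_pq.sum(axis=0)))
    return max_score, top_genotypes, modal_q
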