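"""Reference-free imputation of missing genotypes from flanking loci.

Each missing genotype at locus Q is imputed from a triple (P, Q, R)
where P and R are the nearest loci at which the sample is observed (or
already filled), normally one on each side of Q. Using only the samples
complete at all three loci, the pairwise haplotype frequencies and r^2
are estimated for the three pairs; a three-locus haplotype probability
is approximated as the r^2-weighted product of the pairwise ones; and
every haplotype pair consistent with the observed genotypes at P and R
receives a score combining that probability with empirical genotype
co-occurrence counts and association weights. The Q genotype of the
best-scoring pair is the imputed value.

Runs of consecutive missing genotypes are filled inward from the end
nearest an observed locus, so freshly imputed entries serve as flanks
for their neighbours; when a run reaches a chromosome end, both flanks
are taken from the observed side. Triple statistics are cached per
(P, Q, R), which keeps the total work at O(mw + n) for m samples with
missing data, w loci with missing data and n missing entries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix
from .pairwise_stats import (
    HaplotypeFreqs,
    PairCounts,
    count_pair,
    em_haplotype_freqs,
    ld_stats,
)

__all__ = [
    "TripleContext",
    "CandidateScore",
    "ImputationReport",
    "UnimputableEntryError",
    "ContextUnavailableError",
    "select_flanks",
    "build_triple_context",
    "haplotype_prob3",
    "pair_weight",
    "score_pair",
    "impute_entry",
    "impute_all",
    "R2_FLOOR",
    "W_FLOOR",
]

#: Floor applied to r^2 weights inside a triple context.
R2_FLOOR: float = 1e-5
#: Floor applied to the genotype association weight W.
W_FLOOR: float = 1e-5

#: The 8 three-locus haplotypes (allele 0 = reference, 1 = alternate).
HAPLOTYPES: tuple[tuple[int, int, int], ...] = tuple(
    itertools.product((0, 1), repeat=3)
)
#: The 36 unordered haplotype pairs (with replacement).
HAPLOTYPE_PAIRS: tuple[tuple[tuple[int, int, int], tuple[int, int, int]], ...] = tuple(
    itertools.combinations_with_replacement(HAPLOTYPES, 2)
)


class UnimputableEntryError(ValueError):
    """The sample lacks the two available loci needed for flanks."""


class ContextUnavailableError(ValueError):
    """No sample is complete at all of P, Q and R."""


@dataclass(frozen=True)
class TripleContext:
    """Cached pairwise statistics for a (P, Q, R) locus triple.

    All three contingency tables are tallied over the same sample set:
    those with no missing data at any of P, Q and R. r^2 values are
    floored so a zero never annihilates the three-locus product.
    """

    p: int
    q: int
    r: int
    counts_PQ: PairCounts
    counts_QR: PairCounts
    counts_PR: PairCounts
    freqs_PQ: HaplotypeFreqs
    freqs_QR: HaplotypeFreqs
    freqs_PR: HaplotypeFreqs
    r2_PQ: float
    r2_QR: float
    r2_PR: float
    n_complete: int


@dataclass(frozen=True)
class CandidateScore:
    """Best haplotype pair for one missing entry."""

    genotype_at_Q: int
    hap1: tuple[int, int, int]
    hap2: tuple[int, int, int]
    score: float
    tie: bool = False
    fallback: bool = False  # modal fallback used (all legitimate scores 0)


@dataclass
class ImputationReport:
    """Summary of one imputation pass.

    n_missing_entries / n_loci_with_missing / n_samples_with_missing are
    the n, w and m of the O(mw + n) complexity bound. ``entries`` holds
    one record per missing entry: (sample_id, locus_id, imputed genotype
    or None if unimputable, score, tie_flag, fallback_flag).
    ``n_scored_pairs`` counts haplotype-pair score evaluations, the unit
    of per-entry work.
    """

    n_missing_entries: int = 0
    n_loci_with_missing: int = 0
    n_samples_with_missing: int = 0
    entries: list = field(default_factory=list)
    n_unimputable: int = 0
    n_scored_pairs: int = 0
    n_contexts_built: int = 0


def select_flanks(
    matrix: GenotypeMatrix,
    sample: int,
    locus_q: int,
    available: np.ndarray,
    max_distance: int | None = None,
) -> tuple[int, int, bool]:
    """Pick the flanking loci (P, R) for a missing entry.

    ``available[j]`` marks loci where this sample is observed or already
    filled. P and R are the nearest available loci left and right of Q;
    if one side has none, both are taken from the other side (nearest
    first) and the fallback flag is set. ``max_distance`` optionally
    bounds the search window in columns.
    """
    n_loci = matrix.n_loci
    lo = 0 if max_distance is None else max(0, locus_q - max_distance)
    hi = n_loci if max_distance is None else min(n_loci, locus_q + max_distance + 1)
    left = [j for j in range(locus_q - 1, lo - 1, -1) if available[j]]
    right = [j for j in range(locus_q + 1, hi) if available[j]]
    if left and right:
        return left[0], right[0], False
    side = left or right
    if len(side) >= 2:
        return side[0], side[1], True
    raise UnimputableEntryError(
        f"sample {matrix.sample_ids[sample]!r} has fewer than two available "
        f"loci to flank locus {matrix.locus_ids[locus_q]!r}"
    )


def build_triple_context(
    matrix: GenotypeMatrix,
    p: int,
    q: int,
    r: int,
    cache: dict | None = None,
    n_iterations: int = 10,
    r2_floor: float = R2_FLOOR,
) -> TripleContext:
    """Compute (or fetch from ``cache``) the statistics for (P, Q, R).

    Restricted to samples with no missing data at all three loci; the
    three haplotype-frequency fits use ``n_iterations`` EM cycles.
    """
    if len({p, q, r}) != 3:
        raise ValueError("P, Q, R must be distinct loci")
    key = (p, q, r)
    if cache is not None and key in cache:
        return cache[key]
    g = matrix.genotypes
    complete = (g[:, p] != MISSING) & (g[:, q] != MISSING) & (g[:, r] != MISSING)
    idx = np.flatnonzero(complete)
    if idx.size == 0:
        raise ContextUnavailableError(
            f"no sample is complete at loci {p}, {q}, {r}"
        )
    subset = set(idx.tolist())
    counts_pq = count_pair(matrix, p, q, subset)
    counts_qr = count_pair(matrix, q, r, subset)
    counts_pr = count_pair(matrix, p, r, subset)
    freqs_pq = em_haplotype_freqs(counts_pq, n_iterations)
    freqs_qr = em_haplotype_freqs(counts_qr, n_iterations)
    freqs_pr = em_haplotype_freqs(counts_pr, n_iterations)
    ctx = TripleContext(
        p=p,
        q=q,
        r=r,
        counts_PQ=counts_pq,
        counts_QR=counts_qr,
        counts_PR=counts_pr,
        freqs_PQ=freqs_pq,
        freqs_QR=freqs_qr,
        freqs_PR=freqs_pr,
        r2_PQ=max(ld_stats(freqs_pq).r2, r2_floor),
        r2_QR=max(ld_stats(freqs_qr).r2, r2_floor),
        r2_PR=max(ld_stats(freqs_pr).r2, r2_floor),
        n_complete=int(idx.size),
    )
    if cache is not None:
        cache[key] = ctx
    return ctx


def haplotype_prob3(ctx: TripleContext, h1: int, h2: int, h3: int) -> float:
    """r^2-weighted product approximation to the three-locus haplotype
    probability: P_PQ(h1 h2) r2_PQ * P_QR(h2 h3) r2_QR * P_PR(h1 h3) r2_PR.

    A score, not a normalised probability.
    """
    return (
        ctx.freqs_PQ.prob(h1, h2)
        * ctx.r2_PQ
        * ctx.freqs_QR.prob(h2, h3)
        * ctx.r2_QR
        * ctx.freqs_PR.prob(h1, h3)
        * ctx.r2_PR
    )


def pair_weight(counts: PairCounts, g1: int, g2: int, floor: float = W_FLOOR) -> float:
    """Association weight of the genotype pair (g1, g2) in one table:
    W = 1 - | rowmargin*colmargin/N^2 - n[g1,g2]/N |, floored.
    """
    if counts.total < 1:
        raise ValueError("pair weight undefined on an empty table")
    n = float(counts.total)
    expected = counts.row_margins[g1] * counts.col_margins[g2] / (n * n)
    observed = counts.n[g1, g2] / n
    return max(1.0 - abs(expected - observed), floor)


def score_pair(
    ctx: TripleContext,
    hap1: tuple[int, int, int],
    hap2: tuple[int, int, int],
    w_floor: float = W_FLOOR,
) -> float:
    """Score one unordered haplotype pair against the triple context.

    With gP, gQ, gR the unordered genotypes the pair forms at P, Q, R::

        score = (P3(hap1) + P3(hap2))
                * nPQ(gP,gQ) nPR(gP,gR) nQR(gQ,gR)
                  / (NPQ(gP,.) NPR(.,gR) NQR(gQ,.))
                * W_PQ(gP,gQ) W_PR(gP,gR) W_QR(gQ,gR)

    A zero margin in the denominator yields score 0.
    """
    g_p = hap1[0] + hap2[0]
    g_q = hap1[1] + hap2[1]
    g_r = hap1[2] + hap2[2]
    denom = (
        ctx.counts_PQ.row_margins[g_p]
        * ctx.counts_PR.col_margins[g_r]
        * ctx.counts_QR.row_margins[g_q]
    )
    if denom == 0:
        return 0.0
    numer = (
        ctx.counts_PQ.n[g_p, g_q]
        * ctx.counts_PR.n[g_p, g_r]
        * ctx.counts_QR.n[g_q, g_r]
    )
    if numer == 0:
        return 0.0
    prob = haplotype_prob3(ctx, *hap1) + haplotype_prob3(ctx, *hap2)
    weights = (
        pair_weight(ctx.counts_PQ, g_p, g_q, w_floor)
        * pair_weight(ctx.counts_PR, g_p, g_r, w_floor)
        * pair_weight(ctx.counts_QR, g_q, g_r, w_floor)
    )
    return prob * (numer / denom) * weights


def _modal_q_genotype(ctx: TripleContext) -> int:
    """Most frequent Q genotype among complete samples (ties -> smaller)."""
    margins = ctx.counts_PQ.col_margins
    return int(np.argmax(margins))  # argmax takes the first (smallest) on ties


def impute_entry(
    ctx: TripleContext,
    g_p: int,
    g_r: int,
    w_floor: float = W_FLOOR,
    counter: list | None = None,
) -> CandidateScore:
    """Choose the best haplotype pair consistent with the observed
    flanking genotypes and return its Q genotype.

    Legitimate pairs are the unordered pairs of three-locus haplotypes
    whose implied genotype equals g_p at P and g_r at R; the Q genotype
    is free, so candidates span all three values. Ties on the maximal
    score go to the Q genotype with the largest margin in the P-Q
    table, then to the smaller genotype. If every legitimate pair
    scores 0, the modal Q genotype among complete samples is used.
    """
    if g_p not in (0, 1, 2) or g_r not in (0, 1, 2):
        raise ValueError("flanking genotypes must be 0, 1 or 2")
    scored: list[tuple[float, tuple, tuple]] = []
    for hap1, hap2 in HAPLOTYPE_PAIRS:
        if hap1[0] + hap2[0] != g_p or hap1[2] + hap2[2] != g_r:
            continue
        scored.append((score_pair(ctx, hap1, hap2, w_floor), hap1, hap2))
    if counter is not None:
        counter[0] += len(scored)
    if not scored:
        raise AssertionError("no legitimate haplotype pair — unreachable")
    best = max(s for s, _, _ in scored)
    if best == 0.0:
        g_q = _modal_q_genotype(ctx)
        hap1, hap2 = next(
            (h1, h2) for s, h1, h2 in scored if h1[1] + h2[1] == g_q
        )
        return CandidateScore(
            genotype_at_Q=g_q, hap1=hap1, hap2=hap2, score=0.0, fallback=True
        )
    top = [(h1, h2) for s, h1, h2 in scored if s == best]
    margins = ctx.counts_PQ.col_margins
    top.sort(key=lambda pair: (-margins[pair[0][1] + pair[1][1]], pair[0][1] + pair[1][1]))
    hap1, hap2 = top[0]
    tie = len({h1[1] + h2[1] for h1, h2 in top}) > 1
    return CandidateScore(
        genotype_at_Q=hap1[1] + hap2[1], hap1=hap1, hap2=hap2, score=best, tie=tie
    )


def _runs(missing_cols: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [start, stop] of consecutive missing columns."""
    runs = []
    start = None
    prev = None
    for j in missing_cols:
        if start is None:
            start = prev = j
        elif j == prev + 1:
            prev = j
        else:
            runs.append((start, prev))
            start = prev = j
    if start is not None:
        runs.append((start, prev))
    return runs


def impute_all(
    matrix: GenotypeMatrix,
    n_iterations: int = 10,
    r2_floor: float = R2_FLOOR,
    w_floor: float = W_FLOOR,
    max_flank_distance: int | None = None,
) -> tuple[GenotypeMatrix, ImputationReport]:
    """Impute every missing entry of ``matrix``.

    Entries are processed per sample; within a sample, runs of
    consecutive missing loci are filled from the end nearest an
    observed locus inward (left-to-right when both ends border observed
    loci), so that previously imputed genotypes serve as flanks for the
    rest of the run. Triple contexts are computed from the originally
    observed genotypes only — imputed values never feed back into the
    counting population — and are cached per (P, Q, R).

    Observed genotypes are never modified; unimputable entries stay
    MISSING and are listed in the report.
    """
    if matrix.n_loci < 3:
        raise ValueError("at least 3 loci required for imputation")
    missing = matrix.missing_mask()
    out = matrix.copy()
    report = ImputationReport(
        n_missing_entries=int(missing.sum()),
        n_loci_with_missing=int(missing.any(axis=0).sum()),
        n_samples_with_missing=int(missing.any(axis=1).sum()),
    )
    cache: dict = {}
    counter = [0]
    for s in np.flatnonzero(missing.any(axis=1)):
        available = ~missing[s]
        for start, stop in _runs(np.flatnonzero(missing[s])):
            has_left = available[:start].any()
            has_right = available[stop + 1 :].any()
            if has_left or not has_right:
                order = range(start, stop + 1)  # left-to-right (incl. right-edge runs)
            else:
                order = range(stop, start - 1, -1)  # left-edge run: fill inward
            for q in order:
                try:
                    p, r, fb = select_flanks(
                        matrix, int(s), q, available, max_flank_distance
                    )
                    n_cached = len(cache)
                    ctx = build_triple_context(
                        matrix, p, q, r, cache, n_iterations, r2_floor
                    )
                    report.n_contexts_built += len(cache) - n_cached
                    cand = impute_entry(
                        ctx,
                        int(out.genotypes[s, p]),
                        int(out.genotypes[s, r]),
                        w_floor,
                        counter,
                    )
                except (UnimputableEntryError, ContextUnavailableError):
                    report.n_unimputable += 1
                    report.entries.append(
                        (matrix.sample_ids[s], matrix.locus_ids[q], None, 0.0, False, False)
                    )
                    continue
                out.genotypes[s, q] = cand.genotype_at_Q
                available[q] = True
                report.entries.append(
                    (
                        matrix.sample_ids[s],
                        matrix.locus_ids[q],
                        cand.genotype_at_Q,
                        cand.score,
                        cand.tie,
                        fb or cand.fallback,
                    )
                )
    report.n_scored_pairs = counter[0]
    return out, report
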