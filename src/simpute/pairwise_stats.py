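"""Two-locus genotype counts, EM haplotype frequencies, and LD statistics.

For a pair of biallelic loci, write the alleles at the first locus a/A
and at the second b/B, with a and b the reference alleles. A diploid
sample contributes a cell N_{i,j} to a 3x3 contingency table, where i
and j are the genotype codes (alternate-allele counts) at the two loci.
Every cell except the double heterozygote N_{1,1} resolves into
haplotypes unambiguously; N_{1,1} is a mixture of the phases ab/AB
(proportion X1) and aB/Ab (proportion X2 = 1 - X1). The EM iteration
alternates the frequency equations (haplotype probabilities given X1,
X2) with the phase update (X1, X2 given the probabilities).

From the four haplotype probabilities the classical pairwise LD
measures follow: D = p(ab) - p(a.)p(.b), the normalised D' = D/D_max,
and the squared allelic correlation r^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "PairCounts",
    "HaplotypeFreqs",
    "LDStats",
    "count_pair",
    "em_haplotype_freqs",
    "ld_stats",
]


class UndefinedStatisticsError(ValueError):
    """Raised when a statistic is requested from an empty table."""


@dataclass(frozen=True)
class PairCounts:
    """3x3 genotype contingency table for two loci with margins.

    ``n[i, j]`` counts samples with genotype i at the first locus and j
    at the second; margins and the grand total are precomputed.
    """

    n: np.ndarray
    row_margins: np.ndarray
    col_margins: np.ndarray
    total: int

    @classmethod
    def from_table(cls, n) -> "PairCounts":
        n = np.asarray(n, dtype=np.int64)
        if n.shape != (3, 3) or (n < 0).any():
            raise ValueError("pair counts must be a nonnegative 3x3 table")
        return cls(
            n=n,
            row_margins=n.sum(axis=1),
            col_margins=n.sum(axis=0),
            total=int(n.sum()),
        )


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-locus haplotype probabilities and the phase proportions.

    p_ab/p_aB/p_Ab/p_AB are the four haplotype probabilities; x1 is the
    estimated proportion of phase ab/AB among double heterozygotes and
    x2 = 1 - x1 the proportion of aB/Ab.
    """

    p_ab: float
    p_aB: float
    p_Ab: float
    p_AB: float
    x1: float = 0.5
    x2: float = 0.5

    def __post_init__(self) -> None:
        total = self.p_ab + self.p_aB + self.p_Ab + self.p_AB
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype probabilities sum to {total}, not 1")
        if abs(self.x1 + self.x2 - 1.0) > 1e-9:
            raise ValueError("phase proportions must sum to 1")

    # single-locus allele frequencies (margins of the 2x2 haplotype table)
    @property
    def p_a_dot(self) -> float:
        return self.p_ab + self.p_aB

    @property
    def p_A_dot(self) -> float:
        return self.p_Ab + self.p_AB

    @property
    def p_dot_b(self) -> float:
        return self.p_ab + self.p_Ab

    @property
    def p_dot_B(self) -> float:
        return self.p_aB + self.p_AB

    def prob(self, allele1: int, allele2: int) -> float:
        """Haplotype probability by allele pair (0=ref, 1=alt)."""
        return (
            (self.p_ab, self.p_aB),
            (self.p_Ab, self.p_AB),
        )[allele1][allele2]


@dataclass(frozen=True)
class LDStats:
    """Pairwise LD summary: D, its normaliser, D' and r^2."""

    d: float
    d_max: float
    d_prime: float
    r2: float
    monomorphic_flag: bool = False


def count_pair(
    matrix: GenotypeMatrix,
    locus1: int,
    locus2: int,
    sample_subset=None,
) -> PairCounts:
    """Tally the 3x3 genotype table for two loci.

    Only samples non-missing at *both* loci contribute (pairwise
    complete); ``sample_subset`` optionally restricts the tally further.
    """
    if locus1 == locus2:
        raise ValueError("locus1 and locus2 must differ")
    g1 = matrix.genotypes[:, locus1]
    g2 = matrix.genotypes[:, locus2]
    if sample_subset is not None:
        idx = np.asarray(sorted(sample_subset), dtype=np.intp)
        g1, g2 = g1[idx], g2[idx]
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[keep], g2[keep]
    n = np.zeros((3, 3), dtype=np.int64)
    np.add.at(n, (g1, g2), 1)
    return PairCounts.from_table(n)


def em_haplotype_freqs(
    counts: PairCounts,
    n_iterations: int = 10,
    x1_init: float = 0.5,
) -> HaplotypeFreqs:
    """Estimate two-locus haplotype frequencies by EM.

    Each iteration applies the frequency equations with the current
    phase split, then updates the split::

        p(ab) = (2 N00 + N01 + N10 + X1 N11) / (2 N)
        p(aB) = (2 N02 + N01 + N12 + X2 N11) / (2 N)
        p(Ab) = (2 N20 + N21 + N10 + X2 N11) / (2 N)
        p(AB) = (2 N22 + N21 + N12 + X1 N11) / (2 N)

        X1 = p(ab) p(AB) / (p(ab) p(AB) + p(aB) p(Ab)),  X2 = 1 - X1

    Runs exactly ``n_iterations`` full cycles, no convergence test.
    When the phase-update denominator vanishes the likelihood in X1 is
    flat and the previous split is kept.
    """
    if counts.total < 1:
        raise UndefinedStatisticsError("cannot estimate frequencies from 0 samples")
    n = counts.n
    two_n = 2.0 * counts.total
    x1, x2 = float(x1_init), 1.0 - float(x1_init)
    p_ab = p_aB = p_Ab = p_AB = 0.25
    for _ in range(n_iterations):
        p_ab = (2 * n[0, 0] + n[0, 1] + n[1, 0] + x1 * n[1, 1]) / two_n
        p_aB = (2 * n[0, 2] + n[0, 1] + n[1, 2] + x2 * n[1, 1]) / two_n
        p_Ab = (2 * n[2, 0] + n[2, 1] + n[1, 0] + x2 * n[1, 1]) / two_n
        p_AB = (2 * n[2, 2] + n[2, 1] + n[1, 2] + x1 * n[1, 1]) / two_n
        denom = p_ab * p_AB + p_aB * p_Ab
        if denom > 0.0:
            x1 = p_ab * p_AB / denom
            x2 = p_aB * p_Ab / denom
    return HaplotypeFreqs(p_ab=p_ab, p_aB=p_aB, p_Ab=p_Ab, p_AB=p_AB, x1=x1, x2=x2)


def ld_stats(freqs: HaplotypeFreqs) -> LDStats:
    """Compute D, D_max, D' and r^2 from haplotype frequencies.

    D_max depends on the sign of D::

        D >= 0:  min(p(a.) p(.B), p(A.) p(.b))
        D <  0:  min(p(a.) p(.b), p(A.) p(.B))

    If either locus is monomorphic the measures are undefined; the
    result is flagged and D'/r^2 are set to 0 rather than raising.
    """
    pa, pA = freqs.p_a_dot, freqs.p_A_dot
    pb, pB = freqs.p_dot_b, freqs.p_dot_B
    d = freqs.p_ab - pa * pb
    if min(pa, pA, pb, pB) <= 0.0:
        return LDStats(d=d, d_max=0.0, d_prime=0.0, r2=0.0, monomorphic_flag=True)
    if d >= 0:
        d_max = min(pa * pB, pA * pb)
    else:
        d_max = min(pa * pb, pA * pB)
    d_prime = d / d_max
    r2 = d * d / (pa * pb * pA * pB)
    return LDStats(d=d, d_max=d_max, d_prime=d_prime, r2=r2, monomorphic_flag=False)
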