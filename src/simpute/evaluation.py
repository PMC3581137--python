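"""Masking benchmark harness and synthetic genotype generation.

Emulates the masking experimental designs used to assess flanking-locus
imputation on dense SNP panels: genotypes are simulated by drawing
haplotype pairs from a pool with controllable LD (Hardy-Weinberg
sampling), a fraction of entries is hidden under one of three regimes,
the imputer fills them back, and the error rate — wrongly imputed
entries over masked entries, in percent — is averaged over repeats. A
per-locus modal-genotype imputer serves as the naive baseline.

Masking regimes
---------------
complete
    Uniform masking of a fixed fraction of all entries.
short_input
    The loci are tiled into disjoint 3-SNP windows and at most two of
    a sample's three window entries may be masked, mimicking panels of
    isolated three-SNP regions.
high_ld
    Only loci in strong LD (adjacent-pair r^2 above a threshold,
    default 0.9, on either side) are eligible for masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .imputer import impute_all
from .pairwise_stats import count_pair, em_haplotype_freqs, ld_stats

__all__ = [
    "MaskSpec",
    "HaplotypePool",
    "generate_pool",
    "simulate_genotypes",
    "apply_mask",
    "impute_modal",
    "error_rate",
    "benchmark",
]

REGIMES = ("complete", "short_input", "high_ld")


def _floor_count(rate: float, eligible: int) -> int:
    # floor(rate * eligible), guarded against float dust (0.15*1620 = 242.9999...)
    return int(np.floor(rate * eligible + 1e-9))


@dataclass(frozen=True)
class MaskSpec:
    """Parameters of one masking experiment."""

    missing_rate: float
    regime: str = "complete"
    r2_threshold: float = 0.9  # high_ld only
    max_missing_per_window: int = 2  # short_input only
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in (0, 1)")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass(frozen=True)
class HaplotypePool:
    """A finite haplotype population: allele vectors and frequencies."""

    haplotypes: np.ndarray  # (n_haplotypes, n_loci) of 0/1
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.frequencies.sum()) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if self.haplotypes.shape[0] != len(self.frequencies):
            raise ValueError("one frequency per haplotype required")


def generate_pool(
    n_loci: int, n_haplotypes: int, ld_strength: float, seed: int
) -> HaplotypePool:
    """Build a haplotype pool with tunable pairwise LD.

    A random template haplotype is drawn; each pool haplotype tracks the
    template directly or in complement, starting in alternating phase,
    and at each subsequent locus keeps its phase with probability
    ``ld_strength`` or redraws it uniformly. ld_strength=1 gives
    template/complement haplotypes (near-complete adjacent LD);
    ld_strength=0 gives independent alleles (linkage equilibrium).
    Frequencies are uniform. Deterministic given ``seed``.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    if not 0.0 <= ld_strength <= 1.0:
        raise ValueError("ld_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    template = rng.integers(0, 2, size=n_loci)
    haps = np.empty((n_haplotypes, n_loci), dtype=np.int8)
    for i in range(n_haplotypes):
        flip = i % 2
        for j in range(n_loci):
            if j > 0 and rng.random() >= ld_strength:
                flip = int(rng.integers(0, 2))
            haps[i, j] = template[j] ^ flip
    freqs = np.full(n_haplotypes, 1.0 / n_haplotypes)
    return HaplotypePool(haplotypes=haps, frequencies=freqs)


def simulate_genotypes(
    pool: HaplotypePool, n_samples: int, seed: int
) -> GenotypeMatrix:
    """Draw diploid genotypes by random union of pool haplotypes
    (Hardy-Weinberg sampling). Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    n_hap, n_loci = pool.haplotypes.shape
    picks = rng.choice(n_hap, size=(2, n_samples), p=pool.frequencies)
    geno = pool.haplotypes[picks[0]] + pool.haplotypes[picks[1]]
    return GenotypeMatrix(
        sample_ids=[f"S{i:04d}" for i in range(n_samples)],
        locus_ids=[f"L{j:04d}" for j in range(n_loci)],
        genotypes=geno.astype(np.int16),
    )


def adjacent_r2(matrix: GenotypeMatrix, n_iterations: int = 10) -> np.ndarray:
    """r^2 between each pair of neighbouring loci (length n_loci - 1)."""
    out = np.empty(matrix.n_loci - 1)
    for j in range(matrix.n_loci - 1):
        freqs = em_haplotype_freqs(count_pair(matrix, j, j + 1), n_iterations)
        out[j] = ld_stats(freqs).r2
    return out


def apply_mask(
    matrix: GenotypeMatrix, spec: MaskSpec
) -> tuple[GenotypeMatrix, set[tuple[int, int]]]:
    """Hide genotypes per the masking regime; returns the masked copy
    and the set of (sample, locus) index pairs hidden.

    The mask size is the floor of rate x eligible entries, drawn
    without replacement; reproducible from ``spec.seed``.
    """
    if matrix.missing_mask().any():
        raise ValueError("input matrix already contains missing entries")
    rng = np.random.default_rng(spec.seed)
    n_s, n_l = matrix.n_samples, matrix.n_loci
    total = n_s * n_l

    if spec.regime == "complete":
        k = _floor_count(spec.missing_rate, total)
        if k == 0:
            raise ValueError("missing_rate yields zero masked entries")
        flat = rng.choice(total, size=k, replace=False)
        mask = {(int(f) // n_l, int(f) % n_l) for f in flat}
    elif spec.regime == "short_input":
        if n_l % 3 != 0:
            raise ValueError("short_input regime requires loci in 3-SNP windows")
        k = _floor_count(spec.missing_rate, total)
        if k == 0:
            raise ValueError("missing_rate yields zero masked entries")
        order = rng.permutation(total)
        mask = set()
        per_window: dict[tuple[int, int], int] = {}
        for f in order:
            if len(mask) == k:
                break
            s, l = int(f) // n_l, int(f) % n_l
            wkey = (s, l // 3)
            if per_window.get(wkey, 0) >= spec.max_missing_per_window:
                continue
            mask.add((s, l))
            per_window[wkey] = per_window.get(wkey, 0) + 1
        if len(mask) < k:
            raise ValueError("window constraint leaves too few maskable entries")
    else:  # high_ld
        r2 = adjacent_r2(matrix)
        qualifies = np.zeros(n_l, dtype=bool)
        qualifies[:-1] |= r2 > spec.r2_threshold
        qualifies[1:] |= r2 > spec.r2_threshold
        loci = np.flatnonzero(qualifies)
        if loci.size == 0:
            raise ValueError(
                f"no locus has adjacent r^2 > {spec.r2_threshold}"
            )
        candidates = [(s, int(l)) for l in loci for s in range(n_s)]
        k = _floor_count(spec.missing_rate, len(candidates))
        if k == 0:
            raise ValueError("missing_rate yields zero masked entries")
        picks = rng.choice(len(candidates), size=k, replace=False)
        mask = {candidates[int(i)] for i in picks}

    masked = matrix.copy()
    for s, l in mask:
        masked.genotypes[s, l] = MISSING
    return masked, mask


def impute_modal(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Naive baseline: fill each missing entry with the locus's modal
    genotype among observed samples (ties to the smaller genotype)."""
    out = matrix.copy()
    for j in range(matrix.n_loci):
        col = matrix.genotypes[:, j]
        obs = col[col != MISSING]
        mode = int(np.bincount(obs, minlength=3).argmax()) if obs.size else 0
        out.genotypes[col == MISSING, j] = mode
    return out


def error_rate(
    truth: GenotypeMatrix,
    imputed: GenotypeMatrix,
    mask: set[tuple[int, int]],
) -> float:
    """Imputation error rate in percent:
    100 x (# masked entries imputed wrongly) / (# masked entries)."""
    if not mask:
        raise ValueError("empty mask")
    wrong = sum(
        1
        for s, l in mask
        if imputed.genotypes[s, l] != truth.genotypes[s, l]
    )
    return 100.0 * wrong / len(mask)


def benchmark(
    matrix: GenotypeMatrix,
    spec: MaskSpec,
    n_repeats: int,
    base_seed: int,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Repeat mask -> impute -> score and average.

    Repeat r uses mask seed ``base_seed + r``. Returns a per-repeat
    table (repeat, method, n_masked, n_errors, error_rate_pct) for the
    flanking-locus imputer ("simpute") and the modal baseline
    ("modal"), plus the mean error rate per method.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rows = []
    for rep in range(n_repeats):
        rep_spec = MaskSpec(
            missing_rate=spec.missing_rate,
            regime=spec.regime,
            r2_threshold=spec.r2_threshold,
            max_missing_per_window=spec.max_missing_per_window,
            seed=base_seed + rep,
        )
        masked, mask = apply_mask(matrix, rep_spec)
        filled, _ = impute_all(masked)
        modal = impute_modal(masked)
        for method, result in (("simpute", filled), ("modal", modal)):
            err = error_rate(matrix, result, mask)
            rows.append(
                {
                    "repeat": rep,
                    "method": method,
                    "n_masked": len(mask),
                    "n_errors": round(err * len(mask) / 100.0),
                    "error_rate_pct": err,
                }
            )
    df = pd.DataFrame(rows)
    means = df.groupby("method")["error_rate_pct"].mean().to_dict()
    return df, means
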