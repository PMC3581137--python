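# Methods

## Model and assumptions

`simpute` treats each missing genotype as a local problem: the missing
locus *Q* plus its two flanking loci *P* and *R*. The statistical
ingredients are all two-locus quantities — genotype contingency tables,
EM haplotype frequencies and pairwise LD — combined into a heuristic
score over three-locus haplotype pairs. The approach assumes:

* **Biallelic loci, diploid samples.** Genotypes are alternate-allele
  counts 0/1/2. Multi-allelic VCF records are excluded on read.
* **Random union of haplotypes (HWE)** within the estimation sample,
  which underlies both the EM phase split and the pair score's
  `P(h) + P(h')` term.
* **Local LD carries the signal.** The three-locus haplotype
  probability is *not* estimated directly (three-locus counts are too
  sparse in realistic samples); it is approximated by the product of
  the three pairwise probabilities, each weighted by the pair's r².
  The resulting quantity is a score, not a normalised probability, and
  is documented as such.
* **Missingness is ignorable** for estimation: statistics are computed
  from samples complete at all of P, Q, R.

The method needs no reference panel and no phasing of the input.

## Estimation details

**EM.** The phase proportions start at X₁ = X₂ = 0.5 and exactly 10
full frequency-update/phase-update cycles are run, with no convergence
test. The statement of the procedure could also be read as "stop after
10 iterations or on convergence of X₁ or X₂"; we run the fixed count,
the only unambiguous reading, and expose `n_iterations` for anyone who
wants more. On random tables the 10-cycle estimate agrees with a dense
grid-search maximiser of the multinomial table likelihood to well under
1e-3 (the test suite checks 200 such tables). The fixed point also
solves a cubic; we keep the iteration as the primary path and use the
grid search purely as an independent test oracle. If the phase-update
denominator p(ab)p(AB) + p(aB)p(Ab) is zero while N₁,₁ > 0, the
likelihood is flat in X₁ and the previous split is kept (avoids 0/0).
The returned frequencies are those of the final frequency update; the
returned X₁ is the final phase update computed from them.

**LD.** D' keeps its sign; only r² feeds the imputer. If either locus
is monomorphic the LD statistics are undefined; `ld_stats` returns
flagged zeros rather than raising, and the imputer's own floor (below)
takes over.

**Floors.** Inside a triple context each pairwise r² is floored at
1e-5, and each genotype association weight W is floored at 1e-5. The
floors exist so that a single zero cannot annihilate the product score;
raw `LDStats` values are never floored. Note that W = 1 − |expected −
observed| cannot actually reach 0 on a finite table (a deviation of
exactly 1 would require an observed frequency of 1 together with an
expectation of 0), so the W floor is a guard that only binds for
user-supplied floor values; it is implemented as specified regardless.

**Tie-breaking** (the procedure is silent here): among maximum-score
haplotype pairs, the Q genotype with the largest margin in the P–Q
table wins, then the numerically smaller genotype. Deterministic, and
favours the empirically common genotype. If *every* legitimate pair
scores zero (e.g. Q monomorphic among complete samples), the modal Q
genotype among complete samples is imputed and the entry is flagged as
a fallback — the score is uninformative and the mode is the natural
reference-free default.

**Identical-haplotype pairs** use the score formula literally:
P(h) + P(h) = 2P(h), with no homozygosity correction.

## Traversal, runs and caching

Entries are processed per sample. Within a sample, each maximal run of
consecutive missing loci is filled from the end nearest an observed
locus inward, so freshly imputed entries become flanks for the rest of
the run; a run touching a chromosome end takes both flanks from the
observed side (same-side fallback, flagged per entry). When both run
ends border observed loci the run is filled left-to-right. The
inter-sample order is irrelevant to the output: triple statistics are
computed from the *originally observed* genotypes only — imputed values
never join the counting population (avoids feedback bias and matches
the single statistics pass of the complexity argument) — and a fill
only ever serves as a flank for the same sample.

Contexts are cached per (P, Q, R) triple, giving the O(mw + n) work
profile: one statistics pass per distinct triple plus O(1) scoring
(at most 36 pair evaluations) per missing entry. The report counts
scored pairs, which the tests use as the operation-count proxy for this
contract. "Neighbouring" is defined by column adjacency; base-pair
positions are carried through I/O but do not affect flank selection. An
optional `max_flank_distance` window bounds the flank search (unbounded
by default, since the method is designed for immediate neighbours).

Entries with fewer than two available loci in their sample, or whose
triple has no complete sample, are left missing and reported.

## Synthetic data generator

`generate_pool` builds a haplotype pool by Markov copying against a
random template: each haplotype starts in alternating phase
(template/complement) and at each next locus keeps its phase with
probability `ld_strength`, else redraws it uniformly. `ld_strength=1`
yields a two-pattern pool with near-complete adjacent LD (the regime
the method targets); `ld_strength=0` yields linkage equilibrium up to
finite-pool noise of order 1/n_haplotypes. `simulate_genotypes` draws
two haplotypes per sample independently from the pool frequencies
(HWE). Defaults used throughout the tests mirror desk-scale versions of
genotyping-panel benchmarks: 200 samples, 50 loci, two haplotypes at
0.5/0.5, 5% masking, 10 repeats.

What the generator does **not** emulate: recombination gradients,
allele-frequency spectra, genotyping-error correlation, population
structure, or realistic LD decay. Passing the perfect-LD recovery test
therefore shows the machinery is correct in the regime where the method
is exact, not that real-data error rates will be low; on weakly linked
real loci the method is explicitly not expected to compete with
reference-panel imputation.

## Masking regimes

* `complete`: floor(rate × all entries) entries hidden uniformly
  without replacement. Floor rounding keeps the masked counts integral
  (5% of a 270×6 panel is exactly 81 entries), with a 1e-9 guard
  against float dust in the product.
* `short_input`: loci are tiled into disjoint 3-SNP windows (the
  alternative sliding-window reading was rejected as the emulated
  design is literally "regions of only three SNPs"); a draw that would
  make all 3 of a sample's window entries missing is rejected.
  Requires the locus count to be a multiple of 3.
* `high_ld`: eligibility is restricted to loci whose adjacent-pair r²
  (10-iteration EM on the unmasked matrix) exceeds the threshold
  (default 0.9) on at least one side; the rate applies to the eligible
  entries.

Error rate = 100 × (wrongly imputed masked entries)/(masked entries);
accuracy is its complement. The benchmark baseline is a per-locus
modal-genotype imputer, the genotype-level realisation of "fill with
the major allele".

## Numerical and degenerate-input choices

* Missing sentinel: −1 internally; tabular tokens NA, N, ?, −1, ".".
* The double-heterozygote cell is genotype 1; the 0/1/2 coding is
  fixed by the contingency-table convention (the phase-ambiguity term
  X₁N₁,₁ requires 1 = heterozygote).
* Empty tables raise; monomorphic loci flag rather than raise.
* A two-locus haplotype distribution with one absent class and both
  loci polymorphic always has |D′| = 1; the worked reference value
  (allele frequencies 0.9/0.1 at both loci, AB absent) gives
  r² = 1/81 ≈ 0.012, the package's analytic acceptance value.
* All randomness (pool, sampling, masks) flows through
  `numpy.random.default_rng(seed)`; identical seeds give byte-identical
  results, including through the CLI.

## Known limitations

* Uses only two flanking SNPs: long missing runs at chromosome ends
  degrade to same-side extrapolation and low-LD regions carry little
  signal.
* The pair score's margin normalisation mixes row and column margins
  asymmetrically; it is implemented exactly as specified, and a
  symmetric conditional-frequency variant was deliberately not
  introduced.
* No genotype posteriors, no phasing output, no multi-allelic support,
  no reference-panel mode.
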