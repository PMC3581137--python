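import numpy as np
import pytest

from simpute import (
    MISSING,
    GenotypeMatrix,
    MaskSpec,
    apply_mask,
    build_triple_context,
    generate_pool,
    haplotype_prob3,
    impute_all,
    impute_entry,
    pair_weight,
    score_pair,
    select_flanks,
    simulate_genotypes,
)
from simpute.imputer import (
    HAPLOTYPE_PAIRS,
    ContextUnavailableError,
    UnimputableEntryError,
)
from simpute.pairwise_stats import PairCounts

from _oracles import brute_force_entry
from conftest import matrix_from_array


def available_for(matrix, sample):
    return ~matrix.missing_mask()[sample]


class TestSelectFlanks:
    def test_adjacent_flanks(self):
        row = [0] * 10
        row[5] = MISSING
        m = matrix_from_array([row])
        assert select_flanks(m, 0, 5, available_for(m, 0)) == (4, 6, False)

    def test_left_edge_run_uses_right_side(self):
        # missing at loci 0-3, observed at 4, 5: the rightmost missing
        # locus borrows both flanks from the observed side
        m = matrix_from_array([[MISSING] * 4 + [0, 0]])
        assert select_flanks(m, 0, 3, available_for(m, 0)) == (4, 5, True)

    def test_filled_entries_count_as_available(self):
        m = matrix_from_array([[MISSING] * 4 + [0, 0]])
        avail = available_for(m, 0)
        avail[3] = True  # pretend locus 3 was just imputed
        assert select_flanks(m, 0, 2, avail) == (3, 4, True)

    def test_single_observed_locus_unimputable(self):
        m = matrix_from_array([[MISSING, 0, MISSING]])
        with pytest.raises(UnimputableEntryError):
            select_flanks(m, 0, 2, available_for(m, 0))

    def test_max_distance_window(self):
        row = [0] * 10
        row[5] = MISSING
        row[4] = MISSING
        row[6] = MISSING
        m = matrix_from_array([row])
        with pytest.raises(UnimputableEntryError):
            select_flanks(m, 0, 5, available_for(m, 0), max_distance=1)


class TestTripleContext:
    def test_perfect_ld_r2_one(self, perfect_ld_matrix):
        ctx = build_triple_context(perfect_ld_matrix, 0, 1, 2)
        assert ctx.r2_PQ == pytest.approx(1.0)
        assert ctx.r2_QR == pytest.approx(1.0)
        assert ctx.r2_PR == pytest.approx(1.0)

    def test_monomorphic_r2_floored(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, size=(50, 3))
        geno[:, 1] = 0  # Q monomorphic
        ctx = build_triple_context(matrix_from_array(geno), 0, 1, 2)
        assert ctx.r2_PQ == 1e-5
        assert ctx.r2_QR == 1e-5

    def test_cache_returns_same_object(self, perfect_ld_matrix):
        cache = {}
        a = build_triple_context(perfect_ld_matrix, 0, 1, 2, cache=cache)
        b = build_triple_context(perfect_ld_matrix, 0, 1, 2, cache=cache)
        assert a is b

    def test_counts_restricted_to_complete_samples(self):
        geno = [[0, 0, 0], [2, 2, 2], [MISSING, 1, 1]]
        ctx = build_triple_context(matrix_from_array(geno), 0, 1, 2)
        assert ctx.n_complete == 2
        assert ctx.counts_QR.total == 2  # third sample excluded everywhere

    def test_no_complete_samples_raises(self):
        geno = [[MISSING, 0, 0], [0, MISSING, 0]]
        with pytest.raises(ContextUnavailableError):
            build_triple_context(matrix_from_array(geno), 0, 1, 2)


class TestScoreComponents:
    def test_haplotype_prob3_hand_value(self, perfect_ld_matrix):
        ctx = build_triple_context(perfect_ld_matrix, 0, 1, 2)
        # independence-like stand-in: all pairwise probs 0.25, all r2 = 1
        class Flat:
            def prob(self, a, b):
                return 0.25

        flat_ctx = type(ctx)(
            p=0, q=1, r=2,
            counts_PQ=ctx.counts_PQ, counts_QR=ctx.counts_QR,
            counts_PR=ctx.counts_PR,
            freqs_PQ=Flat(), freqs_QR=Flat(), freqs_PR=Flat(),
            r2_PQ=1.0, r2_QR=1.0, r2_PR=1.0, n_complete=ctx.n_complete,
        )
        assert haplotype_prob3(flat_ctx, 0, 0, 0) == pytest.approx(0.25**3)
        floored = type(ctx)(
            p=0, q=1, r=2,
            counts_PQ=ctx.counts_PQ, counts_QR=ctx.counts_QR,
            counts_PR=ctx.counts_PR,
            freqs_PQ=Flat(), freqs_QR=Flat(), freqs_PR=Flat(),
            r2_PQ=1e-5, r2_QR=1e-5, r2_PR=1e-5, n_complete=ctx.n_complete,
        )
        assert haplotype_prob3(floored, 0, 0, 0) == pytest.approx(0.25**3 * 1e-15)

    def test_prob3_annihilates_on_zero_pairwise_prob(self, perfect_ld_matrix):
        ctx = build_triple_context(perfect_ld_matrix, 0, 1, 2)
        # in a two-haplotype pool at least one allele pairing is unseen
        vals = [haplotype_prob3(ctx, *h) for h in
                [(0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0)]]
        assert min(vals) == 0.0

    def test_pair_weight_hand_value(self):
        n = np.zeros((3, 3), dtype=np.int64)
        n[0, 0] = 10
        n[0, 1] = 40
        n[1, 0] = 40
        n[1, 1] = 10
        c = PairCounts.from_table(n)
        # margins 50x50 over N=100: expectation 0.25, observed 0.10
        assert pair_weight(c, 0, 0) == pytest.approx(0.85)

    def test_pair_weight_independence_is_one(self):
        n = np.zeros((3, 3), dtype=np.int64)
        n[0, 0], n[0, 1], n[1, 0], n[1, 1] = 25, 25, 25, 25
        c = PairCounts.from_table(n)
        assert pair_weight(c, 0, 0) == pytest.approx(1.0)

    def test_pair_weight_floor_contract(self):
        # |deviation| = 1 is unreachable for a finite table (observed 1
        # forces expectation 1), so exercise the floor via the parameter:
        # any weight below the floor is clamped up to it.
        n = np.zeros((3, 3), dtype=np.int64)
        n[0, 0] = 10
        n[0, 1] = 40
        n[1, 0] = 40
        n[1, 1] = 10
        c = PairCounts.from_table(n)
        assert pair_weight(c, 0, 0, floor=0.9) == pytest.approx(0.9)
        assert pair_weight(c, 0, 0, floor=1e-5) == pytest.approx(0.85)

    def test_score_symmetry(self, perfect_ld_matrix):
        ctx = build_triple_context(perfect_ld_matrix, 0, 1, 2)
        for h1, h2 in HAPLOTYPE_PAIRS[:12]:
            assert score_pair(ctx, h1, h2) == score_pair(ctx, h2, h1)

    def test_perfect_ld_scores(self, perfect_ld_matrix):
        ctx = build_triple_context(perfect_ld_matrix, 0, 1, 2)
        g = perfect_ld_matrix.genotypes
        hom = g[g[:, 0] != 1]  # a homozygous sample pattern
        hap = tuple(int(x) // 2 for x in hom[0, :3])
        comp = tuple(1 - a for a in hap)
        assert score_pair(ctx, hap, comp) > 0.0
        # swapping the middle alleles creates unseen haplotypes -> score 0
        mixed1 = (hap[0], comp[1], hap[2])
        mixed2 = (comp[0], hap[1], comp[2])
        assert score_pair(ctx, mixed1, mixed2) == 0.0


class TestImputeEntry:
    def test_forced_by_complete_ld(self, perfect_ld_matrix):
        ctx = build_triple_context(perfect_ld_matrix, 0, 1, 2)
        got = impute_entry(ctx, 1, 1)
        assert got.genotype_at_Q == 1
        g = perfect_ld_matrix.genotypes
        hom = g[g[:, 0] == 0][0]
        got = impute_entry(ctx, 0, int(hom[2]))
        assert got.genotype_at_Q == int(hom[1])

    @pytest.mark.parametrize("batch", range(5))
    def test_agrees_with_brute_force_oracle(self, batch, random_triple_matrix):
        """The selected Q genotype matches an independent 36-pair
        enumeration of the scoring formula (exact ties set aside)."""
        rng = np.random.default_rng(9000 + batch)
        checked = 0
        for trial in range(40):
            m = random_triple_matrix(seed=batch * 1000 + trial)
            try:
                ctx = build_triple_context(m, 0, 1, 2)
            except ContextUnavailableError:
                continue
            g_p, g_r = int(rng.integers(0, 3)), int(rng.integers(0, 3))
            got = impute_entry(ctx, g_p, g_r)
            f = lambda fr: np.array([[fr.p_ab, fr.p_aB], [fr.p_Ab, fr.p_AB]])
            max_score, top, modal = brute_force_entry(
                ctx.counts_PQ.n, ctx.counts_QR.n, ctx.counts_PR.n,
                f(ctx.freqs_PQ), f(ctx.freqs_QR), f(ctx.freqs_PR),
                ctx.r2_PQ, ctx.r2_QR, ctx.r2_PR, g_p, g_r,
            )
            checked += 1
            if max_score == 0.0:
                assert got.fallback and got.genotype_at_Q == modal
            else:
                assert got.score == pytest.approx(max_score, rel=1e-9)
                if len(top) == 1:
                    assert got.genotype_at_Q == top.pop()
                else:
                    assert got.genotype_at_Q in top
        assert checked >= 30


class TestImputeAll:
    def test_no_missing_is_identity(self, perfect_ld_matrix):
        out, rep = impute_all(perfect_ld_matrix)
        assert out == perfect_ld_matrix
        assert (rep.n_missing_entries, rep.n_loci_with_missing,
                rep.n_samples_with_missing) == (0, 0, 0)

    def test_observed_entries_untouched_and_values_valid(self, perfect_ld_matrix):
        masked, mask = apply_mask(
            perfect_ld_matrix, MaskSpec(missing_rate=0.1, seed=3)
        )
        out, rep = impute_all(masked)
        obs = ~masked.missing_mask()
        assert np.array_equal(out.genotypes[obs], masked.genotypes[obs])
        assert set(np.unique(out.genotypes)) <= {0, 1, 2}
        assert rep.n_missing_entries == len(mask)
        assert len(rep.entries) == len(mask)

    def test_left_edge_run_filled_inward(self):
        pool = generate_pool(n_loci=6, n_haplotypes=2, ld_strength=1.0, seed=21)
        truth = simulate_genotypes(pool, n_samples=80, seed=22)
        masked = truth.copy()
        masked.genotypes[0, :4] = MISSING
        out, rep = impute_all(masked)
        assert not out.missing_mask().any()
        assert np.array_equal(out.genotypes[0], truth.genotypes[0])
        # all four entries of the run are same-side (fallback) fills
        run_records = [e for e in rep.entries if e[0] == truth.sample_ids[0]]
        assert len(run_records) == 4 and all(e[5] for e in run_records)

    def test_determinism(self, perfect_ld_matrix):
        masked, _ = apply_mask(perfect_ld_matrix, MaskSpec(missing_rate=0.1, seed=7))
        out1, _ = impute_all(masked)
        out2, _ = impute_all(masked)
        assert out1 == out2

    def test_fewer_than_three_loci_rejected(self):
        with pytest.raises(ValueError, match="3 loci"):
            impute_all(matrix_from_array([[0, 1], [1, MISSING]]))

    def test_unimputable_entries_stay_missing(self):
        geno = np.zeros((5, 4), dtype=np.int16)
        geno[:, 0] = [0, 1, 2, 0, 1]
        geno[0, 1:] = MISSING  # sample 0 observed at a single locus
        out, rep = impute_all(matrix_from_array(geno))
        assert rep.n_unimputable == 3
        assert (out.genotypes[0, 1:] == MISSING).all()


class TestWorkScaling:
    def test_scored_pairs_linear_in_masked_entries(self):
        """With cached contexts, doubling the missing-entry count at
        fixed affected loci/samples exactly doubles the number of
        scored haplotype pairs."""
        # heterozygous-everywhere panel: every entry costs the same 8
        # scored pairs; samples 20-29 stay fully observed so each
        # masked column keeps complete samples for its triple context
        geno = np.ones((30, 15), dtype=np.int16)
        cols = (2, 5, 8, 11)
        small = geno.copy()
        for s in range(20):
            small[s, cols[::2] if s % 2 == 0 else cols[1::2]] = MISSING
        large = geno.copy()
        for s in range(20):
            large[s, cols] = MISSING
        m_small = matrix_from_array(small)
        m_large = matrix_from_array(large)
        _, rep_small = impute_all(m_small)
        _, rep_large = impute_all(m_large)
        # same loci and samples affected, twice the entries
        assert rep_large.n_loci_with_missing == rep_small.n_loci_with_missing
        assert rep_large.n_samples_with_missing == rep_small.n_samples_with_missing
        assert rep_large.n_missing_entries == 2 * rep_small.n_missing_entries
        assert rep_large.n_scored_pairs == 2 * rep_small.n_scored_pairs
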