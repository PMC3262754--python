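"""Pooled likelihood-ratio calling: oracle equivalence, EM, filters.

The oracle used throughout is an independent direct-product enumeration:
plain float products of the per-entry emission probabilities over the
integer allele-count grid, with none of the caller's log-space machinery.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poolcall.caller import (
    CallerConfig,
    PileupColumn,
    PileupEntry,
    adjacency_filter,
    call_candidate,
    column_likelihoods,
    em_allele_count,
    left_align_indel,
    per_strand_llr,
    strand_balance_test,
)

from conftest import make_panel


def make_column(syms, quals, strands=None, ref="A"):
    strands = strands or ["+"] * len(syms)
    entries = [
        PileupEntry(s, q, st_, f"r{i}", 1)
        for i, (s, q, st_) in enumerate(zip(syms, quals, strands))
    ]
    return PileupColumn("c", 10, ref, entries)


# ---------------------------------------------------------------------------
# independent enumeration oracle (plain products, no log space)
# ---------------------------------------------------------------------------

def oracle_llr_and_k(column, alt, n_samples):
    n2 = 2 * n_samples
    l0 = 1.0
    l1 = {}
    probs = []
    for e in column.entries:
        err = max(10.0 ** (-e.qual / 10.0), 1e-10)
        p_ref = (1 - err) if e.sym == column.ref else err / 3
        p_alt = (1 - err) if e.sym == alt else err / 3
        probs.append((p_ref, p_alt))
        l0 *= p_ref
    best_k, best_l1 = None, -1.0
    for k in range(1, n2 + 1):
        f = k / n2
        lk = 1.0
        for p_ref, p_alt in probs:
            lk *= (1 - f) * p_ref + f * p_alt
        l1[k] = lk
        if lk > best_l1:
            best_l1, best_k = lk, k
    return math.log10(best_l1 / l0), best_k


def random_column(rng, max_depth=50, max_n=8):
    depth = int(rng.integers(2, max_depth + 1))
    ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
    syms = [
        alt if rng.random() < 0.2 else (ref if rng.random() < 0.9 else
                                        rng.choice(list("ACGT")))
        for _ in range(depth)
    ]
    quals = rng.integers(20, 41, size=depth)
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(depth)]
    return make_column(syms, quals, strands, ref=str(ref)), str(alt)


class TestOracleEquivalence:
    def test_thousand_random_columns(self):
        """Log-space LLR and k_hat agree with direct product enumeration."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(1000):
            col, alt = random_column(rng)
            n_samples = int(rng.integers(1, 9))
            cfg = CallerConfig(n_samples=n_samples)
            if col.support(alt) == 0:
                continue
            log_l0, log_l1 = column_likelihoods(col, alt, cfg)
            llr = float(log_l1.max() - log_l0)
            oracle_llr, oracle_k = oracle_llr_and_k(col, alt, n_samples)
            assert llr == pytest.approx(oracle_llr, abs=1e-9)
            _, k_hat = em_allele_count(col, alt, cfg)
            assert abs(k_hat - oracle_k) <= 1
            checked += 1
        assert checked > 800

    def test_four_alt_entries_low_error(self):
        """All-alt column at e=0.001: LLR ~= 13.9 with k at the 2N ceiling."""
        col = make_column(["C"] * 4, [30] * 4, ref="A")
        cfg = CallerConfig(n_samples=8)
        log_l0, log_l1 = column_likelihoods(col, "C", cfg)
        llr = float(log_l1.max() - log_l0)
        oracle, k = oracle_llr_and_k(col, "C", 8)
        assert llr == pytest.approx(oracle, abs=1e-9)
        assert llr == pytest.approx(13.9, abs=0.1)
        assert int(np.argmax(log_l1)) + 1 == 16 == k

    def test_half_alt_column_recovers_k_8(self):
        """10 ref / 10 alt at e=0.01, N=8: enumeration argmax is k=8."""
        col = make_column(["C"] * 10 + ["A"] * 10, [20] * 20, ref="A")
        cfg = CallerConfig(n_samples=8)
        _, k_hat = em_allele_count(col, "C", cfg)
        _, oracle_k = oracle_llr_and_k(col, "C", 8)
        assert oracle_k == 8
        assert abs(k_hat - oracle_k) <= 1

    def test_all_reference_column_negative_llr(self):
        col = make_column(["A"] * 30, [25] * 30, ref="A")
        cfg = CallerConfig(n_samples=8)
        log_l0, log_l1 = column_likelihoods(col, "C", cfg)
        assert float(log_l1.max() - log_l0) < 0


class TestCallCandidate:
    def _col(self):
        return make_column(
            ["C"] * 6 + ["A"] * 94,
            [25] * 100,
            ["+", "-"] * 50,
            ref="A",
        )

    def test_strictly_above_threshold(self):
        """A candidate needs LLR strictly above the threshold."""
        col = self._col()
        cfg = CallerConfig(n_samples=8)
        log_l0, log_l1 = column_likelihoods(col, "C", cfg)
        llr = float(log_l1.max() - log_l0)
        at = CallerConfig(n_samples=8, llr_threshold=llr)
        below = CallerConfig(n_samples=8, llr_threshold=llr - 1e-6)
        assert call_candidate(col, at)[0] is None
        assert call_candidate(col, below)[0] is not None

    def test_best_alt_reported(self):
        col = make_column(
            ["C"] * 10 + ["G"] * 3 + ["A"] * 87, [25] * 100, ref="A"
        )
        cand, scored = call_candidate(col, CallerConfig(n_samples=8))
        assert cand.alt_sym == "C"
        assert {c.alt_sym for c in scored} == {"C", "G"}

    def test_no_candidate_from_pure_reference(self):
        col = make_column(["A"] * 50, [30] * 50, ref="A")
        cand, scored = call_candidate(col, CallerConfig(n_samples=8))
        assert cand is None
        assert scored == []


class TestEM:
    @pytest.mark.parametrize("k", [1, 2, 4, 8, 16])
    def test_noiseless_exact_recovery(self, k):
        """With negligible error and exact allele fraction, k_hat is exact."""
        n2, per = 16, 10
        col = make_column(
            ["C"] * (k * per) + ["A"] * ((n2 - k) * per),
            [90] * (n2 * per),
            ref="A",
        )
        f_hat, k_hat = em_allele_count(col, "C", CallerConfig(n_samples=8))
        assert k_hat == k
        assert f_hat == pytest.approx(k / n2, abs=1e-6)

    def test_all_ref_column_f_to_zero(self):
        col = make_column(["A"] * 40, [30] * 40, ref="A")
        f_hat, _ = em_allele_count(col, "C", CallerConfig(n_samples=8))
        assert f_hat < 1e-4

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6, 7, 8])
    def test_median_recovery_at_pool_depth(self, k):
        """Median k_hat over 50 seeds equals planted k (k <= N, e=0.01)."""
        from poolcall.simulate import simulate_pileup_column

        cfg = CallerConfig(n_samples=8)
        depth = 20 * cfg.n_chromosomes
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(1000 * k + seed)
            col = simulate_pileup_column(
                rng, n_samples=8, allele_count=k,
                depth_fwd=depth // 2, depth_rev=depth // 2, error_rate=0.01,
            )
            _, k_hat = em_allele_count(col, "C", cfg)
            estimates.append(k_hat)
        assert int(np.median(estimates)) == k


class TestStrandFilters:
    def test_balanced_table_p_one(self):
        col = make_column(
            ["C"] * 5 + ["A"] * 5 + ["C"] * 5 + ["A"] * 5,
            [25] * 20,
            ["+"] * 10 + ["-"] * 10,
            ref="A",
        )
        assert strand_balance_test(col, "C") == pytest.approx(1.0)

    def test_skewed_table_fails(self):
        """Fisher p for [[10,10],[0,20]] is below 0.05.

        Hand enumeration of the hypergeometric tail for this table gives
        p ~= 4.7e-4, so the candidate fails strand balance.
        """
        col = make_column(
            ["C"] * 10 + ["A"] * 10 + ["A"] * 20,
            [25] * 40,
            ["+"] * 20 + ["-"] * 20,
            ref="A",
        )
        p = strand_balance_test(col, "C")
        # independent oracle: two-sided Fisher by hypergeometric enumeration
        from math import comb

        n_alt, n_fwd, n = 10, 20, 40
        p0 = comb(n_alt, 10) * comb(n - n_alt, n_fwd - 10) / comb(n, n_fwd)
        oracle = sum(
            comb(n_alt, x) * comb(n - n_alt, n_fwd - x) / comb(n, n_fwd)
            for x in range(0, n_alt + 1)
            if comb(n_alt, x) * comb(n - n_alt, n_fwd - x) / comb(n, n_fwd)
            <= p0 * (1 + 1e-9)
        )
        assert p == pytest.approx(oracle, rel=1e-6)
        assert p < 0.05

    def test_zero_alt_entries_p_one(self):
        col = make_column(["A"] * 20, [25] * 20, ["+"] * 10 + ["-"] * 10)
        assert strand_balance_test(col, "C") == 1.0

    def test_swap_strand_labels_invariant(self):
        rng = np.random.default_rng(7)
        syms = ["C" if rng.random() < 0.3 else "A" for _ in range(30)]
        strands = ["+" if rng.random() < 0.6 else "-" for _ in range(30)]
        flipped = ["-" if s == "+" else "+" for s in strands]
        q = [25] * 30
        p1 = strand_balance_test(make_column(syms, q, strands), "C")
        p2 = strand_balance_test(make_column(syms, q, flipped), "C")
        assert p1 == pytest.approx(p2)

    def test_one_strand_support_fails_both_strand_rule(self):
        col = make_column(
            ["C"] * 10 + ["A"] * 40 + ["A"] * 50,
            [25] * 100,
            ["+"] * 50 + ["-"] * 50,
            ref="A",
        )
        cfg = CallerConfig(n_samples=8)
        llr_f, llr_r = per_strand_llr(col, "C", cfg)
        assert llr_f > 3.0
        assert llr_r < 0

    def test_empty_strand_is_minus_infinity(self):
        col = make_column(["C"] * 5 + ["A"] * 5, [25] * 10, ["+"] * 10)
        _, llr_r = per_strand_llr(col, "C", CallerConfig(n_samples=8))
        assert llr_r == -np.inf

    def test_deep_balanced_column_passes_both_strands(self):
        col = make_column(
            (["C"] * 10 + ["A"] * 10) * 2,
            [20] * 40,
            ["+"] * 20 + ["-"] * 20,
            ref="A",
        )
        cfg = CallerConfig(n_samples=8)
        llr_f, llr_r = per_strand_llr(col, "C", cfg)
        assert llr_f > 3.0 and llr_r > 3.0


class TestAdjacency:
    def _cand(self, pos):
        from poolcall.caller import CandidateVariant

        return CandidateVariant("c", pos, "A", "C", llr_total=5.0)

    def test_adjacent_pair_both_fail(self):
        cands = [self._cand(100), self._cand(101)]
        adjacency_filter(cands, CallerConfig(n_samples=8))
        assert all(not c.filters["adjacent_variant"] for c in cands)

    def test_gap_of_two_passes(self):
        cands = [self._cand(100), self._cand(102)]
        adjacency_filter(cands, CallerConfig(n_samples=8))
        assert all(c.filters["adjacent_variant"] for c in cands)

    def test_single_candidate_passes(self):
        cands = [self._cand(100)]
        adjacency_filter(cands, CallerConfig(n_samples=8))
        assert cands[0].filters["adjacent_variant"]


class TestLeftAlign:
    def test_homopolymer_deletion_shifts_left_3bp(self):
        #            0123456789
        panel = make_panel("TTACCCCGTT")
        # delete the 4th C (0-based 6): anchor base at 5, 1-based pos 6
        pos, ref, alt = left_align_indel(panel, "chr1", 6, "CC", "C")
        assert (pos, ref, alt) == (3, "AC", "A")

    def test_non_repeat_indel_unchanged(self):
        panel = make_panel("TTAGCATGCA")
        pos, ref, alt = left_align_indel(panel, "chr1", 4, "GC", "G")
        assert (pos, ref, alt) == (4, "GC", "G")

    def test_insertion_rotations_converge(self):
        panel = make_panel("TTGGCGGCGGCAA")
        # inserting GGC / GCG / CGG at different run anchors is equivalent
        reprs = {
            left_align_indel(panel, "chr1", 5, "C", "CGGC"),
            left_align_indel(panel, "chr1", 11, "C", "CGGC"),
            left_align_indel(panel, "chr1", 9, "G", "GGCG"),
        }
        assert len(reprs) == 1

    @given(st.data())
    def test_idempotent(self, data):
        rng_seq = data.draw(
            st.text(alphabet="ACGT", min_size=10, max_size=30), label="seq"
        )
        panel = make_panel(rng_seq)
        pos = data.draw(st.integers(2, len(rng_seq) - 4), label="pos")
        dlen = data.draw(st.integers(1, 3), label="dlen")
        ref = rng_seq[pos - 1 : pos - 1 + dlen + 1]
        alt = ref[0]
        once = left_align_indel(panel, "chr1", pos, ref, alt)
        assert left_align_indel(panel, "chr1", *once) == once


@given(st.integers(0, 2**31 - 1))
def test_appending_alt_support_never_decreases_llr(seed):
    rng = np.random.default_rng(seed)
    col, alt = random_column(rng, max_depth=30)
    if col.support(alt) == 0:
        col.entries.append(PileupEntry(alt, 25, "+", "rx", 1))
    cfg = CallerConfig(n_samples=4)
    l0, l1 = column_likelihoods(col, alt, cfg)
    before = float(l1.max() - l0)
    col.entries.append(PileupEntry(alt, int(rng.integers(20, 41)), "+", "ry", 1))
    l0, l1 = column_likelihoods(col, alt, cfg)
    after = float(l1.max() - l0)
    assert after >= before - 1e-12
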