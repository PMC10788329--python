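"""LD r^2, greedy block partition vs exhaustive oracle, QTL calling rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plastiqtl import qtl_blocks as qb
from plastiqtl import synthetic_data as sd
from plastiqtl.exceptions import ParameterError


class TestPairwiseR2:
    def test_identical_columns(self, toy_geno_factory):
        G = toy_geno_factory([[0, 0], [1, 1], [2, 2], [1, 1]])
        assert qb.pairwise_r2(G, 0, 1) == pytest.approx(1.0)

    def test_hand_worked_pair(self, toy_geno_factory):
        a = [0, 1, 2, 2, 0, 1]
        b = [0, 0, 2, 1, 1, 2]
        G = toy_geno_factory(np.array([a, b]).T)
        r = np.corrcoef(a, b)[0, 1]
        assert qb.pairwise_r2(G, 0, 1) == pytest.approx(r * r, abs=1e-12)

    def test_independent_snps_near_zero(self):
        G = sd.simulate_parents(500, 200, seed=3)
        rng = np.random.default_rng(0)
        r2s = [qb.pairwise_r2(G, int(i), int(j))
               for i, j in rng.integers(0, 200, size=(100, 2)) if i != j]
        assert np.nanmean(r2s) < 0.01

    def test_monomorphic_returns_nan(self, toy_geno_factory):
        G = toy_geno_factory([[2, 0], [2, 1], [2, 2]])
        assert np.isnan(qb.pairwise_r2(G, 0, 1))

    def test_missing_dropped_pairwise(self, toy_geno_factory):
        G = toy_geno_factory([[0, 0], [-1, 2], [2, 2], [1, 1], [2, 0]])
        a = [0, 2, 1, 2]
        b = [0, 2, 1, 0]
        r = np.corrcoef(a, b)[0, 1]
        assert qb.pairwise_r2(G, 0, 1) == pytest.approx(r * r, abs=1e-12)


def greedy_consistent(G, boundaries, r2_threshold, window):
    """Whether a segmentation (boundary set) matches the adjacency rule."""
    blocks = []
    cur = [0]
    for k in range(1, G.n_snps):
        if k in boundaries:
            blocks.append(cur)
            cur = [k]
        else:
            cur.append(k)
    blocks.append(cur)
    for blk in blocks:
        for i, snp in enumerate(blk[1:], start=1):
            tail = blk[max(0, i - window):i]
            ok = any(qb.pairwise_r2(G, snp, t) >= r2_threshold for t in tail)
            if not ok:
                return False
    for prev, blk in zip(blocks, blocks[1:]):
        tail = prev[-window:]
        if any(qb.pairwise_r2(G, blk[0], t) >= r2_threshold for t in tail):
            return False
    return True


class TestPartition:
    def test_single_snp_singleton_block(self, toy_geno_factory):
        G = toy_geno_factory([[0], [1], [2]])
        blocks = qb.partition_ld_blocks(G)
        assert len(blocks) == 1
        assert blocks[0].snp_indices == [0]

    def test_two_perfectly_correlated_snps_one_block(self, toy_geno_factory):
        G = toy_geno_factory([[0, 0], [2, 2], [1, 1], [2, 2]])
        blocks = qb.partition_ld_blocks(G, r2_threshold=0.6)
        assert len(blocks) == 1
        assert blocks[0].snp_indices == [0, 1]

    def test_matches_exhaustive_segmentation_oracle(self, toy_geno_factory):
        """On 15 SNPs the greedy output is the unique rule-consistent
        segmentation found by enumerating all contiguous segmentations."""
        rng = np.random.default_rng(4)
        base = rng.integers(0, 3, size=(30, 5))
        cols = [base[:, rng.integers(0, 5)] for _ in range(15)]
        noise = rng.integers(0, 3, size=(30, 15))
        mask = rng.random((30, 15)) < 0.25
        d = np.where(mask, noise, np.array(cols).T)
        G = toy_geno_factory(d)
        got = qb.partition_ld_blocks(G, r2_threshold=0.6, window=3)
        got_bounds = {blk.snp_indices[0] for blk in got} - {0}
        consistent = []
        for r in range(15):
            for bounds in itertools.combinations(range(1, 15), r):
                if greedy_consistent(G, set(bounds), 0.6, 3):
                    consistent.append(set(bounds))
        assert consistent == [got_bounds]

    def test_partition_conserves_snps(self, small_parents):
        blocks = qb.partition_ld_blocks(small_parents, r2_threshold=0.4,
                                        window=5)
        seen = [i for blk in blocks for i in blk.snp_indices]
        assert sorted(seen) == list(range(small_parents.n_snps))
        assert len(seen) == len(set(seen))

    def test_blocks_ordered_and_disjoint(self, small_parents):
        blocks = qb.partition_ld_blocks(small_parents, r2_threshold=0.5)
        for ch in set(b.chrom for b in blocks):
            ch_blocks = [b for b in blocks if b.chrom == ch]
            for a, b in zip(ch_blocks, ch_blocks[1:]):
                assert a.end < b.start

    def test_bad_threshold(self, small_parents):
        with pytest.raises(ParameterError):
            qb.partition_ld_blocks(small_parents, r2_threshold=0.0)


def assoc_frame(entries):
    """entries: list of (chrom, pos, p [, af, beta])."""
    rows = []
    for e in entries:
        chrom, pos, p = e[:3]
        af = e[3] if len(e) > 3 else 0.3
        beta = e[4] if len(e) > 4 else 0.1
        rows.append({"chr": chrom, "pos": pos, "allele0": "A", "allele1": "G",
                     "af": af, "beta": beta, "se": 0.01, "wald": 1.0,
                     "p_wald": p, "neglog10p": -np.log10(p)})
    return pd.DataFrame(rows)


def blocks_at(positions, chrom="Chr01"):
    return [qb.LDBlock(chrom=chrom, start=p, end=p, snp_indices=[i])
            for i, p in enumerate(positions)]


class TestCallQtls:
    def test_no_significant_snp_no_qtl(self):
        assoc = assoc_frame([("Chr01", 100, 0.5), ("Chr01", 200, 0.2)])
        assert qb.call_qtls(assoc, blocks_at([100, 200]), 1e-4) == []

    @pytest.mark.parametrize("gap,expected", [
        (500_000, 1),       # 0.5 Mb apart -> merged
        (1_000_000, 2),     # exactly 1 Mb -> not merged (strict rule)
        (1_500_000, 2),     # 1.5 Mb apart -> two QTLs
    ])
    def test_merge_distance_boundaries(self, gap, expected):
        pos = [1_000_000, 1_000_000 + gap]
        assoc = assoc_frame([("Chr01", pos[0], 1e-8), ("Chr01", pos[1], 1e-8)])
        calls = qb.call_qtls(assoc, blocks_at(pos), 1e-4)
        assert len(calls) == expected

    def test_lead_snp_and_brute_force(self):
        entries = [("Chr01", 100, 1e-6), ("Chr01", 200, 1e-9),
                   ("Chr01", 300, 1e-7)]
        assoc = assoc_frame(entries)
        blocks = [qb.LDBlock(chrom="Chr01", start=100, end=300,
                             snp_indices=[0, 1, 2])]
        calls = qb.call_qtls(assoc, blocks, 1e-4)
        assert len(calls) == 1
        # brute force: the max -log10 p member
        best = max(entries, key=lambda e: -np.log10(e[2]))
        assert calls[0].lead_pos == best[1]
        assert calls[0].start == 100 and calls[0].end == 300

    def test_lead_tie_broken_by_position(self):
        assoc = assoc_frame([("Chr01", 500, 1e-9), ("Chr01", 100, 1e-9)])
        calls = qb.call_qtls(assoc, blocks_at([100, 500]), 1e-4)
        assert calls[0].lead_pos == 100

    def test_threshold_monotonicity(self):
        """Lowering the threshold never removes covered QTL territory."""
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(10_000_000, 30, replace=False))
        ps = 10.0 ** rng.uniform(-10, -1, 30)
        assoc = assoc_frame([("Chr01", int(p), float(q))
                             for p, q in zip(pos, ps)])
        blocks = blocks_at([int(p) for p in pos])

        def coverage(thr):
            return set().union(*[set(range(c.start, c.end + 1))
                                 for c in qb.call_qtls(assoc, blocks, thr)],
                               set())
        assert coverage(1e-6) <= coverage(1e-4) <= coverage(1e-2)

    def test_pve_attached_from_lead(self):
        assoc = assoc_frame([("Chr01", 100, 1e-9, 0.5, 1.0)])
        calls = qb.call_qtls(assoc, blocks_at([100]), 1e-4, var_y=2.0)
        assert calls[0].pve_pct == pytest.approx(100 * 2 * 0.25 * 1.0 / 2.0)


class TestPVE:
    def test_zero_beta(self):
        assert qb.pve_of_snp(0.0, 0.3, 1.0) == 0.0

    def test_constructed_quarter(self):
        var_y = 2.0
        beta = np.sqrt(0.25 * var_y / (2 * 0.5 * 0.5))
        assert qb.pve_of_snp(beta, 0.5, var_y) == pytest.approx(25.0)

    def test_af_bounds(self):
        with pytest.raises(ParameterError):
            qb.pve_of_snp(1.0, 0.0, 1.0)

    def test_capped_at_100(self):
        assert qb.pve_of_snp(100.0, 0.5, 1.0) == 100.0

    def test_simulation_recovery(self):
        """Single causal SNP programmed to 30% of variance, n = 2000."""
        rng = np.random.default_rng(6)
        af = 0.4
        x = rng.binomial(2, af, 2000).astype(float)
        beta = 1.0
        var_snp = 2 * af * (1 - af) * beta ** 2
        noise = np.sqrt(var_snp * 70 / 30)
        y = beta * x + rng.normal(0, noise, 2000)
        bhat = np.polyfit(x, y, 1)[0]
        est = qb.pve_of_snp(bhat, x.mean() / 2, y.var())
        assert 25.0 <= est <= 35.0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(beta=st.floats(-10, 10), af=st.floats(0.01, 0.99),
           var_y=st.floats(0.1, 50))
    def test_always_in_unit_range(self, beta, af, var_y):
        assert 0.0 <= qb.pve_of_snp(beta, af, var_y) <= 100.0


def call(chrom, start, end, qid="Q"):
    return qb.QTLCall(qtl_id=qid, chrom=chrom, start=start, end=end,
                      lead_pos=start, lead_alleles=("A", "G"),
                      lead_neglog10p=9.0)


class TestOverlap:
    def test_identical_regions_overlap(self):
        a = [call("Chr01", 100, 200)]
        assert len(qb.overlap_qtls(a, a)) == 1

    def test_adjacent_half_open_no_overlap(self):
        a = [call("Chr01", 100, 200)]
        b = [call("Chr01", 201, 300)]     # [200, 300) touches [99, 200) at 200
        assert qb.overlap_qtls(a, b) == []

    def test_different_chromosomes_no_overlap(self):
        a = [call("Chr01", 100, 200)]
        b = [call("Chr02", 100, 200)]
        assert qb.overlap_qtls(a, b) == []

    def test_random_sets_vs_quadratic_oracle(self):
        rng = np.random.default_rng(7)

        def random_set(n):
            out = []
            for i in range(n):
                s = int(rng.integers(1, 10_000))
                e = s + int(rng.integers(1, 2_000))
                out.append(call(f"Chr{rng.integers(1, 4)}", s, e, qid=f"Q{i}"))
            return out

        a, b = random_set(12), random_set(12)
        got = {(x.qtl_id, y.qtl_id) for x, y in qb.overlap_qtls(a, b)}
        expect = set()
        for x in a:
            for y in b:
                if x.chrom == y.chrom:
                    # 1-based inclusive intersection length
                    if min(x.end, y.end) - max(x.start, y.start) + 1 >= 1:
                        expect.add((x.qtl_id, y.qtl_id))
        assert got == expect
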