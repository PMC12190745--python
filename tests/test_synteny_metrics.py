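"""Gene content distance and syntenic block extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from synflux.genome_io import CladeDataset
from synflux.jump_model import simulate_jumps
from synflux.synteny_metrics import (
    SBLDistribution,
    common_complement,
    compare_all_pairs,
    extract_synteny_blocks,
    gene_content_distance,
    mean_sbl,
)

from conftest import make_genome


class TestGeneContentDistance:
    def test_identical_sets_give_zero(self):
        a = make_genome("A", range(2000))
        b = make_genome("B", reversed(range(2000)))
        summary, gcd = gene_content_distance(a, b)
        assert summary.n_a == summary.n_b == summary.n_shared == 2000
        assert gcd == 0.0

    def test_half_shared_gives_ln2(self):
        a = make_genome("A", range(2000))
        b = make_genome("B", range(1000, 3000))
        summary, gcd = gene_content_distance(a, b)
        assert summary.n_shared == 1000
        assert gcd == pytest.approx(math.log(2), rel=1e-12)

    def test_disjoint_sets_raise(self):
        with pytest.raises(ValueError, match="no ortholog"):
            gene_content_distance(make_genome("A", [1, 2]), make_genome("B", [3, 4]))

    @given(
        st.sets(st.integers(0, 30), min_size=1, max_size=20),
        st.sets(st.integers(0, 30), min_size=1, max_size=20),
    )
    def test_symmetric_and_zero_iff_equal_sets(self, sa, sb):
        a, b = make_genome("A", sorted(sa)), make_genome("B", sorted(sb))
        if not (sa & sb):
            with pytest.raises(ValueError):
                gene_content_distance(a, b)
            return
        _, dab = gene_content_distance(a, b)
        _, dba = gene_content_distance(b, a)
        assert dab == pytest.approx(dba, abs=1e-14)
        assert (dab == 0.0) == (sa == sb)


class TestCommonComplement:
    def test_symmetric_difference_removed(self):
        a = make_genome("A", ["x", "p", "q", "r"])
        b = make_genome("B", ["p", "q", "r", "y"])
        ra, rb = common_complement(a, b)
        assert ra.replicons[0].cog_ids == ("p", "q", "r")
        assert rb.replicons[0].cog_ids == ("p", "q", "r")

    def test_multicopy_shared_cog_removed_from_both(self):
        a = make_genome("A", ["p", "s", "p", "q"])   # p duplicated in A
        b = make_genome("B", ["p", "q", "s"])
        ra, rb = common_complement(a, b)
        assert ra.replicons[0].cog_ids == ("s", "q")
        assert rb.replicons[0].cog_ids == ("q", "s")

    def test_identical_genomes_unchanged(self):
        a = make_genome("A", ["p", "q", "r"])
        ra, rb = common_complement(a, make_genome("B", ["p", "q", "r"]))
        assert ra.replicons[0].cog_ids == rb.replicons[0].cog_ids == ("p", "q", "r")

    def test_no_usable_shared_genes_raises(self):
        a = make_genome("A", ["p", "p"])  # only shared cog is multi-copy
        b = make_genome("B", ["p", "z"])
        with pytest.raises(ValueError, match="single-copy"):
            common_complement(a, b)


class TestExtractSyntenyBlocks:
    def test_single_internal_break_splits_into_two_blocks(self):
        # B carries 4,5,6 reversed: only the 3-4 adjacency of A is broken
        a = make_genome("A", [1, 2, 3, 4, 5, 6])
        b = make_genome("B", [1, 2, 3, 6, 5, 4])
        sbl = extract_synteny_blocks(a, b)
        assert sbl.counts == {3: 2}

    def test_fully_scrambled_pair_gives_singletons(self):
        a = make_genome("A", [1, 2, 3, 4])
        b = make_genome("B", [3, 1, 4, 2])
        sbl = extract_synteny_blocks(a, b)
        assert sbl.counts == {1: 4}
        assert mean_sbl(sbl) == 1.0

    def test_identical_circular_genomes_form_one_block(self):
        a = make_genome("A", range(10), topology="circular")
        b = make_genome("B", range(10), topology="circular")
        assert extract_synteny_blocks(a, b).counts == {10: 1}

    def test_rotation_of_circular_genome_is_one_block(self):
        a = make_genome("A", [0, 1, 2, 3, 4, 5], topology="circular")
        b = make_genome("B", [3, 4, 5, 0, 1, 2], topology="circular")
        assert extract_synteny_blocks(a, b).counts == {6: 1}

    def test_block_crossing_circular_origin_is_merged(self):
        # swapping 0,1 in B breaks the 1-2 and wrap 5-0 adjacencies of A;
        # the run 2..5 plus nothing wraps, runs are [0,1] and [2,3,4,5]
        a = make_genome("A", [0, 1, 2, 3, 4, 5], topology="circular")
        c = make_genome("C", [1, 0, 2, 3, 4, 5], topology="circular")
        assert extract_synteny_blocks(a, c).counts == {2: 1, 4: 1}

    def test_linear_ends_do_not_wrap(self):
        a = make_genome("A", [0, 1, 2, 3], topology="linear")
        b = make_genome("B", [2, 3, 0, 1], topology="linear")
        assert extract_synteny_blocks(a, b).counts == {2: 2}

    @given(st.permutations(list(range(12))), st.sampled_from(["linear", "circular"]))
    def test_symmetry_and_conservation(self, perm, topology):
        a = make_genome("A", range(12), topology=topology)
        b = make_genome("B", perm, topology=topology)
        ab = extract_synteny_blocks(a, b)
        ba = extract_synteny_blocks(b, a)
        assert ab.counts == ba.counts
        assert ab.total_genes == 12


class TestMeanSBL:
    @pytest.mark.parametrize(
        "counts,expected",
        [({3: 2}, 3.0), ({1: 7}, 1.0), ({10: 1}, 10.0), ({1: 2, 4: 2}, 2.5)],
    )
    def test_arithmetic(self, counts, expected):
        assert mean_sbl(SBLDistribution(counts)) == expected

    def test_empty_distribution_raises(self):
        with pytest.raises(ValueError):
            mean_sbl(SBLDistribution({}))

    def test_mean_sbl_decays_with_translocations(self):
        means = []
        for n_jumps in (0, 50, 200, 800):
            vals = []
            for seed in range(3):
                anc, der = simulate_jumps(2000, n_jumps, seed=seed)
                ra, rb = common_complement(anc, der)
                vals.append(mean_sbl(extract_synteny_blocks(ra, rb)))
            means.append(np.mean(vals))
        assert means == sorted(means, reverse=True)
        assert means[0] == 2000.0


class TestCompareAllPairs:
    def test_pair_count_is_n_choose_2(self):
        for n, expected in ((3, 3), (5, 10)):
            ds = CladeDataset(
                "CL", [make_genome(f"G{i}", ["x", "y", f"z{i}"]) for i in range(n)]
            )
            assert len(compare_all_pairs(ds)) == expected

    def test_identical_content_pair_is_flagged_unusable(self):
        ds = CladeDataset("CL", [
            make_genome("G0", ["a", "b", "c"]),
            make_genome("G1", ["c", "b", "a"]),
            make_genome("G2", ["a", "b", "d"]),
        ])
        pairs = {(p.genome_a, p.genome_b): p for p in compare_all_pairs(ds)}
        assert not pairs[("G0", "G1")].usable
        assert pairs[("G0", "G1")].gcd == 0.0
        assert pairs[("G0", "G2")].usable

    def test_disjoint_pair_is_flagged_not_fatal(self):
        ds = CladeDataset("CL", [
            make_genome("G0", ["a", "b"]),
            make_genome("G1", ["c", "d"]),
            make_genome("G2", ["a", "c"]),
        ])
        pairs = compare_all_pairs(ds)
        assert len(pairs) == 3
        flags = {(p.genome_a, p.genome_b): p.usable for p in pairs}
        assert not flags[("G0", "G1")]
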