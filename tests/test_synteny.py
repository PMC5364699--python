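"""Synteny tests, including the exhaustive monotone-chain oracle."""

import numpy as np
import pytest

from paleodup.genome_io import Gene, GeneIndex, HomologHit, ValidationError
from paleodup.synteny import (Anchor, ChainParams, SUB1, SUB2, UNASSIGNED,
                              SyntenyBlock, block_stats, build_anchors,
                              chain_blocks, partition_subgenomes)


def mk_anchor(r, d, score=10.0, rc="R1", dc="D1"):
    return Anchor(f"r{rc}{r}", f"d{dc}{d}", rc, dc, r, d, score)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of monotone chains


def oracle_chain_score(anchors, orientation, params):
    """Best chain score by depth-first enumeration of every monotone chain."""
    sign = 1 if orientation == "same" else -1
    pts = sorted(range(len(anchors)),
                 key=lambda i: (anchors[i].ref_rank, anchors[i].desc_rank))
    best = [float("-inf")]

    def extend(last, score):
        best[0] = max(best[0], score)
        for i in pts:
            a = anchors[i]
            if last is not None:
                rgap = a.ref_rank - anchors[last].ref_rank
                dgap = sign * (a.desc_rank - anchors[last].desc_rank)
                if rgap < 1 or dgap < 1:
                    continue
                if rgap > params.max_gap or dgap > params.max_gap:
                    continue
                gap_cost = params.gap_penalty * (max(rgap, dgap) - 1)
            else:
                gap_cost = 0.0
            extend(i, score + params.match_score + gap_cost)

    extend(None, 0.0)
    return best[0]


def oracle_best_score(anchors, params):
    return max(oracle_chain_score(anchors, o, params)
               for o in ("same", "inverted"))


class TestChainBlocks:
    def test_fifteen_collinear_anchors_one_block(self):
        anchors = [mk_anchor(i, i) for i in range(15)]
        blocks = chain_blocks(anchors, ChainParams(min_block_size=15))
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 15
        assert blocks[0].orientation == "same"

    def test_fourteen_anchors_below_threshold(self):
        anchors = [mk_anchor(i, i) for i in range(14)]
        assert chain_blocks(anchors, ChainParams(min_block_size=15)) == []

    def test_interleaved_direct_and_inverted_runs(self):
        # ten direct anchors and ten inverted ones on separate rank bands
        direct = [mk_anchor(i, i) for i in range(10)]
        inverted = [mk_anchor(10 + i, 40 - i) for i in range(10)]
        params = ChainParams(min_block_size=5)
        blocks = chain_blocks(direct + inverted, params)
        assert len(blocks) == 2
        assert {b.orientation for b in blocks} == {"same", "inverted"}
        got = {frozenset((a.ref_rank, a.desc_rank) for a in b.anchors)
               for b in blocks}
        assert frozenset((i, i) for i in range(10)) in got
        assert frozenset((10 + i, 40 - i) for i in range(10)) in got
        # the top chain score matches exhaustive enumeration
        score = max(b.chain_score for b in blocks)
        assert score == pytest.approx(
            oracle_best_score(direct + inverted, params))

    def test_empty_input(self):
        assert chain_blocks([], ChainParams()) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        anchors = [mk_anchor(int(r), int(d))
                   for r, d in zip(rng.integers(0, 30, n),
                                   rng.integers(0, 30, n))]
        # dedupe identical rank pairs
        anchors = list({(a.ref_rank, a.desc_rank): a for a in anchors}.values())
        params = ChainParams(min_block_size=2, max_gap=10)
        blocks = chain_blocks(anchors, params)
        if blocks:
            top = max(b.chain_score for b in blocks)
            assert top == pytest.approx(oracle_best_score(anchors, params))
        else:
            # no chain of >= 2 anchors beats two singletons
            assert oracle_best_score(anchors, params) <= \
                2 * params.match_score - 1e-9 or len(anchors) < 2

    def test_anchor_in_at_most_one_block(self):
        rng = np.random.default_rng(3)
        anchors = [mk_anchor(int(r), int(d))
                   for r, d in zip(rng.permutation(40), rng.permutation(40))]
        blocks = chain_blocks(anchors, ChainParams(min_block_size=2))
        seen = []
        for b in blocks:
            seen.extend((a.ref_rank, a.desc_rank) for a in b.anchors)
        assert len(seen) == len(set(seen))

    @pytest.mark.parametrize("size", [2, 5, 10, 20])
    def test_monotonicity_in_min_block_size(self, size):
        rng = np.random.default_rng(9)
        anchors = [mk_anchor(int(r), int(d))
                   for r, d in zip(sorted(rng.integers(0, 60, 30)),
                                   rng.integers(0, 60, 30))]
        smaller = chain_blocks(anchors, ChainParams(min_block_size=2))
        larger = chain_blocks(anchors, ChainParams(min_block_size=size))
        assert len(larger) <= len(smaller)

    def test_determinism_under_input_shuffling(self):
        rng = np.random.default_rng(4)
        anchors = [mk_anchor(int(r), int(d))
                   for r, d in zip(rng.integers(0, 40, 25),
                                   rng.integers(0, 40, 25))]
        anchors = list({(a.ref_rank, a.desc_rank): a for a in anchors}.values())
        ref = chain_blocks(anchors, ChainParams(min_block_size=2))
        for _ in range(5):
            rng.shuffle(anchors)
            again = chain_blocks(list(anchors), ChainParams(min_block_size=2))
            assert [(b.block_id, b.orientation,
                     [(a.ref_rank, a.desc_rank) for a in b.anchors])
                    for b in again] == \
                [(b.block_id, b.orientation,
                  [(a.ref_rank, a.desc_rank) for a in b.anchors])
                 for b in ref]


class TestBuildAnchors:
    def _indexes(self):
        ref = GeneIndex("ref", [Gene(f"r{i}", "R1", 100 * i + 1, 100 * i + 50)
                                for i in range(5)])
        desc = GeneIndex("desc", [Gene(f"d{i}", "D1", 100 * i + 1,
                                       100 * i + 50) for i in range(5)])
        return ref, desc

    def test_inter_genome_hits_only(self):
        ref, desc = self._indexes()
        hits = [HomologHit(f"r{i}", f"d{i}", 1e-30, 100.0) for i in range(5)]
        hits += [HomologHit("d0", "d1", 1e-30, 90.0),
                 HomologHit("d1", "d2", 1e-30, 90.0),
                 HomologHit("r0", "r1", 1e-30, 90.0)]
        anchors = build_anchors(hits, ref, desc)
        assert len(anchors) == 5
        assert all(a.score == 100.0 for a in anchors)

    def test_empty_hits(self):
        ref, desc = self._indexes()
        assert build_anchors([], ref, desc) == []

    def test_unknown_gene_listed(self):
        ref, desc = self._indexes()
        with pytest.raises(ValidationError, match="ghost"):
            build_anchors([HomologHit("r0", "ghost", 1e-30, 10.0)], ref, desc)


def _block(block_id, ref_ranks, desc_ranks, score, rc="R1", dc="D1"):
    anchors = [Anchor(f"{rc}r{r}", f"{dc}d{d}", rc, dc, r, d, 1.0)
               for r, d in zip(ref_ranks, desc_ranks)]
    return SyntenyBlock(block_id, rc, dc, anchors, "same", score)


class TestPartitionSubgenomes:
    def test_two_equal_blocks_split(self):
        ref = GeneIndex("ref", [])
        b1 = _block("B1", range(10), range(10), 10.0, dc="D1")
        b2 = _block("B2", range(10), range(10), 10.0, dc="D2")
        asg = partition_subgenomes([b1, b2], ref)
        assert {asg.label("B1"), asg.label("B2")} == {SUB1, SUB2}

    def test_lone_block_goes_to_subgenome1(self):
        ref = GeneIndex("ref", [])
        asg = partition_subgenomes([_block("B1", range(5), range(5), 5.0)],
                                   ref)
        assert asg.label("B1") == SUB1

    def test_three_overlapping_blocks(self):
        ref = GeneIndex("ref", [])
        b30 = _block("B30", range(12), range(12), 30.0, dc="D1")
        b20 = _block("B20", range(8), range(8), 20.0, dc="D2")
        b10 = _block("B10", range(6), range(6), 10.0, dc="D3")
        asg = partition_subgenomes([b30, b20, b10], ref)
        assert asg.label("B30") == SUB1
        assert asg.label("B20") == SUB2
        assert asg.label("B10") == UNASSIGNED

    def test_subgenome1_has_more_anchors(self):
        ref = GeneIndex("ref", [])
        big = _block("BIG", range(20), range(20), 5.0, dc="D1")
        small = _block("SMALL", range(8), range(8), 9.0, dc="D2")
        asg = partition_subgenomes([big, small], ref)
        assert asg.label("BIG") == SUB1

    def test_no_subgenome_overlaps_itself(self, small_dataset):
        from paleodup.synteny import _overlaps, build_anchors
        ds = small_dataset
        anchors = build_anchors(ds.hits, ds.ref_index, ds.desc_index)
        blocks = chain_blocks(anchors, ChainParams(min_block_size=5),
                              ds.ref_index, ds.desc_index)
        asg = partition_subgenomes(blocks, ds.ref_index)
        for sub in (SUB1, SUB2):
            mine = asg.assigned_blocks(sub)
            for i in range(len(mine)):
                for j in range(i + 1, len(mine)):
                    assert not _overlaps(mine[i], mine[j])

    def test_no_desc_gene_in_two_subgenomes(self, small_dataset):
        ds = small_dataset
        anchors = build_anchors(ds.hits, ds.ref_index, ds.desc_index)
        blocks = chain_blocks(anchors, ChainParams(min_block_size=5))
        asg = partition_subgenomes(blocks, ds.ref_index)
        seen = {}
        for sub in (SUB1, SUB2):
            for b in asg.assigned_blocks(sub):
                for a in b.anchors:
                    assert seen.setdefault(a.desc_gene_id, sub) == sub


class TestBlockStats:
    def _toy(self):
        # 12 genes of 10 bp on one chromosome; genome length 240
        genes = [Gene(f"d{i}", "D1", 20 * i + 1, 20 * i + 10)
                 for i in range(12)]
        return GeneIndex("desc", genes, {"D1": 240})

    def test_coverage_percentages(self):
        desc = self._toy()
        b = SyntenyBlock("B1", "R1", "D1",
                         [Anchor(f"r{i}", f"d{i}", "R1", "D1", i,
                                 i, 1.0) for i in range(6)], "same", 6.0)
        asg = partition_subgenomes([b], GeneIndex("ref", []))
        cov = block_stats(asg, desc)
        span = desc["d5"].end - desc["d0"].start + 1  # 110 bp
        assert cov.per_subgenome[SUB1]["span_bp"] == span
        assert cov.per_subgenome[SUB1]["n_genes_in_spans"] == 6
        assert cov.pct_genome_length == pytest.approx(100 * span / 240)
        assert cov.pct_genome_genes == pytest.approx(50.0)

    def test_empty_assignment(self):
        asg = partition_subgenomes([], GeneIndex("ref", []))
        cov = block_stats(asg, self._toy())
        assert cov.total_blocks == 0
        assert cov.total_span_bp == 0
        assert cov.pct_genome_genes == 0.0

    def test_zero_length_genome_rejected(self):
        asg = partition_subgenomes([], GeneIndex("ref", []))
        empty = GeneIndex("desc", [], {})
        with pytest.raises(ValidationError):
            block_stats(asg, empty)
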