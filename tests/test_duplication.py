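import logging

import numpy as np
import pytest

from _oracles import oracle_best_chain_score
from genefam.duplication import (
    DISPERSED,
    PROXIMAL,
    SINGLETON,
    TANDEM,
    WGD_SEGMENTAL,
    HomologPair,
    _best_chain,
    Anchor,
    chain_collinear_blocks,
    classify_duplications,
    subgenome_collinearity_summary,
    write_collinearity,
)
from genefam.io_formats import GeneLocus
from genefam.simulate import SimulationConfig, simulate_genome


def loci_on(chrom, genes, start_order=1):
    return [
        GeneLocus(
            gene_id=g,
            chromosome=chrom,
            start=(start_order + i - 1) * 1000 + 1,
            end=(start_order + i - 1) * 1000 + 600,
            strand="+",
            order_index=start_order + i,
        )
        for i, g in enumerate(genes)
    ]


class TestChaining:
    def test_five_ordered_pairs_one_same_block(self):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        loci = loci_on("c1", a) + loci_on("c2", b)
        pairs = [HomologPair(x, y) for x, y in zip(a, b)]
        blocks = chain_collinear_blocks(loci, pairs)
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == 5
        assert blocks[0].orientation == "same"

    def test_reversed_order_gives_inverted_block(self):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        loci = loci_on("c1", a) + loci_on("c2", list(reversed(b)))
        pairs = [HomologPair(x, y) for x, y in zip(a, b)]
        blocks = chain_collinear_blocks(loci, pairs)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_four_pairs_below_size_floor(self):
        a = [f"a{i}" for i in range(4)]
        b = [f"b{i}" for i in range(4)]
        loci = loci_on("c1", a) + loci_on("c2", b)
        pairs = [HomologPair(x, y) for x, y in zip(a, b)]
        assert chain_collinear_blocks(loci, pairs, min_block_size=5) == []

    def test_unplaced_gene_excluded_with_warning(self, caplog):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        loci = loci_on("c1", a) + loci_on("c2", b)
        pairs = [HomologPair(x, y) for x, y in zip(a, b)]
        pairs.append(HomologPair("a0", "nowhere"))
        with caplog.at_level(logging.WARNING):
            blocks = chain_collinear_blocks(loci, pairs)
        assert "lacks a chromosome placement" in caplog.text
        assert len(blocks) == 1

    def test_gap_constraint_splits_blocks(self):
        """Anchors separated by more than max_gap ranks cannot chain."""
        a = [f"a{i}" for i in range(10)]
        b = [f"b{i}" for i in range(10)]
        # second half offset by a 40-rank gap on both chromosomes
        loci = loci_on("c1", a[:5]) + loci_on("c1", a[5:], start_order=50)
        loci += loci_on("c2", b[:5]) + loci_on("c2", b[5:], start_order=50)
        pairs = [HomologPair(x, y) for x, y in zip(a, b)]
        blocks = chain_collinear_blocks(loci, pairs, min_block_size=5, max_gap=25)
        assert len(blocks) == 2
        assert all(len(blk.anchors) == 5 for blk in blocks)

    def test_dp_matches_exhaustive_search(self):
        """DP chain score equals exhaustive monotone-subset search on 200
        random instances of up to 12 anchors."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            max_gap = int(rng.choice([3, 10, 25]))
            pts = set()
            while len(pts) < n:
                pts.add((int(rng.integers(1, 40)), int(rng.integers(1, 40))))
            points = sorted(pts)
            anchors = [
                Anchor(pair=HomologPair(f"x{i}", f"y{i}"), order_a=a, order_b=b)
                for i, (a, b) in enumerate(points)
            ]
            best = 0.0
            for orientation in ("same", "inverted"):
                score, chain = _best_chain(anchors, orientation, max_gap, 1.0, 0.25)
                best = max(best, score)
            expected = oracle_best_chain_score(points, max_gap)
            assert best == pytest.approx(expected, abs=1e-9)


class TestClassification:
    def test_gene_without_pairs_is_singleton(self):
        loci = loci_on("c1", ["g1", "g2", "g3"])
        pairs = [HomologPair("g1", "g2")]
        calls = {c.gene_id: c.dup_type
                 for c in classify_duplications(loci, pairs, [])}
        assert calls["g3"] == SINGLETON

    def test_adjacent_ranks_are_tandem(self):
        loci = loci_on("c1", [f"g{i}" for i in range(1, 10)])
        pairs = [HomologPair("g7", "g8")]
        calls = {c.gene_id: c.dup_type
                 for c in classify_duplications(loci, pairs, [])}
        assert calls["g7"] == calls["g8"] == TANDEM

    def test_proximal_and_dispersed_rank_windows(self):
        loci = loci_on("c1", [f"g{i}" for i in range(1, 30)])
        pairs = [
            HomologPair("g1", "g6"),   # 5 ranks apart -> proximal
            HomologPair("g10", "g25"),  # 15 ranks apart -> dispersed
        ]
        calls = {c.gene_id: c.dup_type
                 for c in classify_duplications(loci, pairs, [],
                                                proximal_rank=10)}
        assert calls["g1"] == calls["g6"] == PROXIMAL
        assert calls["g10"] == calls["g25"] == DISPERSED

    def test_block_membership_takes_precedence(self):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        loci = loci_on("c1", a) + loci_on("c2", b)
        pairs = [HomologPair(x, y) for x, y in zip(a, b)]
        # a0 also has a tandem partner a1; block anchor wins
        pairs.append(HomologPair("a0", "a1"))
        blocks = chain_collinear_blocks(loci, pairs)
        calls = {c.gene_id: c.dup_type
                 for c in classify_duplications(loci, pairs, blocks)}
        assert calls["a0"] == WGD_SEGMENTAL


class TestPlantedRecovery:
    def test_noise_free_recovery_is_perfect(self, genome_fixture):
        blocks = chain_collinear_blocks(genome_fixture.loci, genome_fixture.pairs)
        calls = classify_duplications(
            genome_fixture.loci, genome_fixture.pairs, blocks
        )
        assert all(
            genome_fixture.truth[c.gene_id] == c.dup_type for c in calls
        )

    def test_ten_percent_noise_recovery_above_95(self):
        fix = simulate_genome(SimulationConfig(seed=7, noise_pair_rate=0.1))
        blocks = chain_collinear_blocks(fix.loci, fix.pairs)
        calls = classify_duplications(fix.loci, fix.pairs, blocks)
        acc = np.mean([fix.truth[c.gene_id] == c.dup_type for c in calls])
        assert acc >= 0.95

    def test_wgd_and_dispersed_dominate_duplicates(self, genome_fixture):
        """On WGD-style simulations the duplicated genes are mostly
        WGD/segmental, with dispersed the second class."""
        blocks = chain_collinear_blocks(genome_fixture.loci, genome_fixture.pairs)
        calls = [
            c
            for c in classify_duplications(
                genome_fixture.loci, genome_fixture.pairs, blocks
            )
            if c.dup_type != SINGLETON
        ]
        counts = {}
        for c in calls:
            counts[c.dup_type] = counts.get(c.dup_type, 0) + 1
        ranked = sorted(counts, key=counts.get, reverse=True)
        assert ranked[0] == WGD_SEGMENTAL
        assert ranked[1] == DISPERSED


def test_subgenome_summary(genome_fixture):
    blocks = chain_collinear_blocks(genome_fixture.loci, genome_fixture.pairs)
    sub_of = {c: c[0] for c in SimulationConfig().chromosomes}
    summary = subgenome_collinearity_summary(blocks, sub_of)
    assert summary["total"] == len(blocks)
    assert (
        summary.get("within_A", 0) + summary.get("within_D", 0) + summary["cross"]
        == summary["total"]
    )


def test_collinearity_writer(tmp_path, genome_fixture):
    blocks = chain_collinear_blocks(genome_fixture.loci, genome_fixture.pairs)
    out = tmp_path / "blocks.txt"
    write_collinearity(blocks, out)
    text = out.read_text()
    assert text.count("## Alignment") == len(blocks)
    for b in blocks:
        assert b.anchors[0].pair.gene_a in text
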