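"""Collinear-block chaining and five-way duplication typing.

Homologous gene pairs are chained, per chromosome pair and orientation, into
collinear blocks: runs of anchors whose gene *order* is monotone in both
genomes, with bounded rank gaps.  Chains are found by dynamic programming
(score = anchors minus a per-rank gap penalty) and extracted greedily without
anchor reuse, in the style of MCScanX.  Each gene is then assigned one
duplication origin with precedence

    wgd_segmental > tandem > proximal > dispersed > singleton

where membership in any block anchor means WGD/segmental, an adjacent-rank
homolog on the same chromosome means tandem, a homolog within ``proximal_rank``
ranks means proximal, any remaining homolog means dispersed, and no homolog at
all means singleton.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneLocus

log = logging.getLogger(__name__)

WGD_SEGMENTAL = "wgd_segmental"
TANDEM = "tandem"
PROXIMAL = "proximal"
DISPERSED = "dispersed"
SINGLETON = "singleton"

DUP_TYPES = (SINGLETON, DISPERSED, PROXIMAL, TANDEM, WGD_SEGMENTAL)


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    score: float = 1.0

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r}")

    @property
    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass(frozen=True)
class Anchor:
    pair: HomologPair
    order_a: int
    order_b: int


@dataclass(frozen=True)
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: tuple[Anchor, ...]
    orientation: str  # "same" | "inverted"
    score: float

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise ValueError("a collinear block needs >= 2 anchors")

    @property
    def gene_set(self) -> frozenset:
        genes = set()
        for a in self.anchors:
            genes |= a.pair.key
        return frozenset(genes)


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    dup_type: str

    def __post_init__(self):
        if self.dup_type not in DUP_TYPES:
            raise ValueError(f"unknown duplication type {self.dup_type!r}")


def _locus_map(loci: Sequence[GeneLocus]) -> dict[str, GeneLocus]:
    return {l.gene_id: l for l in loci}


def chain_score(
    points: Sequence[tuple[int, int]],
    anchor_score: float = 1.0,
    gap_penalty: float = 0.25,
) -> float:
    """Score of a chain already ordered along both axes."""
    score = anchor_score * len(points)
    for (a0, b0), (a1, b1) in zip(points, points[1:]):
        score -= gap_penalty * ((abs(a1 - a0) - 1) + (abs(b1 - b0) - 1))
    return score


def _best_chain(
    anchors: list[Anchor],
    orientation: str,
    max_gap: int,
    anchor_score: float,
    gap_penalty: float,
) -> tuple[float, list[Anchor]]:
    """DP over anchors: best-scoring chain monotone in both coordinates.

    Orientation "same" requires order_b strictly increasing with order_a;
    "inverted" strictly decreasing.  Consecutive anchors must be within
    ``max_gap`` intervening gene ranks on both chromosomes.
    """
    sign = 1 if orientation == "same" else -1
    pts = sorted(anchors, key=lambda a: (a.order_a, sign * a.order_b))
    n = len(pts)
    dp = [anchor_score] * n
    back = [-1] * n
    for i in range(n):
        ai, bi = pts[i].order_a, sign * pts[i].order_b
        for j in range(i):
            aj, bj = pts[j].order_a, sign * pts[j].order_b
            if aj >= ai or bj >= bi:
                continue
            gap_a = ai - aj - 1
            gap_b = bi - bj - 1
            if gap_a > max_gap or gap_b > max_gap:
                continue
            cand = dp[j] + anchor_score - gap_penalty * (gap_a + gap_b)
            if cand > dp[i] + 1e-12:
                dp[i] = cand
                back[i] = j
    if not dp:
        return 0.0, []
    best = max(range(n), key=lambda i: (dp[i], -pts[i].order_a))
    chain = []
    i = best
    while i != -1:
        chain.append(pts[i])
        i = back[i]
    chain.reverse()
    return dp[best], chain


def chain_collinear_blocks(
    loci: Sequence[GeneLocus],
    pairs: Sequence[HomologPair],
    min_block_size: int = 5,
    max_gap: int = 25,
    anchor_score: float = 1.0,
    gap_penalty: float = 0.25,
) -> list[CollinearBlock]:
    """Chain homolog pairs into collinear blocks per chromosome pair.

    Pairs naming genes without a locus are excluded with a warning (genes
    lacking placement on assembled chromosomes cannot be chained).  Blocks
    from the same chromosome pair never share anchors: the best chain is
    extracted, its anchors removed, and the DP repeated until no chain
    reaches ``min_block_size`` anchors.
    """
    if not pairs:
        raise ValueError("no homolog pairs supplied")
    lmap = _locus_map(loci)
    by_chrom_pair: dict[tuple[str, str], list[Anchor]] = {}
    for p in pairs:
        la, lb = lmap.get(p.gene_a), lmap.get(p.gene_b)
        if la is None or lb is None:
            missing = p.gene_a if la is None else p.gene_b
            log.warning("pair (%s, %s): gene %s lacks a chromosome placement; "
                        "excluded", p.gene_a, p.gene_b, missing)
            continue
        # canonical orientation of the chromosome pair; within one chromosome
        # the smaller order goes on the a-axis
        if (la.chromosome, la.order_index) <= (lb.chromosome, lb.order_index):
            key = (la.chromosome, lb.chromosome)
            anchor = Anchor(pair=p, order_a=la.order_index, order_b=lb.order_index)
        else:
            key = (lb.chromosome, la.chromosome)
            anchor = Anchor(pair=p, order_a=lb.order_index, order_b=la.order_index)
        by_chrom_pair.setdefault(key, []).append(anchor)

    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in sorted(by_chrom_pair.items()):
        pool = list(anchors)
        while len(pool) >= min_block_size:
            best = None
            for orientation in ("same", "inverted"):
                score, chain = _best_chain(
                    pool, orientation, max_gap, anchor_score, gap_penalty
                )
                if chain and (best is None or score > best[0] + 1e-12):
                    best = (score, chain, orientation)
            if best is None or len(best[1]) < min_block_size:
                break
            score, chain, orientation = best
            blocks.append(
                CollinearBlock(
                    chrom_a=ca,
                    chrom_b=cb,
                    anchors=tuple(chain),
                    orientation=orientation,
                    score=score,
                )
            )
            used = {id(a) for a in chain}
            pool = [a for a in pool if id(a) not in used]
    for b in blocks:  # post-hoc invariant check: gap constraint on every block
        for a0, a1 in zip(b.anchors, b.anchors[1:]):
            assert abs(a1.order_a - a0.order_a) - 1 <= max_gap
            assert abs(a1.order_b - a0.order_b) - 1 <= max_gap
    return blocks


def classify_duplications(
    loci: Sequence[GeneLocus],
    pairs: Sequence[HomologPair],
    blocks: Sequence[CollinearBlock],
    proximal_rank: int = 10,
    tandem_rank: int = 1,
) -> list[DuplicationCall]:
    """Assign one duplication origin per locus, with the standard precedence."""
    lmap = _locus_map(loci)
    block_genes: set[str] = set()
    for b in blocks:
        block_genes |= b.gene_set
    partners: dict[str, set[str]] = {}
    for p in pairs:
        if p.gene_a in lmap and p.gene_b in lmap:
            partners.setdefault(p.gene_a, set()).add(p.gene_b)
            partners.setdefault(p.gene_b, set()).add(p.gene_a)
    calls = []
    for locus in sorted(loci, key=lambda l: (l.chromosome, l.order_index)):
        g = locus.gene_id
        mates = partners.get(g, set())
        if not mates:
            dup = SINGLETON
        elif g in block_genes:
            dup = WGD_SEGMENTAL
        else:
            min_rank_gap = None
            for m in mates:
                lm = lmap[m]
                if lm.chromosome != locus.chromosome:
                    continue
                gap = abs(lm.order_index - locus.order_index)
                if min_rank_gap is None or gap < min_rank_gap:
                    min_rank_gap = gap
            if min_rank_gap is not None and min_rank_gap <= tandem_rank:
                dup = TANDEM
            elif min_rank_gap is not None and min_rank_gap <= proximal_rank:
                dup = PROXIMAL
            else:
                dup = DISPERSED
        calls.append(DuplicationCall(gene_id=g, dup_type=dup))
    return calls


def subgenome_collinearity_summary(
    blocks: Sequence[CollinearBlock],
    subgenome_of_chrom: Mapping[str, str],
) -> dict:
    """Partition blocks by subgenome: within each, and across (homeologous).

    Returns counts keyed ``within_<S>`` per subgenome plus ``cross`` and the
    cross fraction; also the ratio of within-subgenome counts when exactly two
    subgenomes are present (reported as second:first in sorted order).
    """
    counts: dict[str, int] = {}
    cross = 0
    for b in blocks:
        sa = subgenome_of_chrom[b.chrom_a]
        sb = subgenome_of_chrom[b.chrom_b]
        if sa == sb:
            counts[sa] = counts.get(sa, 0) + 1
        else:
            cross += 1
    total = sum(counts.values()) + cross
    out: dict = {f"within_{s}": n for s, n in sorted(counts.items())}
    out["cross"] = cross
    out["total"] = total
    out["cross_fraction"] = cross / total if total else float("nan")
    subs = sorted(counts)
    if len(subs) == 2:
        first, second = subs
        out[f"within_{second}_to_{first}_ratio"] = (
            counts[second] / counts[first] if counts[first] else float("inf")
        )
    return out


def write_collinearity(blocks: Sequence[CollinearBlock], path) -> None:
    """MCScanX-style text listing of collinear blocks and their anchors."""
    with open(path, "w") as fh:
        fh.write("############### collinear blocks ###############\n")
        for i, b in enumerate(blocks):
            sign = "plus" if b.orientation == "same" else "minus"
            fh.write(
                f"## Alignment {i}: score={b.score:.2f} "
                f"N={len(b.anchors)} {b.chrom_a}&{b.chrom_b} {sign}\n"
            )
            for j, a in enumerate(b.anchors):
                fh.write(f"{i:3d}-{j:3d}:\t{a.pair.gene_a}\t{a.pair.gene_b}\n")


def write_duplication_calls(calls: Sequence[DuplicationCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdup_type\n")
        for c in sorted(calls, key=lambda c: c.gene_id):
            fh.write(f"{c.gene_id}\t{c.dup_type}\n")
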