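"""Gene-family membership decisions from profile-HMM hits and orthogroups.

The decision engine combines two independent homology signals:

1. a ranked profile-HMM search per subfamily, thresholded at the E-value of
   the *last* (worst-scoring) reference member seen in the output, and
2. orthogroup structure: how completely each cluster of orthologs/recent
   paralogs is recovered above that threshold (the *completion ratio*).

A gene is kept when it scores above the subfamily threshold and either sits in
a cluster containing a previously identified member (*known* cluster), forms a
cluster by itself (*singleton*), or sits in a cluster whose completion ratio
reaches the configurable cutoff (default 50%).  Reference members of the
anchor species can be force-included regardless of score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import HmmHit, Orthogroup, gene_id_of

log = logging.getLogger(__name__)

# verdicts
KEEP = "keep"
REJECT = "reject"

# reason codes
KNOWN_ABOVE = "KNOWN_ABOVE"
SINGLETON_ABOVE = "SINGLETON_ABOVE"
PARTIAL_GE50 = "PARTIAL_GE50"
FORCED = "FORCED"
BELOW_THRESHOLD = "BELOW_THRESHOLD"
PARTIAL_LT50 = "PARTIAL_LT50"
NO_HIT = "NO_HIT"

# cluster types
SINGLETON = "singleton"
COMPLETE = "complete"
PARTIAL = "partial"
ABSENT = "absent"


@dataclass(frozen=True)
class ReferenceSet:
    """Previously validated members per subfamily, in the anchor species.

    ``members`` maps subfamily -> reference transcript or gene ids; these
    anchor the E-value threshold.  ``force_include`` lists gene ids that are
    always kept (the anchor species' published family is retained wholesale).
    """

    members: Mapping[str, tuple[str, ...]]
    force_include: frozenset = frozenset()

    def genes(self, subfamily: str) -> frozenset:
        if subfamily not in self.members or not self.members[subfamily]:
            raise ValueError(f"no reference members configured for {subfamily!r}")
        return frozenset(gene_id_of(m) for m in self.members[subfamily])

    @property
    def force_include_genes(self) -> frozenset:
        return frozenset(gene_id_of(g) for g in self.force_include)


@dataclass(frozen=True)
class Threshold:
    subfamily: str
    anchor_id: str  # transcript id of the hit that set the cutoff
    evalue_cutoff: float

    def __post_init__(self):
        if self.evalue_cutoff <= 0:
            raise ValueError("E-value cutoff must be > 0")


@dataclass(frozen=True)
class ClusterAssessment:
    group_id: str
    cluster_type: str  # singleton | complete | partial | absent
    is_known: bool
    completion_ratio: float
    member_genes: tuple[str, ...]
    above_genes: tuple[str, ...]


@dataclass(frozen=True)
class ClassificationDecision:
    gene_id: str
    subfamily: str
    verdict: str  # keep | reject
    reason_code: str
    group_id: str | None
    cluster_type: str | None
    completion_ratio: float | None
    evalue: float | None  # best (smallest) E-value over the gene's variants
    ambiguous: bool = False


def determine_threshold(
    hits: Sequence[HmmHit], refs: ReferenceSet, subfamily: str
) -> Threshold:
    """Set the inclusion cutoff from the worst-scoring reference member.

    For each reference gene, its *first-occurring* hit in the ranked output
    (any transcript variant) represents it; the cutoff is the largest E-value
    among those representatives.  Ties break toward the later-ranked hit, then
    the lexicographically smaller id, so the result is deterministic.
    """
    ref_genes = refs.genes(subfamily)
    first_hit: dict[str, HmmHit] = {}
    for hit in hits:
        g = hit.gene_id
        if g in ref_genes and g not in first_hit:
            first_hit[g] = hit
    if not first_hit:
        raise ValueError(
            f"threshold undefined: no reference member of {subfamily!r} "
            "appears in the search output"
        )
    anchor = max(
        first_hit.values(),
        key=lambda h: (h.evalue, h.rank, _neg_lex(h.target_id)),
    )
    log.info(
        "%s threshold anchored at %s (E-value %.3g, rank %d)",
        subfamily,
        anchor.target_id,
        anchor.evalue,
        anchor.rank,
    )
    return Threshold(
        subfamily=subfamily, anchor_id=anchor.target_id, evalue_cutoff=anchor.evalue
    )


class _neg_lex(str):
    """Reverses lexicographic comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def genes_above_threshold(
    hits: Iterable[HmmHit], threshold: Threshold
) -> frozenset:
    """Gene ids with any transcript variant at E-value <= cutoff (inclusive)."""
    return frozenset(
        h.gene_id for h in hits if h.evalue <= threshold.evalue_cutoff
    )


def best_evalue_per_gene(hits: Iterable[HmmHit]) -> dict[str, float]:
    best: dict[str, float] = {}
    for h in hits:
        g = h.gene_id
        if g not in best or h.evalue < best[g]:
            best[g] = h.evalue
    return best


def assess_cluster(
    group: Orthogroup,
    hits_above: frozenset | set,
    known_ids: frozenset | set,
) -> ClusterAssessment:
    """Type one orthogroup against the set of above-threshold genes.

    Transcript variants are collapsed to genes before counting; a cluster
    whose members are all variants of one gene is a singleton.
    """
    genes = group.member_genes
    if not genes:
        raise ValueError(f"orthogroup {group.group_id!r} has no member genes")
    known_genes = {gene_id_of(k) for k in known_ids}
    above = tuple(sorted(set(genes) & set(hits_above)))
    ratio = len(above) / len(genes)
    if len(genes) == 1:
        ctype = SINGLETON
    elif ratio == 1.0:
        ctype = COMPLETE
    elif ratio == 0.0:
        ctype = ABSENT
    else:
        ctype = PARTIAL
    return ClusterAssessment(
        group_id=group.group_id,
        cluster_type=ctype,
        is_known=bool(set(genes) & known_genes),
        completion_ratio=ratio,
        member_genes=genes,
        above_genes=above,
    )


def decide(
    assessments: Sequence[ClusterAssessment],
    hits_above: frozenset | set,
    refs: ReferenceSet,
    subfamily: str,
    *,
    hit_genes: frozenset | set | None = None,
    completion_threshold: float = 0.5,
    partial_keep_below: bool = False,
) -> list[ClassificationDecision]:
    """Apply the decision table to every gene in the assessed clusters.

    Keep policy (default): above threshold AND (known cluster OR singleton OR
    completion ratio >= ``completion_threshold``), or membership in the
    force-include list.  ``partial_keep_below=True`` additionally keeps
    below-threshold members of clusters that reach the completion cutoff.
    ``hit_genes`` distinguishes genes with *some* hit (rejected as
    BELOW_THRESHOLD) from genes with none (rejected as NO_HIT).
    """
    forced = refs.force_include_genes
    hit_genes = frozenset(hit_genes) if hit_genes is not None else frozenset(hits_above)
    decisions = []
    for a in assessments:
        for gene in a.member_genes:
            above = gene in hits_above
            if above:
                if a.is_known:
                    verdict, code = KEEP, KNOWN_ABOVE
                elif a.cluster_type == SINGLETON:
                    verdict, code = KEEP, SINGLETON_ABOVE
                elif a.completion_ratio >= completion_threshold:
                    verdict, code = KEEP, PARTIAL_GE50
                elif gene in forced:
                    verdict, code = KEEP, FORCED
                else:
                    verdict, code = REJECT, PARTIAL_LT50
            else:
                if gene in forced:
                    verdict, code = KEEP, FORCED
                elif (
                    partial_keep_below
                    and a.cluster_type == PARTIAL
                    and a.completion_ratio >= completion_threshold
                ):
                    verdict, code = KEEP, PARTIAL_GE50
                elif gene not in hit_genes:
                    verdict, code = REJECT, NO_HIT
                else:
                    verdict, code = REJECT, BELOW_THRESHOLD
            decisions.append(
                ClassificationDecision(
                    gene_id=gene,
                    subfamily=subfamily,
                    verdict=verdict,
                    reason_code=code,
                    group_id=a.group_id,
                    cluster_type=a.cluster_type,
                    completion_ratio=a.completion_ratio,
                    evalue=None,
                )
            )
    return decisions


@dataclass
class ClassificationResult:
    thresholds: dict[str, Threshold]
    decisions: list[ClassificationDecision]

    @property
    def kept_genes(self) -> dict[str, str]:
        """kept gene id -> subfamily (first subfamily wins on ambiguity)."""
        out: dict[str, str] = {}
        for d in self.decisions:
            if d.verdict == KEEP and d.gene_id not in out:
                out[d.gene_id] = d.subfamily
        return out


def classify_family(
    groups: Sequence[Orthogroup],
    hits_by_subfamily: Mapping[str, Sequence[HmmHit]],
    refs: ReferenceSet,
    *,
    known_ids_by_subfamily: Mapping[str, Iterable[str]] | None = None,
    completion_threshold: float = 0.5,
    partial_keep_below: bool = False,
) -> ClassificationResult:
    """Run threshold determination + cluster assessment + decisions per subfamily.

    Known cluster membership defaults to the reference genes themselves;
    supply ``known_ids_by_subfamily`` to add other previously published ids.
    Genes decided in more than one subfamily are flagged ambiguous in every
    one of their decisions (no silent drop).
    """
    thresholds: dict[str, Threshold] = {}
    all_decisions: list[ClassificationDecision] = []
    for subfamily in sorted(hits_by_subfamily):
        hits = hits_by_subfamily[subfamily]
        threshold = determine_threshold(hits, refs, subfamily)
        thresholds[subfamily] = threshold
        above = genes_above_threshold(hits, threshold)
        hit_genes = frozenset(h.gene_id for h in hits)
        known = set(refs.genes(subfamily))
        if known_ids_by_subfamily and subfamily in known_ids_by_subfamily:
            known |= {gene_id_of(k) for k in known_ids_by_subfamily[subfamily]}
        assessments = [
            assess_cluster(g, above, known)
            for g in groups
            if set(g.member_genes) & hit_genes
        ]
        decisions = decide(
            assessments,
            above,
            refs,
            subfamily,
            hit_genes=hit_genes,
            completion_threshold=completion_threshold,
            partial_keep_below=partial_keep_below,
        )
        best = best_evalue_per_gene(hits)
        decisions = [replace(d, evalue=best.get(d.gene_id)) for d in decisions]
        all_decisions.extend(decisions)
    # flag genes decided under more than one subfamily
    seen: dict[str, set[str]] = {}
    for d in all_decisions:
        seen.setdefault(d.gene_id, set()).add(d.subfamily)
    all_decisions = [
        replace(d, ambiguous=len(seen[d.gene_id]) > 1) for d in all_decisions
    ]
    kept = {d.gene_id for d in all_decisions if d.verdict == KEEP}
    for gene, subs in sorted(seen.items()):
        if len(subs) > 1 and gene in kept:
            log.warning("kept gene %s decided in multiple subfamilies: %s",
                        gene, ",".join(sorted(subs)))
    return ClassificationResult(thresholds=thresholds, decisions=all_decisions)


def summarize_by_species(
    decisions: Sequence[ClassificationDecision],
    species_of_gene: Mapping[str, str],
    published_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Counts of kept genes per species x subfamily, split published vs new."""
    published = {gene_id_of(g) for g in published_ids} if published_ids else set()
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for d in decisions:
        if d.verdict != KEEP:
            continue
        sp = species_of_gene.get(d.gene_id, "?")
        key = (sp, d.subfamily)
        row = rows.setdefault(key, {"published": 0, "new": 0, "total": 0})
        row["published" if d.gene_id in published else "new"] += 1
        row["total"] += 1
    out = pd.DataFrame(
        [
            {"species": sp, "subfamily": sub, **counts}
            for (sp, sub), counts in sorted(rows.items())
        ],
        columns=["species", "subfamily", "published", "new", "total"],
    )
    return out
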