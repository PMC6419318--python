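import pytest

from genefam.classify import (
    ABSENT,
    BELOW_THRESHOLD,
    COMPLETE,
    FORCED,
    KEEP,
    KNOWN_ABOVE,
    NO_HIT,
    PARTIAL,
    PARTIAL_GE50,
    PARTIAL_LT50,
    REJECT,
    SINGLETON,
    SINGLETON_ABOVE,
    ReferenceSet,
    Threshold,
    assess_cluster,
    best_evalue_per_gene,
    classify_family,
    decide,
    determine_threshold,
    genes_above_threshold,
    summarize_by_species,
)
from genefam.io_formats import HmmHit, Orthogroup


def make_hits(rows, subfamily="RAF"):
    """rows: list of (target_id, evalue); ranks follow list order."""
    return [
        HmmHit(target_id=t, subfamily=subfamily, evalue=e, bitscore=100.0, rank=i)
        for i, (t, e) in enumerate(rows, start=1)
    ]


def group(gid, *genes):
    return Orthogroup(
        group_id=gid, members=tuple(("Sp", g, f"{g}.1") for g in genes)
    )


class TestDetermineThreshold:
    def test_worst_scoring_reference_sets_cutoff(self):
        """The documented anchor pattern: the reference member whose first hit
        has the largest E-value anchors the threshold."""
        hits = make_hits(
            [
                ("AT1G01.1", 1e-120),
                ("OTHER1.1", 1e-100),
                ("AT2G02.1", 1e-90),
                ("AT5G07140.1", 4.10e-79),
                ("DECOY.1", 1e-20),
            ]
        )
        refs = ReferenceSet(
            members={"RAF": ("AT1G01.1", "AT2G02.1", "AT5G07140.1")}
        )
        thr = determine_threshold(hits, refs, "RAF")
        assert thr.anchor_id == "AT5G07140.1"
        assert thr.evalue_cutoff == 4.10e-79

    def test_single_reference_single_hit(self):
        hits = make_hits([("R1.1", 1e-50)])
        refs = ReferenceSet(members={"RAF": ("R1.1",)})
        thr = determine_threshold(hits, refs, "RAF")
        assert thr.evalue_cutoff == 1e-50

    def test_first_variant_instance_represents_the_gene(self):
        """A gene with variants .1 (earlier, stronger) and .2 (later, weaker)
        is represented by its first-occurring variant."""
        rows = [(f"F{i}.1", 10.0 ** -(100 - i)) for i in range(6)]  # fillers
        rows += [("REFA.1", 1e-60), ("OTHER.1", 1e-58), ("REFA.2", 1e-55)]
        hits = make_hits(rows)
        refs = ReferenceSet(members={"RAF": ("REFA.1", "F0.1")})
        thr = determine_threshold(hits, refs, "RAF")
        assert thr.anchor_id == "REFA.1"
        assert thr.evalue_cutoff == 1e-60

    def test_no_reference_in_output_is_an_error(self):
        hits = make_hits([("X.1", 1e-10)])
        refs = ReferenceSet(members={"RAF": ("ABSENT.1",)})
        with pytest.raises(ValueError, match="threshold undefined"):
            determine_threshold(hits, refs, "RAF")

    def test_anchor_itself_is_above_threshold(self):
        """Inclusive comparison: the anchor hit passes its own cutoff."""
        hits = make_hits([("R1.1", 1e-50), ("R2.1", 1e-40)])
        refs = ReferenceSet(members={"RAF": ("R1.1", "R2.1")})
        thr = determine_threshold(hits, refs, "RAF")
        assert "R2" in genes_above_threshold(hits, thr)


class TestAssessCluster:
    def test_partial_cluster_ratio(self):
        g = group("OG1", "a", "b", "c", "d")
        a = assess_cluster(g, {"a", "b"}, set())
        assert a.cluster_type == PARTIAL
        assert a.completion_ratio == 0.5

    def test_singleton_above(self):
        a = assess_cluster(group("OG1", "a"), {"a"}, set())
        assert a.cluster_type == SINGLETON
        assert a.completion_ratio == 1.0

    def test_multivariant_singleton(self):
        """Multiple transcript variants of one gene still form a singleton."""
        g = Orthogroup(
            group_id="OG1", members=(("Sp", "a", "a.1"), ("Sp", "a", "a.2"))
        )
        assert assess_cluster(g, {"a"}, set()).cluster_type == SINGLETON

    def test_complete_and_absent(self):
        g = group("OG1", "a", "b", "c")
        assert assess_cluster(g, {"a", "b", "c"}, set()).cluster_type == COMPLETE
        assert assess_cluster(g, set(), set()).cluster_type == ABSENT

    def test_known_via_any_member(self):
        g = group("OG1", "a", "b")
        assert assess_cluster(g, {"a"}, {"b"}).is_known
        assert not assess_cluster(g, {"a"}, {"z"}).is_known


def _run_one(ctype, above, known, forced, has_hit=True):
    """Build the minimal cluster realizing one truth-table cell and decide."""
    focal = "focal"
    if ctype == "singleton":
        g = group("OG", focal)
        above_set = {focal} if above else set()
    elif ctype == "complete":
        g = group("OG", focal, "f1", "f2")
        above_set = {focal, "f1", "f2"}  # complete requires all above
    elif ctype == "partial_ge50":
        g = group("OG", focal, "f1", "f2", "f3")
        above_set = ({focal, "f1"} if above else {"f1", "f2"})  # ratio 0.5
    elif ctype == "partial_lt50":
        g = group("OG", focal, "f1", "f2", "f3")
        above_set = {focal} if above else {"f1"}  # ratio 0.25
    known_ids = {"f1"} if (known and ctype != "singleton") else (
        {focal} if known else set()
    )
    refs = ReferenceSet(
        members={"RAF": ("ref.1",)},
        force_include=frozenset({focal}) if forced else frozenset(),
    )
    hit_genes = set(g.member_genes) if has_hit else above_set
    assessment = assess_cluster(g, above_set, known_ids)
    decisions = decide([assessment], above_set, refs, "RAF", hit_genes=hit_genes)
    return next(d for d in decisions if d.gene_id == focal)


# hand-written oracle over every feasible combination of
# {above, below} x {known, unknown} x cluster type x {forced, not}
TRUTH_TABLE = []
for ctype in ("singleton", "complete", "partial_ge50", "partial_lt50"):
    for above in (True, False):
        if ctype == "complete" and not above:
            continue  # infeasible: complete means every member is above
        for known in (True, False):
            for forced in (True, False):
                if above:
                    if known:
                        expected = (KEEP, KNOWN_ABOVE)
                    elif ctype == "singleton":
                        expected = (KEEP, SINGLETON_ABOVE)
                    elif ctype in ("complete", "partial_ge50"):
                        expected = (KEEP, PARTIAL_GE50)
                    elif forced:
                        expected = (KEEP, FORCED)
                    else:
                        expected = (REJECT, PARTIAL_LT50)
                else:
                    expected = (KEEP, FORCED) if forced else (REJECT, BELOW_THRESHOLD)
                TRUTH_TABLE.append((ctype, above, known, forced, expected))


@pytest.mark.parametrize("ctype,above,known,forced,expected", TRUTH_TABLE)
def test_decision_table_matches_oracle(ctype, above, known, forced, expected):
    d = _run_one(ctype, above, known, forced)
    assert (d.verdict, d.reason_code) == expected


def test_no_hit_reason_code():
    d = _run_one("partial_lt50", above=False, known=False, forced=False,
                 has_hit=False)
    assert (d.verdict, d.reason_code) == (REJECT, NO_HIT)


def test_partial_keep_below_flag():
    g = group("OG", "a", "b", "c", "d")
    above = {"a", "b"}
    refs = ReferenceSet(members={"RAF": ("r.1",)})
    assessment = assess_cluster(g, above, set())
    kept = {
        d.gene_id
        for d in decide([assessment], above, refs, "RAF",
                        hit_genes=set(g.member_genes), partial_keep_below=True)
        if d.verdict == KEEP
    }
    assert kept == {"a", "b", "c", "d"}


class TestInvariants:
    def _scenario(self, completion_threshold=0.5, cutoff=1e-50):
        hits = make_hits(
            [
                ("r1.1", 1e-80),
                ("a.1", 1e-70),
                ("b.1", 1e-60),
                ("r2.1", cutoff),
                ("c.1", 1e-40),
                ("d.1", 1e-30),
            ]
        )
        groups = [group("OG1", "a", "b", "c"), group("OG2", "d", "r1", "r2")]
        refs = ReferenceSet(members={"RAF": ("r1.1", "r2.1")})
        result = classify_family(
            groups, {"RAF": hits}, refs,
            completion_threshold=completion_threshold,
        )
        return result

    def test_determinism(self):
        r1, r2 = self._scenario(), self._scenario()
        assert r1.decisions == r2.decisions
        assert r1.thresholds == r2.thresholds

    def test_raising_completion_threshold_never_adds_genes(self):
        kept_05 = set(self._scenario(0.5).kept_genes)
        kept_08 = set(self._scenario(0.8).kept_genes)
        assert kept_08 <= kept_05

    def test_soundness_kept_genes_are_above_threshold(self):
        result = self._scenario()
        thr = result.thresholds["RAF"]
        hits = make_hits([("r1.1", 1e-80), ("a.1", 1e-70), ("b.1", 1e-60),
                          ("r2.1", 1e-50), ("c.1", 1e-40), ("d.1", 1e-30)])
        above = genes_above_threshold(hits, thr)
        for d in result.decisions:
            if d.verdict == KEEP and d.reason_code != FORCED:
                assert d.gene_id in above


def test_end_to_end_recovery_on_clean_fixture(family_fixture):
    """With 10 orders of E-value separation and clean clusters, membership
    recovery is perfect."""
    result = classify_family(
        family_fixture.groups, family_fixture.hits, family_fixture.refs
    )
    kept = set(result.kept_genes)
    truth = set(family_fixture.truth.all_members)
    assert kept == truth  # precision = recall = 1.0
    # and every kept gene lands in its true subfamily
    for gene, sub in result.kept_genes.items():
        assert gene in family_fixture.truth.members[sub]


def test_contaminated_fixture_has_low_ratio_partial_clusters():
    from genefam.simulate import SimulationConfig, simulate_family

    fix = simulate_family(SimulationConfig(seed=5, cluster_contamination=0.3))
    result = classify_family(fix.groups, fix.hits, fix.refs)
    ratios = {
        d.completion_ratio
        for d in result.decisions
        if d.cluster_type == PARTIAL
    }
    assert any(r < 0.5 for r in ratios)


def test_summarize_by_species(family_fixture):
    result = classify_family(
        family_fixture.groups, family_fixture.hits, family_fixture.refs
    )
    species_of = family_fixture.truth.species_of_gene
    df = summarize_by_species(
        result.decisions, species_of, published_ids=family_fixture.truth.known
    )
    assert set(df.columns) == {"species", "subfamily", "published", "new", "total"}
    assert (df["published"] + df["new"] == df["total"]).all()
    total_kept = sum(
        1 for d in result.decisions if d.verdict == KEEP
    )
    assert df["total"].sum() == total_kept


def test_best_evalue_per_gene_collapses_variants():
    hits = make_hits([("g.1", 1e-50), ("g.2", 1e-60)])
    assert best_evalue_per_gene(hits) == {"g": 1e-60}
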