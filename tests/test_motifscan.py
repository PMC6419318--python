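import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import oracle_null_pmf_mitm, oracle_null_pmf_small
from genefam.motifscan import (
    AMINO_ACIDS,
    DEFAULT_MOTIFS,
    PatternError,
    compile_motif,
    exact_score_pvalues,
    motif_conservation_report,
    parse_pattern,
    scan_protein,
)


class TestPatternCompilation:
    def test_wildcard_column_is_background(self):
        m = compile_motif("x")
        assert np.allclose(m.pwm, 0.0)

    def test_alternation_log_odds(self):
        """(L/V/M) on uniform background, zero pseudocount: allowed residues
        score log2((1/3)/(1/20)) = log2(20/3); others hit the floor."""
        m = compile_motif("(L/V/M)")
        allowed = [AMINO_ACIDS.index(r) for r in "LVM"]
        assert np.allclose(m.pwm[0, allowed], np.log2(20 / 3))
        others = [i for i in range(20) if i not in allowed]
        assert (m.pwm[0, others] == -30.0).all()

    def test_raf_motif_length(self):
        assert len(compile_motif("GTxx(W/Y)MAPE")) == 9

    @pytest.mark.parametrize("bad", ["", "GT(Z)A", "(A/)", "gt", "G T"])
    def test_invalid_patterns_rejected(self, bad):
        with pytest.raises(PatternError):
            parse_pattern(bad)


class TestExactNull:
    def test_two_of_twenty_column(self):
        """One column allowing 2 residues: p-value of the max score = 2/20."""
        m = compile_motif("(W/Y)")
        null = exact_score_pvalues(m)
        assert null.pvalue_of_int(null.tail.size - 1) == pytest.approx(0.1)

    def test_all_wildcard_pvalue_one(self):
        null = exact_score_pvalues(compile_motif("xxx"))
        assert null.pvalue_of_int(0) == 1.0

    @pytest.mark.parametrize("pattern", ["GA", "(L/V)x", "G(T/S)A"])
    def test_dp_equals_enumeration_short_motifs(self, pattern):
        """DP null pmf equals full 20**L enumeration on the same integer grid."""
        m = compile_motif(pattern)
        null = exact_score_pvalues(m)
        pmf = oracle_null_pmf_small(null.column_ints, m.background)
        assert pmf.shape == null.pmf.shape
        # identical integer support; probabilities agree to summation round-off
        assert ((pmf > 0) == (null.pmf > 0)).all()
        assert np.abs(pmf - null.pmf).max() < 1e-12

    def test_dp_equals_enumeration_l6_nonuniform_background(self):
        rng = np.random.default_rng(42)
        bg = rng.dirichlet(np.full(20, 5.0))
        m = compile_motif("G(T/S)Px(F/Y)V", background=bg)
        null = exact_score_pvalues(m, granularity=1000)
        pmf = oracle_null_pmf_mitm(null.column_ints, m.background)
        tv = 0.5 * np.abs(pmf - null.pmf).sum()
        assert tv < 1e-12

    def test_pvalues_monotone_and_in_unit_interval(self):
        null = exact_score_pvalues(compile_motif(DEFAULT_MOTIFS["MEKK"]))
        tail = null.tail
        assert (tail > 0).all() and (tail <= 1).all()
        assert (np.diff(tail) <= 1e-15).all()
        assert null.pmf.sum() == pytest.approx(1.0, abs=1e-12)


class TestScanning:
    @pytest.mark.parametrize(
        "sub,consensus",
        [("ZIK", "GTPEFMAPELY"), ("MEKK", "GTPAFMAPEV"), ("RAF", "GTAAWMAPE")],
    )
    def test_consensus_sequence_hits_at_1e4(self, sub, consensus):
        m = compile_motif(DEFAULT_MOTIFS[sub], name=sub)
        seq = "A" * 30 + consensus + "A" * 30
        hit = scan_protein(m, "p", seq, pvalue_threshold=1e-4)
        assert hit is not None
        assert hit.window == consensus
        assert hit.offset == 31
        # a consensus window attains the model maximum
        assert hit.score == pytest.approx(m.max_score)

    def test_protein_shorter_than_motif(self):
        m = compile_motif(DEFAULT_MOTIFS["ZIK"])
        assert scan_protein(m, "p", "GTPEF") is None

    def test_window_count_position_covering(self):
        """The scan considers len - L + 1 windows: a consensus at the very
        last offset is still found."""
        m = compile_motif("GTAAWMAPE")
        seq = "K" * 40 + "GTAAWMAPE"
        hit = scan_protein(m, "p", seq, pvalue_threshold=1e-4)
        assert hit.offset == 41

    def test_random_proteins_rarely_hit(self):
        """Null behavior: random length-50 proteins essentially never pass
        1e-4 against the 11-column ZIK motif."""
        m = compile_motif(DEFAULT_MOTIFS["ZIK"])
        null = exact_score_pvalues(m)
        rng = np.random.default_rng(2024)
        n_hits = 0
        for _ in range(200):
            seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 50))
            if scan_protein(m, "p", seq, 1e-4, null=null) is not None:
                n_hits += 1
        assert n_hits <= 2  # >= 99% of seeds yield no hit

    def test_relaxed_threshold_admits_superset(self):
        """Hits at p < 1e-3 are a superset of hits at p < 1e-4."""
        m = compile_motif(DEFAULT_MOTIFS["RAF"])
        null = exact_score_pvalues(m)
        rng = np.random.default_rng(7)
        hits4, hits3 = set(), set()
        for i in range(300):
            seq = "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, 60))
            # plant partial motifs in some sequences to populate mid p-values
            if i % 3 == 0:
                seq = seq[:20] + "GTAAWMAPE"[: 5 + i % 5] + seq[25:]
            if scan_protein(m, str(i), seq, 1e-4, null=null):
                hits4.add(i)
            if scan_protein(m, str(i), seq, 1e-3, null=null):
                hits3.add(i)
        assert hits4 <= hits3
        assert len(hits3) > len(hits4)  # the relaxation admits new hits here

    def test_unknown_residue_scores_conservatively(self):
        m = compile_motif("GTAAWMAPE")
        consensus = "GTAAWMAPE"
        degraded = "GTAXWMAPE"
        assert m.score_window(degraded) < m.score_window(consensus)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_best_hit_pvalue_never_above_any_window(seed):
    """The reported hit is the minimum-p-value window of the protein."""
    m = compile_motif("G(T/S)xA")
    null = exact_score_pvalues(m)
    rng = np.random.default_rng(seed)
    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 30))
    hit = scan_protein(m, "p", seq, pvalue_threshold=1.1, null=null)
    assert hit is not None
    for off in range(len(seq) - len(m) + 1):
        window = seq[off : off + len(m)]
        idx = [AMINO_ACIDS.index(c) for c in window]
        p = null.pvalue_of_int(null.int_score(idx))
        assert hit.pvalue <= p


def test_conservation_report_on_planted_families(family_fixture):
    truth = family_fixture.truth
    gene_sub = {
        g: sub for sub, genes in truth.members.items() for g in genes
    }
    models = {
        sub: compile_motif(DEFAULT_MOTIFS[sub], name=sub)
        for sub in truth.members
    }
    seqs = {r.id: r.sequence for r in family_fixture.records}
    per_gene, summary = motif_conservation_report(seqs, gene_sub, models)
    assert len(per_gene) == len(gene_sub)
    # every planted member carries its subfamily motif
    assert per_gene["conserved_at_0.0001"].all()
    assert (
        summary.set_index("subfamily")["n_genes"].to_dict()
        == {s: len(g) for s, g in truth.members.items()}
    )
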