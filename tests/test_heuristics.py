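import io
import json
from importlib import resources

import pytest

from heurosplice.heuristics import (
    BaseCascade,
    RuleTableError,
    cascade_compare,
    classify_all_sites,
    classify_indel,
    classify_snv,
    creates_dinucleotide,
    default_rule_table,
    load_rule_table,
    route,
)
from heurosplice.synthetic import (
    enumerate_window_snvs,
    mirror_fixture,
    mirror_variant,
)
from heurosplice.transcript_model import RelativePosition, VariantRecord
from conftest import make_variant


@pytest.fixture(scope="module")
def table():
    return default_rule_table()


class TestRouting:
    def test_plus5_routes_to_dd4_dd6(self, table):
        assert route(RelativePosition.parse("+5"), table) == ["DD4", "DD6"]

    def test_plus1_routes_gc_vs_gt(self, table):
        ids = route(RelativePosition.parse("+1"), table)
        assert ids[:2] == ["DD1", "DD2"]

    def test_mid_exon_not_covered(self, table):
        assert route(RelativePosition.parse("E+50"), table) == []

    def test_deep_intronic_empty(self, table):
        assert route(RelativePosition.parse("+200"), table) == []
        assert route(RelativePosition.parse("-51"), table) == []

    def test_acceptor_positions_route(self, table):
        assert route(RelativePosition.parse("-1"), table) == ["DA2"]
        assert "DA9" in route(RelativePosition.parse("-15"), table)
        assert "DA1" in route(RelativePosition.parse("-10"), table)


class TestCascades:
    def test_e_minus1_a_to_t_less_preferred(self, table):
        cascade = table.cascades["E_minus_1"]
        assert cascade_compare("A", "T", cascade) == "less_preferred"

    def test_plus3_c_t_equal(self, table):
        assert cascade_compare("C", "T", table.cascades["plus_3"]) == "equal"
        assert cascade_compare("T", "C", table.cascades["plus_3"]) == "equal"

    def test_e_plus1_a_c_equal(self, table):
        assert cascade_compare("A", "C", table.cascades["E_plus_1"]) == "equal"

    def test_n_indeterminate(self, table):
        assert cascade_compare("N", "A", table.cascades["plus_3"]) is None

    def test_cascade_must_cover_acgt(self):
        with pytest.raises(ValueError):
            BaseCascade("bad", (frozenset("AG"),))


class TestCreatesDinucleotide:
    def test_snv_creates_ag(self):
        #            -10 C>A with G at -9
        ref = "TTTCGTTTT"
        alt = "TTTAGTTTT"
        assert creates_dinucleotide(ref, alt, "AG") == [3]

    def test_plus3_a_to_g_with_t_at_4_creates_gt(self):
        ref = "GTATGT"
        alt = "GTGTGT"
        assert 2 in creates_dinucleotide(ref, alt, "GT")

    def test_destroying_without_creating_is_empty(self):
        assert creates_dinucleotide("TTAGTT", "TTATTT", "AG") == []


class TestNarratedRegressions:
    """Every subgroup narrated in the text, as deterministic fixtures."""

    CASES = [
        # (intron/exon anchor, relpos, sense alt, rule, subgroup, p)
        ("plus1_gt", 0, "+1", "A", "DD2", "standard", 99.9),
        ("plus2_gt", 0, "+2", "C", "DD2", "standard", 99.9),
        ("gc_donor_std", 4, "+1", "A", "DD1", "standard", 100.0),
        ("gc_donor_ctx_gt", 4, "+2", "T", "DD1", "context", 81.2),
        ("plus5_e1_not_g", 1, "+5", "A", "DD4", "standard", 99.7),
        ("plus5_e1_g", 0, "+5", "A", "DD6", "standard", 95.1),
        ("plus5_ref_not_g", 3, "+5", "C", "DD6", "auxiliary", 28.6),
        ("eminus1_less", 2, "E-1", "T", "DD7", "standard", 94.0),
        ("eminus1_more", 2, "E-1", "G", "DD7", "auxiliary", 25.0),
        ("plus4_creates_cc", 2, "+4", "C", "DD5", "standard", 95.4),
        ("plus3_less", 1, "+3", "C", "DD8", "standard", 93.6),
        ("plus3_more", 2, "+3", "A", "DD8", "auxiliary", 25.0),
        ("acceptor_ag", 0, "-1", "C", "DA2", "standard", 99.7),
        ("acceptor_ag2", 0, "-2", "C", "DA2", "standard", 99.7),
        ("agez_creation", 0, "-10", "A", "DA1", "standard", 97.7),
        ("upstream_ag_bp_ctx", 0, "-17", "G", "DA1", "context", 78.0),
        ("upstream_ag_no_bp", 3, "-19", "G", "DA1", "auxiliary", 28.0),
        ("eplus1_y_at_minus3", 0, "E+1", "T", "DA6", "standard", 66.7),
        ("eplus1_r_at_minus3", 2, "E+1", "T", "DA3", "standard", 99.2),
        ("ppt_strong", 1, "-15", "G", "DA9", "context", 3.3),
        ("ppt_standard", 2, "-20", "A", "DA9", "standard", 25.4),
        ("ppt_introduces_t", 2, "-19", "T", "DA9", "auxiliary", 4.6),
    ]

    @pytest.mark.parametrize(
        "name,intron,relpos,alt,rule,subgroup,p",
        CASES, ids=[c[0] for c in CASES])
    def test_narrated_subgroup(self, genome, transcript, name, intron,
                               relpos, alt, rule, subgroup, p):
        var = make_variant(transcript, genome, intron, relpos, alt)
        a = classify_snv(var, transcript, genome)
        assert (a.rule_id, a.subgroup) == (rule, subgroup), a.trace
        assert a.annotation.p == p
        assert a.annotation.text_verified
        assert a.trace  # non-empty trace for every match

    @pytest.mark.parametrize(
        "name,intron,relpos,alt,rule,subgroup,p",
        CASES, ids=[c[0] for c in CASES])
    def test_strand_equivalence(self, genome, transcript, name, intron,
                                relpos, alt, rule, subgroup, p):
        var = make_variant(transcript, genome, intron, relpos, alt)
        mg, mtx = mirror_fixture(genome, transcript)
        mvar = mirror_variant(var, len(genome[transcript.chrom]))
        a = classify_snv(var, transcript, genome)
        b = classify_snv(mvar, mtx, mg)
        assert (a.rule_id, a.subgroup) == (b.rule_id, b.subgroup)
        assert a.relative_position == b.relative_position


class TestClassifyFlags:
    def test_deep_intronic_flag(self, genome, transcript):
        var = make_variant(transcript, genome, 0, "+30", "A")
        a = classify_snv(var, transcript, genome)
        assert not a.assigned
        assert "deep_intronic" in a.flags and "pseudoexon_pathway" in a.flags

    def test_mid_exon_sre_flag(self, genome, transcript):
        var = make_variant(transcript, genome, 0, "E+40", "A")
        a = classify_snv(var, transcript, genome)
        assert "SRE_not_covered" in a.flags

    def test_intergenic_flag(self, genome, transcript):
        var = VariantRecord("chrD", 5, genome["chrD"][4], "A")
        a = classify_snv(var, transcript, genome)
        assert "intergenic" in a.flags

    def test_u12_unsupported(self, genome, transcript):
        import dataclasses
        u12tx = dataclasses.replace(
            transcript,
            intron_classes=("U12",) + ("U2",) * (transcript.n_introns - 1))
        var = make_variant(transcript, genome, 0, "+1", "A")
        a = classify_snv(var, u12tx, genome)
        assert not a.assigned and "U12_unsupported" in a.flags

    def test_figure_estimate_rules_are_flagged(self, genome, transcript):
        var = make_variant(transcript, genome, 0, "E-2", "A")
        a = classify_snv(var, transcript, genome)
        assert a.rule_id == "DD3"
        assert "annotation_is_estimate" in a.flags
        assert not a.annotation.text_verified

    def test_ref_mismatch_names_position(self, genome, transcript):
        from heurosplice.transcript_model import RefMismatchError
        g0 = transcript.intron_interval(0)[0]
        wrong_ref = "A" if genome["chrD"][g0] != "A" else "C"
        var = VariantRecord("chrD", g0 + 1, wrong_ref, "T")
        with pytest.raises(RefMismatchError, match=str(g0 + 1)):
            classify_snv(var, transcript, genome)

    def test_determinism(self, genome, transcript):
        var = make_variant(transcript, genome, 0, "+5", "A")
        a = classify_snv(var, transcript, genome)
        b = classify_snv(var, transcript, genome)
        assert a.trace == b.trace
        assert (a.rule_id, a.subgroup) == (b.rule_id, b.subgroup)


class TestExhaustiveness:
    def test_every_window_snv_is_assigned_or_flagged(self, genome,
                                                     transcript):
        for var in enumerate_window_snvs(transcript, genome):
            a = classify_snv(var, transcript, genome)
            assert a.assigned or a.flags, (var, a)

    def test_every_assignment_has_annotation_and_trace(self, genome,
                                                       transcript):
        for var in enumerate_window_snvs(transcript, genome):
            a = classify_snv(var, transcript, genome)
            if a.assigned:
                assert a.annotation is not None
                assert len(a.trace) >= 1


class TestIndels:
    def test_gt_deletion_summary_is_dd2(self, genome, transcript):
        g0 = transcript.intron_interval(0)[0]
        ref = genome["chrD"][g0 - 1:g0 + 2]
        var = VariantRecord("chrD", g0, ref, ref[0])  # deletes +1..+2 GT
        matches, summary = classify_indel(var, transcript, genome)
        assert (summary.rule_id, summary.subgroup) == ("DD2", "standard")
        assert summary.annotation.p == 99.9
        assert any(m.rule_id == "DD2" for m in matches)

    def test_summary_is_max_spliceogenicity(self, genome, transcript):
        # delete E-1..+2: DD7 (E-1) and DD2 (+1/+2) both match; DD2 wins
        g0 = transcript.intron_interval(0)[0]
        ref = genome["chrD"][g0 - 2:g0 + 2]
        var = VariantRecord("chrD", g0 - 1, ref, ref[0])
        matches, summary = classify_indel(var, transcript, genome)
        rules = {m.rule_id for m in matches if m.assigned}
        assert {"DD2", "DD7"} <= rules
        assert summary.annotation.p == max(
            m.annotation.p for m in matches if m.assigned)

    def test_insertion_creating_ag_matches_da1(self, genome, transcript):
        # insert "AG" between -9 and -8 of intron 4's AG-free acceptor
        rel = RelativePosition.parse("-9")
        g0 = transcript.rel_to_genomic(rel, intron_index=3)
        base = genome["chrD"][g0]
        var = VariantRecord("chrD", g0 + 1, base, base + "AG")
        matches, summary = classify_indel(var, transcript, genome)
        assert any(m.rule_id == "DA1" and m.subgroup == "standard"
                   for m in matches if m.assigned)

    def test_whole_exon_deletion_not_covered(self, genome, transcript):
        s, e = transcript.exons[1]
        ref = genome["chrD"][s - 1:e]
        var = VariantRecord("chrD", s, ref, ref[0])
        matches, summary = classify_indel(var, transcript, genome)
        assert not summary.assigned
        assert "not_covered" in summary.flags

    def test_snv_rejected(self, genome, transcript):
        var = make_variant(transcript, genome, 0, "+1", "A")
        with pytest.raises(ValueError):
            classify_indel(var, transcript, genome)


class TestShortExonBothSites:
    def test_both_site_classes_reported(self):
        # a 3 nt internal exon: E+1 is also E-3
        flank = "T" * 60
        acc = ("TC" * 13) + "TGA" + "TCTTC" + "T" * 16 + "TCAG"
        acc = acc[-50:] if len(acc) >= 50 else acc
        intron1 = "GTAAGT" + "C" * 20 + ("TCTCTCTCTCTCTCTCTC" + "TGA"
                                         + "TCTTC" + "T" * 11 + "TTCCTTTCC"
                                         + "TCAG")
        intron2 = "GTAAGT" + "C" * 64 + ("TCTCTCTCTCTCTCTCTC" + "TGA"
                                         + "TCTTC" + "T" * 11 + "TTCCTTTCC"
                                         + "TCAG")
        exon_mid = "GAG"
        seq = flank + "ATGCAG" + intron1 + exon_mid + intron2 + "G" * 40 + flank
        s1 = len(flank)
        e1 = s1 + 6
        s2 = e1 + len(intron1)
        e2 = s2 + 3
        s3 = e2 + len(intron2)
        from heurosplice.transcript_model import TranscriptModel
        tx = TranscriptModel("SHORT1", "G", "c", "+",
                             ((s1, e1), (s2, e2), (s3, s3 + 40)))
        genome = {"c": seq}
        var = VariantRecord("c", s2 + 1, "G", "T")  # E+1 == E-3
        assignments = classify_all_sites(var, tx, genome)
        classes = {a.site_class for a in assignments}
        assert classes == {"donor", "acceptor"}


class TestLoadRuleTable:
    def _raw(self):
        path = resources.files("heurosplice.data") / "rules.json"
        with path.open() as fh:
            return json.load(fh)

    def test_bundled_table_has_twelve_dd_rules(self, table):
        dd = {r.rule_id for r in table.rules if r.rule_id.startswith("DD")}
        assert len(dd) == 12
        da = {r.rule_id for r in table.rules if r.rule_id.startswith("DA")}
        assert len(da) == 9

    def test_annotation_under_10_rejected(self):
        raw = self._raw()
        raw["annotations"]["DD2:standard"]["n"] = 9
        with pytest.raises(RuleTableError, match="at least 10"):
            load_rule_table(io.StringIO(json.dumps(raw)))

    def test_unknown_predicate_rejected(self):
        raw = self._raw()
        raw["rules"][0]["branches"][0]["predicates"].append(
            {"op": "definitely_not_real"})
        with pytest.raises(RuleTableError, match="unknown predicate"):
            load_rule_table(io.StringIO(json.dumps(raw)))

    def test_undeclared_context_position_rejected(self):
        raw = self._raw()
        for rule in raw["rules"]:
            if rule["rule_id"] == "DD4":
                rule["branches"][0]["predicates"].append(
                    {"op": "context_base", "pos": "-40", "bases": ["A"]})
        with pytest.raises(RuleTableError, match="undeclared"):
            load_rule_table(io.StringIO(json.dumps(raw)))

    def test_missing_annotation_rejected(self):
        raw = self._raw()
        del raw["annotations"]["DD2:standard"]
        with pytest.raises(RuleTableError, match="no annotation"):
            load_rule_table(io.StringIO(json.dumps(raw)))

    def test_paper_values_bundled_verbatim(self, table):
        ann = table.annotation("DD2", "standard")
        assert (ann.p, tuple(ann.ci), ann.n) == (99.9, (98.1, 100.0), 2218)
        ann = table.annotation("DA2", "standard")
        assert (ann.p, tuple(ann.ci), ann.n) == (99.7, (98.1, 100.0), 2817)
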