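import dataclasses

import pytest

from heurosplice.checklist import (
    ChecklistConfig,
    ExonContext,
    check_agez,
    count_ppt,
    evaluate_checklist,
    exon_context_from_transcript,
    find_branchpoints,
    theoretical_intron_minimum,
)

CONFIG = ChecklistConfig()


def acceptor_region(ppt: str = "T" * 20, tail: str = "TCAG",
                    head: str = None) -> str:
    """-50..-1 region: 26 head + 20 PPT (-24..-5) + 4 tail (-4..-1)."""
    head = head if head is not None else "TCTCTCTCTCTCTCTCTC" + "TGA" + "TCTTC"
    region = head + ppt + tail
    assert len(region) == 50
    return region


def compliant_context(**overrides) -> ExonContext:
    fields = dict(
        exon_category="internal",
        exon_length=100,
        acceptor_intronic=acceptor_region(),
        acceptor_exonic="G" + "C" * 49,
        donor_exonic="C" * 47 + "CAG",
        donor_intronic="GTAAGT" + "C" * 44,
        upstream_intron_length=150,
        downstream_intron_length=150,
    )
    fields.update(overrides)
    return ExonContext(**fields)


class TestCountPpt:
    def test_exactly_nine_pyrimidines_passes_minimum(self):
        ppt = "TCTCTTCTC" + "A" * 11  # 9 pyrimidines in -24..-5
        # place the pyrimidines at the -24 end; -5..-4 purine tail
        region = acceptor_region(ppt=ppt, tail="ACAG")
        counts = count_ppt(region, CONFIG)
        assert counts["pyrimidines_in_window"] == 9
        assert counts["passes_minimum"]

    def test_eight_pyrimidines_fails_minimum(self):
        ppt = "TCTCTTCT" + "A" * 12
        counts = count_ppt(acceptor_region(ppt=ppt, tail="ACAG"), CONFIG)
        assert counts["pyrimidines_in_window"] == 8
        assert not counts["passes_minimum"]

    def test_twelve_consecutive_is_strong(self):
        ppt = "T" * 12 + "A" * 8
        counts = count_ppt(acceptor_region(ppt=ppt, tail="ACAG"), CONFIG)
        assert counts["max_consecutive"] == 12
        assert counts["total_in_strength_window"] == 12
        assert counts["is_strong"]

    def test_seventeen_scattered_is_strong(self):
        # 17 pyrimidines in -24..-4 with runs broken by purines (max run 5)
        ppt = "TCTA" + "CTTA" + "TCTA" + "CTTA" + "TCTA"  # -24..-5: 15 pyr
        # strength window -24..-4 adds the T at -4: 16 -> not strong yet
        counts = count_ppt(acceptor_region(ppt=ppt, tail="TCAG"), CONFIG)
        assert not counts["is_strong"]
        ppt = "TCTA" + "CTTA" + "TCTA" + "CTTA" + "TCTC"  # 16 pyr in -24..-5
        counts = count_ppt(acceptor_region(ppt=ppt, tail="TCAG"), CONFIG)
        assert counts["total_in_strength_window"] == 17
        assert counts["max_consecutive"] < 12
        assert counts["is_strong"]

    def test_windows_keep_off_by_one_distinction(self):
        # pyrimidine at -4 counts for strength but not the minimum
        ppt = "A" * 20
        counts = count_ppt(acceptor_region(ppt=ppt, tail="TCAG"), CONFIG)
        assert counts["pyrimidines_in_window"] == 0
        assert counts["total_in_strength_window"] == 1


class TestFindBranchpoints:
    def test_tna_candidate_at_minus_25(self):
        head = "T" * 23 + "TGA"  # A at -25, T at -27
        region = head + "T" * 20 + "TCAG"
        cands = find_branchpoints(region, CONFIG)
        assert [c.distance for c in cands] == [25]
        assert cands[0].motif_window == "TGA"
        assert str(cands[0].position) == "-25"

    def test_distance_below_17_rejected(self):
        # TTA with the A at -10
        region = "T" * 38 + "TTA" + "T" * 5 + "TCAG"
        assert region[50 - 10] == "A"
        assert find_branchpoints(region, CONFIG) == []

    def test_a_at_minus_50_accepted_minus_51_rejected(self):
        # 52 nt region so the -50 candidate keeps its 2 nt motif context
        region = "TTA" + "T" * 45 + "TCAG"
        assert len(region) == 52 and region[2] == "A"  # A at -50
        cands = find_branchpoints(region, CONFIG)
        assert 50 in [c.distance for c in cands]
        # one base further upstream (-51) falls outside the window
        shifted = "TAT" + "T" * 45 + "TCAG"
        assert len(shifted) == 52 and shifted[1] == "A"  # A at -51
        cands = find_branchpoints(shifted, CONFIG)
        assert all(c.distance <= 50 for c in cands)
        assert 51 not in [c.distance for c in cands]

    def test_yna_motif_widens_matches(self):
        head = "T" * 23 + "CCA"  # CNA: YNA yes, TNA no
        region = head + "T" * 20 + "TCAG"
        assert find_branchpoints(region, CONFIG) == []
        assert [c.distance for c in
                find_branchpoints(region, CONFIG, motif="YNA")] == [25]


class TestCheckAgez:
    def test_ag_at_minus5_tolerated(self):
        # ...AGYAG|G: AG with its A at -5
        region = acceptor_region(ppt="T" * 19 + "A", tail="GCAG")
        result = check_agez(region, CONFIG)
        assert result["pass"] and result["violating_AG_positions"] == []

    def test_ag_at_minus8_violates(self):
        ppt = "T" * 16 + "AGTT"  # A at -8, G at -7
        result = check_agez(acceptor_region(ppt=ppt), CONFIG)
        assert not result["pass"]
        assert result["violating_AG_positions"] == [-8]

    def test_no_ag_passes_with_empty_list(self):
        result = check_agez(acceptor_region(), CONFIG)
        assert result["pass"] and result["violating_AG_positions"] == []


class TestTheoreticalMinimum:
    def test_absolute_minimum_is_62(self):
        assert theoretical_intron_minimum(CONFIG)["absolute_min_nt"] == 62

    def test_low_risk_minimum_is_77(self):
        assert theoretical_intron_minimum(CONFIG)["low_risk_min_nt"] == 77

    def test_additivity_when_bp_window_raised(self):
        cfg = dataclasses.replace(CONFIG, bp_window_nt=(20, 50))
        assert theoretical_intron_minimum(cfg)["absolute_min_nt"] == 65


class TestEvaluateChecklist:
    def test_compliant_exon_passes(self):
        result = evaluate_checklist(compliant_context(), CONFIG)
        assert result.passed, result.failed_items()

    def test_intron_shortened_to_79_fails_at_80_passes(self):
        r79 = evaluate_checklist(
            compliant_context(upstream_intron_length=79), CONFIG)
        assert r79.items["intron_length_upstream"].status == "fail"
        assert not r79.passed
        r80 = evaluate_checklist(
            compliant_context(upstream_intron_length=80), CONFIG)
        assert r80.passed

    def test_last_exon_length_boundary_119(self):
        ctx118 = compliant_context(exon_category="last", exon_length=118,
                                   donor_exonic=None, donor_intronic=None,
                                   downstream_intron_length=None)
        assert not evaluate_checklist(ctx118, CONFIG).passed
        ctx119 = dataclasses.replace(ctx118, exon_length=119)
        assert evaluate_checklist(ctx119, CONFIG).passed

    @pytest.mark.parametrize("category,minimum", [("first", 30),
                                                  ("internal", 31)])
    def test_other_exon_minima(self, category, minimum):
        kw = dict(exon_category=category, exon_length=minimum)
        if category == "first":
            kw.update(acceptor_intronic=None, acceptor_exonic=None,
                      upstream_intron_length=None)
        assert evaluate_checklist(compliant_context(**kw), CONFIG).passed
        kw["exon_length"] = minimum - 1
        assert not evaluate_checklist(compliant_context(**kw), CONFIG).passed

    def test_missing_branchpoint_is_indeterminate_not_fail(self):
        # head with no A at all -> no branchpoint candidates
        head = "TC" * 13
        ctx = compliant_context(acceptor_intronic=acceptor_region(head=head))
        result = evaluate_checklist(ctx, CONFIG)
        assert result.items["branchpoint"].status == "indeterminate"
        assert result.passed  # indeterminate branchpoint does not gate

    def test_non_canonical_donor_fails(self):
        ctx = compliant_context(donor_intronic="ATAAGT" + "C" * 44)
        result = evaluate_checklist(ctx, CONFIG)
        assert result.items["donor_motif"].status == "fail"

    def test_gc_donor_accepted_with_consensus_context(self):
        ctx = compliant_context(donor_intronic="GCAAGT" + "C" * 44)
        result = evaluate_checklist(ctx, CONFIG)
        # CAG|GCAAGT matches the GC consensus at 8 of 9 positions
        assert result.items["donor_motif"].status == "pass"
        assert result.gc_donor

    def test_n_bases_never_pass(self):
        ctx = compliant_context(
            acceptor_intronic=acceptor_region(ppt="N" * 20))
        result = evaluate_checklist(ctx, CONFIG)
        assert result.items["ppt"].status == "indeterminate"
        assert result.overall == "indeterminate"

    def test_first_exon_skips_acceptor_side(self):
        ctx = compliant_context(exon_category="first", exon_length=60,
                                acceptor_intronic=None, acceptor_exonic=None,
                                upstream_intron_length=None)
        result = evaluate_checklist(ctx, CONFIG)
        assert result.items["acceptor_motif"].status == "skipped"
        assert result.passed

    def test_in_silico_mode_warns_on_placeholder_thresholds(self):
        with pytest.warns(UserWarning, match="placeholder"):
            result = evaluate_checklist(compliant_context(), CONFIG,
                                        mode="in_silico")
        assert result.mode == "in_silico"
        assert "bits" in result.items["donor_motif"].measured

    def test_modes_agree_on_motif_extremes(self):
        import warnings
        good = compliant_context()
        bad = compliant_context(donor_intronic="ATAAGT" + "C" * 44)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert evaluate_checklist(good, mode="manual").passed
            assert evaluate_checklist(good, mode="in_silico").passed
            assert not evaluate_checklist(bad, mode="manual").passed
            assert not evaluate_checklist(bad, mode="in_silico").passed

    def test_tightening_thresholds_is_monotone(self):
        ctx = compliant_context()
        base = evaluate_checklist(ctx, CONFIG)
        tighter = dataclasses.replace(
            CONFIG, min_intron_nt=200, ppt_min_pyrimidines=25,
            min_exon_nt={"first": 30, "internal": 200, "last": 119})
        tightened = evaluate_checklist(ctx, tighter)
        for item, verdict in tightened.items.items():
            if verdict.status == "pass":
                assert base.items[item].status == "pass"

    def test_checklist_on_sampled_exons(self, sampled_data):
        n_pass = n_total = 0
        for tx in sampled_data.transcripts:
            for i in range(tx.n_exons):
                ctx = exon_context_from_transcript(
                    tx, i, sampled_data.genome)
                n_total += 1
                if evaluate_checklist(ctx, CONFIG).passed:
                    n_pass += 1
        assert n_pass / n_total >= 0.95

    def test_degenerate_generator_produces_failures(self):
        from heurosplice.synthetic import GeneratorConfig, generate_genome
        data = generate_genome(GeneratorConfig(seed=3, n_transcripts=3,
                                               degenerate=True))
        results = []
        for tx in data.transcripts:
            for i in range(tx.n_exons):
                ctx = exon_context_from_transcript(tx, i, data.genome)
                results.append(evaluate_checklist(ctx, CONFIG).passed)
        assert not all(results)

    def test_forced_short_introns_fail_intron_length(self):
        ctx = compliant_context(upstream_intron_length=70,
                                downstream_intron_length=70)
        result = evaluate_checklist(ctx, CONFIG)
        assert result.items["intron_length_upstream"].status == "fail"
        assert result.items["intron_length_downstream"].status == "fail"
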