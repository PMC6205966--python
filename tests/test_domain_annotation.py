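"""Domain detection, active-site grading, activity calls and TM prediction."""

import random

import pytest

from panscan.domain_annotation import (
    classify_activity,
    extract_active_site,
    predict_tm,
    scan_domains,
)
from panscan.seqsim import rand_protein


def _annotate(seq, domains, **kw):
    hits = scan_domains(seq, domains, **kw)
    sites = [extract_active_site(seq, h) for h in hits]
    return hits, sites


class TestScanDomains:
    def test_self_scan_identity_100_and_intact(self, domains):
        for ref in domains:
            hits, sites = _annotate(ref.sequence, domains)
            mine = [h for h in hits if h.domain == ref.name]
            assert len(mine) == 1
            assert mine[0].alignment.identity_pct == 100.0
            site = sites[hits.index(mine[0])]
            assert site.grade == "intact"

    def test_embedded_exact_domain_found(self, domain_by_name, domains):
        ggdef = domain_by_name["GGDEF"]
        protein = rand_protein(40, 1) + ggdef.sequence + rand_protein(40, 2)
        hits = scan_domains(protein, [ggdef])
        assert len(hits) == 1
        assert hits[0].alignment.identity_pct == 100.0
        assert hits[0].query_span == (40, 40 + len(ggdef.sequence))

    def test_degenerate_domain_still_located(self, domains, ref_proteins):
        # the cdgC-type fixture has an intact GGDEF plus a degenerate EAL
        hits, sites = _annotate(ref_proteins["cdgC"].sequence, domains)
        kinds = {h.domain for h in hits}
        assert kinds == {"GGDEF", "EAL"}
        grades = {s.domain: s.grade for s in sites}
        assert grades == {"GGDEF": "intact", "EAL": "degenerate"}

    def test_shuffled_sequences_are_null(self, domains):
        ggdef = domains[0]
        rng = random.Random(4)
        n_hits = 0
        for _ in range(20):
            shuffled = list(ggdef.sequence)
            rng.shuffle(shuffled)
            n_hits += bool(scan_domains("".join(shuffled), domains))
        assert n_hits <= 1  # at most 1 of 20 shuffles may scrape through

    def test_hit_count_monotone_in_min_identity(self, domains, ref_proteins):
        seq = ref_proteins["cdgC"].sequence
        counts = [len(scan_domains(seq, domains, min_identity=t))
                  for t in (30, 50, 70, 90)]
        assert counts == sorted(counts, reverse=True)


class TestActiveSite:
    @pytest.mark.parametrize(
        "motif, grade",
        [
            ("GGDEF", "intact"),
            ("GGEEF", "intact"),
            ("GGDDF", "atypical"),    # one mismatch from GG[DE]EF
            ("ALLEF", "degenerate"),  # the engineered triple substitution
            ("AADEF", "degenerate"),
        ],
    )
    def test_ggdef_asite_grades(self, domain_by_name, motif, grade):
        ref = domain_by_name["GGDEF"]
        seq = list(ref.sequence)
        seq[ref.asite_span[0]:ref.asite_span[1]] = motif
        seq = "".join(seq)
        hits = scan_domains(seq, [ref])
        site = extract_active_site(seq, hits[0])
        assert site.asite_motif == motif
        assert site.grade == grade

    def test_isite_motif_reported(self, domain_by_name):
        ref = domain_by_name["GGDEF"]
        hits = scan_domains(ref.sequence, [ref])
        site = extract_active_site(ref.sequence, hits[0])
        assert site.isite_motif is not None
        assert site.isite_motif[0] == "R" and site.isite_motif[3] == "D"

    def test_uncovered_asite_grades_degenerate_with_x(self, domain_by_name):
        ref = domain_by_name["GGDEF"]
        # keep only the N-terminal part: the A-site columns are never aligned
        seq = ref.sequence[:100]
        hits = scan_domains(seq, [ref], min_identity=30, min_coverage=40)
        assert hits
        site = extract_active_site(seq, hits[0])
        assert site.grade == "degenerate"
        assert site.asite_motif == "X" * 5

    def test_eal_missing_key_glutamate_not_intact(self, domain_by_name):
        ref = domain_by_name["EAL"]
        seq = list(ref.sequence)
        seq[ref.key_glutamate] = "A"
        seq = "".join(seq)
        hits = scan_domains(seq, [ref])
        site = extract_active_site(seq, hits[0])
        assert site.grade == "degenerate"

    def test_hdgyp_missing_gyp_degenerate(self, domain_by_name):
        ref = domain_by_name["HD-GYP"]
        seq = list(ref.sequence)
        seq[ref.asite_span[0]:ref.asite_span[1]] = "ASR"
        seq = "".join(seq)
        hits = scan_domains(seq, [ref])
        site = extract_active_site(seq, hits[0])
        assert site.grade == "degenerate"


class TestClassifyActivity:
    def _call(self, seq, domains):
        hits, sites = _annotate(seq, domains)
        return classify_activity(hits, sites, predict_tm(seq))

    def test_table_fixture_classes(self, domains, ref_proteins):
        expected = {name: p.expected_class for name, p in ref_proteins.items()}
        got = {name: self._call(p.sequence, domains).protein_class
               for name, p in ref_proteins.items()}
        assert got == expected

    def test_activity_labels(self, domains, ref_proteins):
        labels = {name: self._call(p.sequence, domains).activity_label
                  for name, p in ref_proteins.items()}
        assert labels["cdgF"] == "DGC/PDE"
        assert labels["hdgB"] == "none"
        assert labels["bldD"] == "none"
        assert labels["rmdA"] == labels["rmdB"] == "PDE"

    def test_order_invariance(self, domains, ref_proteins):
        seq = ref_proteins["cdgF"].sequence
        hits, sites = _annotate(seq, domains)
        fwd = classify_activity(hits, sites)
        rev = classify_activity(hits[::-1], sites[::-1])
        assert fwd == rev

    def test_no_hits_is_none(self):
        call = classify_activity([], [])
        assert call.protein_class == "none"
        assert call.architecture_string == "none"

    def test_planted_allef_flips_dgc_but_domain_remains(self, domains,
                                                        ref_proteins):
        cdgd = ref_proteins["cdgD"]
        dom = cdgd.domains[0]
        seq = list(cdgd.sequence)
        seq[dom.asite_span[0]:dom.asite_span[1]] = "ALLEF"
        seq = "".join(seq)
        before = self._call(cdgd.sequence, domains)
        after = self._call(seq, domains)
        assert before.protein_class == "DGC"
        assert after.protein_class != "DGC"
        assert any(h.domain == "GGDEF" for h in scan_domains(seq, domains))

    def test_architecture_rendering(self, domains, ref_proteins):
        call = self._call(ref_proteins["cdgC"].sequence, domains)
        assert call.architecture_string == "10TM-GGDEF-degEAL"
        call = self._call(ref_proteins["hdgB"].sequence, domains)
        assert call.architecture_string == "6TM-degHD-GYP"


class TestPredictTM:
    def test_hydrophilic_protein_has_no_segments(self):
        tm = predict_tm("S" * 200)
        assert tm.count == 0 and not tm.membrane_bound

    def test_single_embedded_helix(self):
        seq = "S" * 80 + "L" * 25 + "S" * 80
        tm = predict_tm(seq)
        assert tm.count == 1 and tm.membrane_bound

    def test_two_separated_helices(self):
        seq = "S" * 50 + "L" * 25 + "S" * 40 + "L" * 25 + "S" * 50
        assert predict_tm(seq).count == 2

    def test_case_invariance(self):
        seq = "S" * 50 + "L" * 25 + "S" * 50
        assert predict_tm(seq) == predict_tm(seq.lower())

    def test_short_protein_no_output(self):
        assert predict_tm("MKT").count == 0
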