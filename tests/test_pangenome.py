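"""Ortholog assignment, BBH, borderline validation, clustering, categories."""

import pytest

from panscan.align import align_pair, score_pair
from panscan.pangenome import (
    OrthologAssignment,
    PangenomeConfig,
    assign_ortholog,
    bbh,
    build_presence_absence,
    classify_conservation,
    cluster_unassigned,
    validate_borderline,
)
from panscan.seqsim import mutate_to_identity, rand_protein

CFG = PangenomeConfig()


def _derive(seq, identity, seed):
    """Diverged copy whose measured semiglobal identity is verified."""
    out = mutate_to_identity(seq, identity, 0.0, seed)
    got = align_pair(out, seq, mode="semiglobal").identity_pct
    assert abs(got - 100 * identity) < 3
    return out


class TestAssignOrtholog:
    def test_identical_query_assigned_at_100(self, ref_proteins):
        refs = {n: p.sequence for n, p in ref_proteins.items() if n != "pcdgG"}
        name, idp, cov = assign_ortholog(ref_proteins["cdgD"].sequence, refs)
        assert name == "cdgD" and idp == 100.0 and cov == 100.0

    def test_61_percent_query_assigned(self, ref_proteins):
        refs = {"cdgD": ref_proteins["cdgD"].sequence}
        q = _derive(refs["cdgD"], 0.61, 21)
        hit = assign_ortholog(q, refs)
        assert hit is not None and hit[0] == "cdgD"

    @pytest.mark.parametrize("identity", [0.44, 0.43])
    def test_below_cutoff_not_assigned(self, ref_proteins, identity):
        refs = {"cdgD": ref_proteins["cdgD"].sequence,
                "cdgF": ref_proteins["cdgF"].sequence}
        q = _derive(refs["cdgD" if identity == 0.44 else "cdgF"], identity, 33)
        assert assign_ortholog(q, refs) is None

    def test_raising_cutoff_monotone(self, ref_proteins):
        refs = {n: p.sequence for n, p in ref_proteins.items()
                if n in ("cdgB", "cdgD", "rmdA")}
        queries = [_derive(refs["cdgD"], t, 40 + i)
                   for i, t in enumerate((0.5, 0.6, 0.7, 0.9))]
        counts = []
        for cutoff in (0.45, 0.55, 0.65, 0.85):
            cfg = PangenomeConfig(id_cutoff=cutoff, borderline_cutoff=cutoff)
            counts.append(
                sum(assign_ortholog(q, refs, cfg) is not None for q in queries)
            )
        assert counts == sorted(counts, reverse=True)


class TestBBH:
    def test_identical_proteomes_pair_up(self):
        prot = {f"p{i}": rand_protein(60, i) for i in range(3)}
        pairs = bbh(prot, dict(prot))
        assert {(a, b) for a, b, _ in pairs} == {(f"p{i}", f"p{i}") for i in range(3)}

    def test_unpaired_extra_protein(self):
        a1 = rand_protein(60, 1)
        b2 = rand_protein(60, 2)
        pairs = bbh({"a1": a1}, {"b1": mutate_to_identity(a1, 0.8, 0, 5), "b2": b2})
        assert {(a, b) for a, b, _ in pairs} == {("a1", "b1")}

    def test_matches_brute_force_oracle_on_random_proteomes(self):
        A = {f"a{i}": rand_protein(50, 10 + i) for i in range(3)}
        B = {f"b{i}": rand_protein(50, 20 + i) for i in range(3)}
        # independent oracle: full score matrix + explicit unique-argmax scan
        S = {(a, b): score_pair(A[a], B[b]) for a in A for b in B}
        expected = set()
        for a in A:
            row = sorted(B, key=lambda b: -S[(a, b)])
            if len(row) > 1 and S[(a, row[0])] == S[(a, row[1])]:
                continue
            b = row[0]
            colmax = sorted(A, key=lambda x: -S[(x, b)])
            if len(colmax) > 1 and S[(colmax[0], b)] == S[(colmax[1], b)]:
                continue
            if colmax[0] == a:
                expected.add((a, b))
        got = {(a, b) for a, b, _ in bbh(A, B)}
        assert got == expected

    def test_symmetry(self):
        A = {f"a{i}": rand_protein(50, 30 + i) for i in range(3)}
        B = {f"b{i}": rand_protein(50, 40 + i) for i in range(3)}
        fwd = {(a, b) for a, b, _ in bbh(A, B)}
        rev = {(a, b) for b, a, _ in bbh(B, A)}
        assert fwd == rev


class TestValidateBorderline:
    def _assignment(self, sp, tag, idp):
        return OrthologAssignment(
            species_id=sp, locus_tag=tag, cluster_name="R1",
            identity_pct=idp, coverage_pct=100.0, validated=False,
            method="reference_anchor",
        )

    def test_borderline_bbh_retained(self):
        r1 = rand_protein(120, 1)
        q1 = mutate_to_identity(r1, 0.48, 0, 2)
        out = validate_borderline(
            [self._assignment("sp", "q1", 48.0)],
            {"R1": r1}, {"sp": {"q1": q1}},
        )
        assert len(out) == 1 and out[0].validated

    def test_borderline_non_bbh_demoted(self):
        r1 = rand_protein(120, 1)
        q_strong = mutate_to_identity(r1, 0.9, 0, 3)
        q_weak = mutate_to_identity(r1, 0.48, 0, 4)
        out = validate_borderline(
            [self._assignment("sp", "q_strong", 90.0),
             self._assignment("sp", "q_weak", 48.0)],
            {"R1": r1}, {"sp": {"q_strong": q_strong, "q_weak": q_weak}},
        )
        tags = {a.locus_tag for a in out}
        assert tags == {"q_strong"}  # weak copy loses the BBH to the paralog

    def test_above_borderline_untouched(self):
        out = validate_borderline(
            [self._assignment("sp", "q", 70.0)], {"R1": "MKT"}, {"sp": {}},
        )
        assert out[0].validated


class TestClusterUnassigned:
    def test_single_linkage_chain_transitivity(self):
        base = rand_protein(150, 7)
        b = mutate_to_identity(base, 0.55, 0, 8)
        c = mutate_to_identity(b, 0.55, 0, 9)
        assert align_pair(base, c, mode="semiglobal").identity_pct < 45
        clusters = cluster_unassigned(
            {("s1", "a"): base, ("s2", "b"): b, ("s3", "c"): c}
        )
        assert len(clusters) == 1
        assert len(clusters["NOVEL-001"]["members"]) == 3

    def test_unrelated_candidates_stay_singletons(self):
        clusters = cluster_unassigned(
            {("s1", "a"): rand_protein(100, 1), ("s2", "b"): rand_protein(100, 2)}
        )
        assert len(clusters) == 2
        assert all(len(c["members"]) == 1 for c in clusters.values())

    def test_ids_ordered_by_size_then_member(self):
        base = rand_protein(150, 3)
        cands = {("s1", "x"): rand_protein(100, 4)}
        for i in range(3):
            cands[(f"t{i}", "m")] = mutate_to_identity(base, 0.8, 0, 50 + i)
        clusters = cluster_unassigned(cands)
        assert len(clusters["NOVEL-001"]["members"]) == 3
        assert len(clusters["NOVEL-002"]["members"]) == 1


class TestPresenceAbsence:
    def _assign(self, sp, tag, cluster):
        return OrthologAssignment(sp, tag, cluster, 80.0, 100.0, True,
                                  "reference_anchor")

    def test_column_sums_and_paralog_collapse(self):
        assignments = [
            self._assign("s1", "a", "cdgB"),
            self._assign("s2", "b", "cdgB"),
            self._assign("s3", "c", "cdgB"),
            self._assign("s3", "c2", "cdgD"),
            self._assign("s3", "c3", "cdgD"),  # paralog: still one cell
        ]
        mat = build_presence_absence(assignments, {}, ["s2", "s1", "s3"],
                                     ["cdgB", "cdgD"])
        assert mat.species == ["s1", "s2", "s3"]  # alphabetical
        assert mat.counts == {"cdgB": 3, "cdgD": 1}

    def test_empty_novel_set_keeps_reference_columns(self):
        mat = build_presence_absence(
            [self._assign("s1", "a", "cdgB")], {}, ["s1"], ["cdgB", "cdgD"]
        )
        assert mat.clusters == ["cdgB", "cdgD"]

    def test_row_order_invariant_to_input_species_order(self):
        assignments = [self._assign("s1", "a", "cdgB")]
        m1 = build_presence_absence(assignments, {}, ["s1", "s2"], ["cdgB"])
        m2 = build_presence_absence(assignments, {}, ["s2", "s1"], ["cdgB"])
        assert m1.cells.equals(m2.cells)


class TestConservationCategories:
    @pytest.mark.parametrize(
        "count, expected",
        [(93, "core"), (92, "soft_core"), (90, "soft_core"), (88, "soft_core"),
         (87, "accessory"), (50, "accessory"), (2, "accessory"), (1, "unique")],
    )
    def test_printed_boundaries_at_n93(self, count, expected):
        assert classify_conservation(count, 93).category == expected

    def test_every_count_has_exactly_one_category(self):
        cats = [classify_conservation(c, 93).category for c in range(1, 94)]
        assert cats.count("core") == 1
        assert cats.count("soft_core") == 5       # 88..92
        assert cats.count("accessory") == 86      # 2..87
        assert cats.count("unique") == 1

    def test_generalized_softcore_at_n20(self):
        assert classify_conservation(19, 20).category == "soft_core"
        assert classify_conservation(18, 20).category == "accessory"

    @pytest.mark.parametrize("count", [0, 94])
    def test_out_of_range_count_rejected(self, count):
        with pytest.raises(ValueError):
            classify_conservation(count, 93)
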