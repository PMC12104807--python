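"""Hit-table plumbing and the annotation decision cascade."""

import pytest

from opsin_dollo.hits import (
    HitTable,
    PathwayEntry,
    Status,
    SubjectInfo,
    Tier,
    best_hit_per_query,
    evalue_prefilter,
    kegg_tiered_annotation,
    read_hit_table,
    reciprocal_opsin_filter,
)


def table(rows):
    return HitTable.from_rows(
        [[q, s, 90.0, 100, 5, 1, 1, 100, 1, 100, ev, bit] for q, s, ev, bit in rows]
    )


META = {
    "ops1": SubjectInfo("ops1", "Opsin 1", True, "cl_a", "ACC_OPS1"),
    "ops2": SubjectInfo("ops2", "Opsin 2", True, "cl_b", "ACC_OPS2"),
    "gpr1": SubjectInfo("gpr1", "Non-opsin GPCR 1", False, "cl_c", "ACC_GPR1"),
    "gpr2": SubjectInfo("gpr2", "Non-opsin GPCR 2", False, "cl_d", "ACC_GPR2"),
    "gpr3": SubjectInfo("gpr3", "Non-opsin GPCR 3", False, "cl_e", "ACC_GPR3"),
}


class TestBestHit:
    def test_max_bitscore_wins(self):
        t = table([("q1", "s1", 1e-50, 200.0), ("q1", "s2", 1e-60, 150.0)])
        best = best_hit_per_query(t)
        assert len(best) == 1 and best.df.iloc[0]["sseqid"] == "s1"

    def test_tie_breaks_by_evalue_then_subject_and_is_logged(self):
        t = table([("q1", "sB", 1e-40, 200.0), ("q1", "sA", 1e-50, 200.0)])
        best = best_hit_per_query(t)
        assert best.df.iloc[0]["sseqid"] == "sA"  # lower e-value
        assert best.tie_log and best.tie_log[0]["tied_subjects"] == ["sB"]
        t2 = table([("q1", "sB", 1e-50, 200.0), ("q1", "sA", 1e-50, 200.0)])
        assert best_hit_per_query(t2).df.iloc[0]["sseqid"] == "sA"  # lexicographic

    def test_empty_table_passes_through(self):
        empty = HitTable.from_rows([])
        assert len(best_hit_per_query(empty)) == 0


class TestEvaluePrefilter:
    def test_default_cutoff_keeps_only_significant_rows(self):
        t = table([("q1", "s1", 1e-6, 50.0), ("q2", "s2", 1e-3, 60.0)])
        kept = evalue_prefilter(t)
        assert len(kept) == 1 and kept.df.iloc[0]["qseqid"] == "q1"

    def test_infinite_threshold_is_identity_and_all_filtered_gives_empty(self):
        t = table([("q1", "s1", 1e-6, 50.0), ("q2", "s2", 1e-3, 60.0)])
        assert len(evalue_prefilter(t, float("inf"))) == 2
        assert len(evalue_prefilter(t, 1e-99)) == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            evalue_prefilter(table([]), -1.0)


class TestReciprocalFilter:
    def test_one_opsin_in_top_three_is_enough(self):
        back = table(
            [("c1", "ops1", 1e-50, 200.0), ("c1", "gpr1", 1e-40, 190.0), ("c1", "gpr2", 1e-30, 180.0)]
        )
        (d,) = reciprocal_opsin_filter(["c1"], back, META)
        assert d.status is Status.ANNOTATED

    def test_no_opsin_in_top_three_removed(self):
        back = table(
            [("c1", "gpr1", 1e-50, 200.0), ("c1", "gpr2", 1e-40, 190.0), ("c1", "gpr3", 1e-30, 180.0)]
        )
        (d,) = reciprocal_opsin_filter(["c1"], back, META)
        assert d.status is Status.REMOVED and "top-3" in d.reason

    def test_opsin_ranked_fourth_is_truncated_away(self):
        back = table(
            [
                ("c1", "gpr1", 1e-50, 200.0),
                ("c1", "gpr2", 1e-45, 195.0),
                ("c1", "gpr3", 1e-40, 190.0),
                ("c1", "ops1", 1e-35, 185.0),
            ]
        )
        (d,) = reciprocal_opsin_filter(["c1"], back, META, k=3)
        assert d.status is Status.REMOVED
        (d4,) = reciprocal_opsin_filter(["c1"], back, META, k=4)
        assert d4.status is Status.ANNOTATED

    def test_candidate_without_hits_removed_with_reason(self):
        (d,) = reciprocal_opsin_filter(["ghost"], table([]), META)
        assert d.status is Status.REMOVED and d.reason == "no hits"

    def test_decision_log_is_deterministic(self):
        back = table(
            [("c1", "ops1", 1e-50, 200.0), ("c2", "gpr1", 1e-40, 190.0)]
        )
        a = [d.to_dict() for d in reciprocal_opsin_filter(["c1", "c2"], back, META)]
        b = [d.to_dict() for d in reciprocal_opsin_filter(["c1", "c2"], back, META)]
        assert a == b


DB = {
    "K00001": PathwayEntry(
        "K00001",
        accessions={"ACC_OPS1"},
        names={"Adenosine receptor A2a"},
        ambiguous_names={"Adenosine receptor A2"},
        clusters={"cl_a"},
    )
}


class TestTieredAnnotation:
    def hits_for(self, subject):
        return table([("p1", subject, 1e-50, 200.0)])

    def test_accession_tier_fires_first(self):
        (d,) = kegg_tiered_annotation(self.hits_for("ops1"), META, DB)
        assert (d.status, d.tier, d.ko) == (Status.ANNOTATED, Tier.ACCESSION, "K00001")

    def test_name_tier_requires_exact_unambiguous_name(self):
        meta = {
            "a2a": SubjectInfo("a2a", "Adenosine receptor A2a", False, "cl_z", "X1"),
            "a2": SubjectInfo("a2", "Adenosine receptor A2", False, "cl_z2", "X2"),
        }
        (d,) = kegg_tiered_annotation(self.hits_for("a2a"), meta, DB)
        assert d.tier is Tier.NAME
        (d2,) = kegg_tiered_annotation(self.hits_for("a2"), meta, DB)
        assert d2.status is Status.UNRESOLVED

    def test_cluster_tier_fires_last(self):
        meta = {"rel": SubjectInfo("rel", "Uncharacterized protein", False, "cl_a", "X3")}
        (d,) = kegg_tiered_annotation(self.hits_for("rel"), meta, DB)
        assert d.tier is Tier.CLUSTER

    def test_tier_precedence_no_accession_qualified_hit_lands_lower(self):
        # subject qualifies at accession AND cluster level: accession wins
        (d,) = kegg_tiered_annotation(self.hits_for("ops1"), META, DB)
        assert d.tier is Tier.ACCESSION

    def test_empty_accession_set_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="empty accession"):
            PathwayEntry("K9", accessions=set())


def test_hit_table_io_round_trip(tmp_path):
    from pandas.testing import assert_frame_equal

    t = table([("q1", "s1", 1e-50, 200.0), ("q2", "s2", 1e-40, 190.0)])
    p = tmp_path / "hits.tsv"
    t.write(p)
    assert_frame_equal(read_hit_table(p).df, t.df)
    # with header
    t.write(p, header=True)
    assert_frame_equal(read_hit_table(p).df, t.df)


def test_invalid_tables_rejected():
    with pytest.raises(ValueError, match="negative e-value"):
        table([("q1", "s1", -1e-5, 10.0)])
    with pytest.raises(ValueError, match="columns"):
        HitTable(__import__("pandas").DataFrame({"a": [1]}))
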