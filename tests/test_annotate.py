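"""Tag classification precedence, exact known-miRNA matching, and family
aggregation."""

import pandas as pd
import pytest

from budmir._util import revcomp
from budmir.annotate import (ReferenceSet, classify_tags, family_summary,
                             load_reference_fasta, match_known_mirnas,
                             member_name)
from budmir.preprocess import tag_table
from reference_values import (FAMILY_MEMBER_COUNTS, MIR156_IMPERFECT_TOTAL,
                              MIR156_PERFECT_TOTAL, TABLE4_FAMILY_ROWS)


def _refset(label, records):
    return ReferenceSet(label=label, records=pd.DataFrame(
        records, columns=["id", "family", "seq"]))


RRNA = "G" * 10 + "ACGTACGTACGTACGTAC" + "C" * 10
TRNA = "T" * 5 + "ACGTACGTACGTACGTAC" + "A" * 5


@pytest.fixture
def refs():
    return {
        "rRNA": _refset("rRNA", [("rrna-1", "", RRNA)]),
        "tRNA": _refset("tRNA", [("trna-1", "", TRNA)]),
        "miRNA": _refset("miRNA", [("miR156a", "MIR156",
                                    "TGACAGAAGAGAGTGAGCAC")]),
    }


def _tags(seqs):
    return tag_table({"perfect": {s: 1 for s in seqs}})


def test_precedence_rrna_beats_trna(refs):
    classes, _ = classify_tags(_tags(["ACGTACGTACGTACGTAC"]), refs)
    assert classes.iloc[0] == "rRNA"


def test_reverse_strand_fragment_matches(refs):
    classes, _ = classify_tags(_tags([revcomp(RRNA[5:25])]), refs)
    assert classes.iloc[0] == "rRNA"


def test_unmatched_tag_is_unannotated(refs):
    classes, tally = classify_tags(_tags(["TTTTGGGGCCCCAAAATTTT"]), refs)
    assert classes.iloc[0] == "unannotated"
    assert tally.loc["unannotated", "unique"] == 1


def test_mirna_match_requires_full_length_identity(refs):
    mature = "TGACAGAAGAGAGTGAGCAC"
    variant = mature[:-1] + "T"          # 1 nt substitution
    fragment = mature[:-1]               # substring, not full length
    classes, _ = classify_tags(_tags([mature, variant, fragment]), refs)
    assert classes[mature] == "miRNA"
    assert classes[variant] == "unannotated"
    assert classes[fragment] == "unannotated"


def test_empty_references_warns(refs):
    with pytest.warns(UserWarning):
        classes, _ = classify_tags(_tags(["ACGTACGTACGTACGTAC"]), {})
    assert (classes == "unannotated").all()


def test_match_known_mirnas_copies_counts(refs):
    mature = "TGACAGAAGAGAGTGAGCAC"
    tags = tag_table({"perfect": {mature: 7}, "imperfect": {mature: 3}})
    hits = match_known_mirnas(tags, refs["miRNA"])
    assert len(hits) == 1
    row = hits.iloc[0]
    assert (row.mirna_id, row.family_id) == ("miR156a", "MIR156")
    assert (row.perfect, row.imperfect) == (7, 3)


def test_duplicate_mature_sequences_both_reported():
    seq = "TGACAGAAGAGAGTGAGCAC"
    ref = _refset("miRNA", [("miR1", "MIR1", seq), ("miR2", "MIR2", seq)])
    tags = tag_table({"perfect": {seq: 5}})
    with pytest.warns(UserWarning):
        hits = match_known_mirnas(tags, ref)
    assert sorted(hits.mirna_id) == ["miR1", "miR2"]


def test_member_name_strips_arm_suffix():
    assert member_name("miR171b-3p") == "miR171b"
    assert member_name("miR167-3p") == "miR167"
    assert member_name("miR156a") == "miR156a"


def _family_hits():
    rows = [{"tag": f"T{i}", "mirna_id": mid, "family_id": fam,
             "perfect": xp, "imperfect": xi}
            for i, (fam, mid, xp, xi) in enumerate(TABLE4_FAMILY_ROWS)]
    return pd.DataFrame(rows)


def test_family_summary_reproduces_published_aggregates():
    fam = family_summary(_family_hits())
    assert fam.loc["MIR156", "perfect"] == MIR156_PERFECT_TOTAL
    assert fam.loc["MIR156", "imperfect"] == MIR156_IMPERFECT_TOTAL
    for family, members in FAMILY_MEMBER_COUNTS.items():
        assert fam.loc[family, "members"] == members


def test_family_totals_conserve_hit_counts():
    hits = _family_hits()
    fam = family_summary(hits)
    assert fam["perfect"].sum() == hits["perfect"].sum()
    assert fam["imperfect"].sum() == hits["imperfect"].sum()


def test_single_hit_family():
    fam = family_summary(pd.DataFrame([{
        "tag": "T", "mirna_id": "miR9a", "family_id": "MIR9",
        "perfect": 4, "imperfect": 9}]))
    assert fam.loc["MIR9", "members"] == 1
    assert fam.loc["MIR9", "perfect"] == 4


def test_classification_order_invariance(refs):
    seqs = ["ACGTACGTACGTACGTAC", "TGACAGAAGAGAGTGAGCAC",
            "TTTTGGGGCCCCAAAATTTT"]
    t1 = _tags(seqs)
    t2 = _tags(list(reversed(seqs)))
    _, tally1 = classify_tags(t1, refs)
    _, tally2 = classify_tags(t2, refs)
    pd.testing.assert_frame_equal(tally1, tally2)


def test_planted_references_recovered(sim_full):
    """All 61 planted matures are seen and the category tally matches the
    generator truth."""
    refs = {
        label: ReferenceSet(label=label, records=sub[["id", "family", "seq"]]
                            .reset_index(drop=True))
        for label, sub in sim_full.references.groupby("class")
    }
    classes, tally = classify_tags(sim_full.tags, refs)
    hits = match_known_mirnas(sim_full.tags, refs["miRNA"])
    assert hits["mirna_id"].nunique() == 61
    assert hits["family_id"].nunique() == 24
    # redundant class totals equal truth (clean reads whose insert equals a
    # planted species of that class)
    truth = sim_full.truth.reads
    clean = truth[truth["category"] == "clean"]
    known_seqs = set(sim_full.references.query("`class` == 'miRNA'")["seq"])
    truth_mirna_reads = clean["insert"].isin(known_seqs).sum()
    assert tally.loc["miRNA", "redundant"] == truth_mirna_reads


def test_load_reference_fasta_roundtrip(tmp_path):
    p = tmp_path / "refs.fa"
    p.write_text(">miR1|MIR1|miRNA\nUGACAGAAGAGAGUGAGCAC\n"
                 ">rrna-1|none|rRNA\nACGTACGTACGTACGTACGT\n")
    refs = load_reference_fasta(p)
    assert set(refs) == {"miRNA", "rRNA"}
    assert refs["miRNA"].records.iloc[0]["seq"] == "TGACAGAAGAGAGTGAGCAC"
    with pytest.raises(ValueError):
        bad = tmp_path / "bad.fa"
        bad.write_text(">nopipes\nACGT\n")
        load_reference_fasta(bad)
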