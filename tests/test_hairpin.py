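"""Genome mapping, window extraction, stem-loop criteria, and the self-audit
of accepted candidates."""

import pytest

from budmir._util import revcomp
from budmir.fold import fold
from budmir.hairpin import (GenomeLocus, HairpinThresholds, discover,
                            evaluate_candidate, extract_windows,
                            first_nt_bias, map_to_genome)
from budmir.simlib import HairpinDesign, build_precursor, star_sequence

import numpy as np

_PAIRED = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"),
           ("T", "G")}


# ---------------------------------------------------------------------------
# mapping

def test_map_finds_planted_minus_strand_locus(sim_small):
    genome = sim_small.genome
    for row in sim_small.truth.hairpins.itertuples():
        loci = map_to_genome([row.mature], genome)
        assert len(loci) == 1
        locus = loci[0]
        assert locus.strand == row.strand
        assert locus.scaffold == row.scaffold
        assert row.start <= locus.start and locus.end <= row.end


def test_absent_tag_maps_nowhere():
    assert map_to_genome(["TTTTTTTTTTTTTTTTTTTT"], {"s": "ACGT" * 100}) == []


def test_palindromic_tag_yields_both_strand_loci():
    tag = "ACGTACGTACGTACGTACGT"
    assert tag == revcomp(tag)
    genome = {"s": "GGGGG" + tag + "GGGGG"}
    loci = map_to_genome([tag], genome)
    assert {l.strand for l in loci} == {"+", "-"}
    assert all(l.start == 5 for l in loci)


def test_repeat_tags_dropped():
    tag = "ACGTTGCAACGTTGCAACTT"
    genome = {"s": ("X".join([tag] * 25)).replace("X", "CC")}
    assert map_to_genome([tag], genome, max_loci=20) == []


# ---------------------------------------------------------------------------
# windows

def test_interior_window_arithmetic():
    genome = {"s": "A" * 2000}
    locus = GenomeLocus("s", 1000, 1021, "+", "T" * 21)
    (a1, w1, o1), (a2, w2, o2) = extract_windows(locus, genome, flank=250)
    assert (len(w1), o1, a1) == (20 + 21 + 250, 20, 980)
    assert (len(w2), o2, a2) == (250 + 21 + 20, 250, 750)


def test_edge_window_is_clipped():
    genome = {"s": "A" * 400}
    locus = GenomeLocus("s", 0, 21, "+", "T" * 21)
    (a1, w1, o1), (a2, w2, o2) = extract_windows(locus, genome, flank=250)
    assert a1 == 0 and o1 == 0
    assert a2 == 0 and o2 == 0


def test_minus_strand_window_contains_tag_at_offset(sim_small):
    genome = sim_small.genome
    minus = sim_small.truth.hairpins.query("strand == '-'")
    for row in minus.itertuples():
        locus = map_to_genome([row.mature], genome)[0]
        for _, window, offset in extract_windows(locus, genome):
            assert window[offset:offset + len(row.mature)] == row.mature


# ---------------------------------------------------------------------------
# candidate evaluation

def _planted_window(seed=0, arm="5p", n_mismatch=1):
    design = HairpinDesign(name="t", mature="TGTACCGATCGGTTACAGCAG",
                          arm=arm, n_mismatch=n_mismatch)
    pre, star = build_precursor(design, np.random.default_rng(seed))
    rng = np.random.default_rng(seed + 1)
    flank5 = "".join(rng.choice(list("ACGT"), size=40))
    flank3 = "".join(rng.choice(list("ACGT"), size=40))
    window = flank5 + pre + flank3
    offset = 40 + pre.find(design.mature)
    return design, pre, star, window, offset


def test_planted_hairpin_accepted_with_correct_arm():
    for arm in ("5p", "3p"):
        design, pre, star, window, offset = _planted_window(arm=arm)
        cand = evaluate_candidate(window, offset, len(design.mature),
                                  {design.mature: 100, star: 2})
        assert cand.accepted, cand.reasons
        assert cand.arm == arm
        assert cand.star == star
        assert cand.mature == design.mature


def test_star_without_reads_is_rejected():
    design, pre, star, window, offset = _planted_window()
    cand = evaluate_candidate(window, offset, len(design.mature),
                              {design.mature: 100})
    assert not cand.accepted
    assert "no miRNA* read support" in cand.reasons


def test_weak_stem_rejected_for_energy():
    """An AU-only stem folds far above -18 kcal/mol and must carry the MFE
    rejection reason even though its duplex geometry is fine."""
    mature = "TATTAATATTAATATTAATAT"
    star = star_sequence(mature, "CC")
    loop = "CACACACACACA"
    window = "CGCG" + mature + loop + star + "CGCG"
    offset = 4
    cand = evaluate_candidate(window, offset, len(mature),
                              {mature: 50, star: 2})
    assert not cand.accepted
    assert any("MFE above threshold" in r for r in cand.reasons)


def test_mismatch_heavy_duplex_rejected():
    design, pre, star, window, offset = _planted_window(n_mismatch=0)
    # corrupt 6 spread stem positions of the star within the window
    sstart = window.find(star)
    w = list(window)
    for k in range(3, 15, 2):
        w[sstart + k] = {"A": "G", "C": "T", "G": "A", "T": "C"}[w[sstart + k]]
    window2 = "".join(w)
    star2 = window2[sstart:sstart + len(star)]
    cand = evaluate_candidate(window2, offset, len(design.mature),
                              {design.mature: 100, star2: 2})
    assert not cand.accepted


def test_accepted_candidates_self_audit(discovery_full):
    """Re-verify every invariant of each accepted candidate from primitive
    string operations and a fresh fold."""
    accepted = [c for c in discovery_full if c.accepted]
    assert accepted
    for c in accepted:
        pre = c.precursor
        assert len(pre) >= 50
        a = pre.find(c.mature)
        s = pre.find(c.star)
        assert a >= 0 and s >= 0
        # non-overlap
        assert a + len(c.mature) <= s or s + len(c.star) <= a
        # 2 nt 3' overhang geometry: mature k pairs star end-2-k
        d = s + len(c.star) - 1
        mism = sum((pre[a + k], pre[d - 2 - k]) not in _PAIRED
                   for k in range(len(c.mature) - 2))
        assert mism <= 4
        assert c.duplex_mismatches is not None and c.duplex_mismatches <= 4
        # energy gate re-checked with a fresh fold
        assert fold(pre).mfe <= -18.0
        assert c.fold is not None and c.fold.mfe <= -18.0
        assert c.star_count >= 1 and c.mature_count >= 5
        assert c.reasons == []


def test_discovery_dedupes_star_seeded_duplicates(discovery_full, sim_full):
    accepted = [c for c in discovery_full if c.accepted]
    keys = [(c.locus.scaffold, c.locus.strand, c.locus.start // 50)
            for c in accepted]
    assert len(keys) == len(set(keys))
    matures = {c.mature for c in accepted}
    stars = set(sim_full.truth.hairpins["star"])
    assert not matures & stars  # the mature-seeded candidate won each locus


# ---------------------------------------------------------------------------
# first-nucleotide bias

def test_first_nt_bias_all_u():
    df = first_nt_bias(["TACGTACGTACGTACGTACGT", "TACGTACGTACGTACGTACGTA"])
    assert (df["U"] == 1.0).all()


def test_first_nt_bias_single_candidate():
    df = first_nt_bias(["GACGTACGTACGTACGTACGT"])
    assert df.loc[21, "G"] == 1.0
    assert df.loc[21].sum() == pytest.approx(1.0)


def test_first_nt_bias_rows_sum_to_one(discovery_full):
    accepted = [c.mature for c in discovery_full if c.accepted]
    df = first_nt_bias(accepted)
    assert df.sum(axis=1).round(9).eq(1.0).all()


def test_first_nt_bias_empty():
    assert first_nt_bias([]).empty


def test_first_nt_bias_recovers_planted_u_fraction():
    """A planted 70% 5'-U fraction is recovered within 3 binomial sigmas."""
    rng = np.random.default_rng(6)
    n = 400
    matures = []
    for _ in range(n):
        first = "T" if rng.random() < 0.7 else rng.choice(list("ACG"))
        matures.append(first + "".join(rng.choice(list("ACGT"), size=20)))
    df = first_nt_bias(matures)
    observed = (df["U"] * df.index.to_series().map(
        lambda L: sum(len(m) == L for m in matures))).sum() / n
    sigma = (0.7 * 0.3 / n) ** 0.5
    assert abs(observed - 0.7) <= 3 * sigma
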