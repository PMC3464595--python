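"""Generator guarantees: determinism, planted-locus uniqueness, duplex
constructibility, abundance recovery, and error handling."""

import warnings

import numpy as np
import pytest

from budmir._util import revcomp
from budmir.fold import fold
from budmir.simlib import (HairpinDesign, SimulationSpec, build_precursor,
                           make_genome, make_references, make_transcripts,
                           simulate_libraries, star_sequence, write_dataset)

_PAIRED = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"),
           ("T", "G")}


def test_identical_seed_gives_byte_identical_files(tmp_path):
    spec = SimulationSpec(seed=7, library_depth=3000)
    p1 = write_dataset(spec, tmp_path / "a")
    p2 = write_dataset(spec, tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_zero_hairpins_gives_pure_background_genome():
    spec = SimulationSpec(seed=0, planted_hairpins=[], scaffold_len=5000)
    genome, truth = make_genome(spec)
    assert truth.hairpins.empty
    assert len(genome) == spec.n_scaffolds
    assert all(len(s) == 5000 for s in genome.values())


def test_each_mature_occurs_exactly_once_by_naive_scan(sim_small):
    """Oracle: exhaustive string scan of both strands of every scaffold."""
    genome = sim_small.genome
    for row in sim_small.truth.hairpins.itertuples():
        hits = 0
        for seq in genome.values():
            hits += seq.count(row.mature) + revcomp(seq).count(row.mature)
        assert hits == 1
        # the recorded locus really contains the precursor
        sub = genome[row.scaffold][row.start:row.end]
        expected = row.precursor if row.strand == "+" else revcomp(row.precursor)
        assert sub == expected


def test_planted_duplex_constructibility(sim_small):
    """Every planted hairpin folds so mature and star pair on the designed
    stem with at most 4 non-pairing positions."""
    for row in sim_small.truth.hairpins.itertuples():
        pre, mature, star = row.precursor, row.mature, row.star
        a = pre.find(mature)
        c = pre.find(star)
        assert a >= 0 and c >= 0 and (a + len(mature) <= c or c + len(star) <= a)
        L = len(mature)
        d = c + len(star) - 1
        mismatches = sum(
            (mature[k], pre[d - 2 - k]) not in _PAIRED for k in range(L - 2))
        assert mismatches <= 4
        f = fold(pre)
        assert f.mfe <= -18.0
        # mature sits on a stem arm in the MFE structure
        partners = [f.pairs[p] for p in range(a, a + L) if f.pairs[p] >= 0]
        assert len(partners) >= L - 8
        assert all(q < a or q >= a + L for q in partners)


def test_star_sequence_geometry():
    mature = "TGACAGAAGAGAGTGAGCACA"
    star = star_sequence(mature, "GT")
    assert len(star) == len(mature)
    # star[:L-2] is the reverse complement of mature[:L-2]
    assert star[:-2] == revcomp(mature[:-2])
    with pytest.raises(ValueError):
        star_sequence(mature, "G")


def test_infeasible_design_rejected():
    weak = HairpinDesign(name="weak", mature="AT" * 10 + "A")  # AU-only stem
    with pytest.raises(ValueError, match="infeasible"):
        build_precursor(weak, np.random.default_rng(0), max_tries=10)
    with pytest.raises(ValueError, match="stem"):
        HairpinDesign(name="short", mature="ACGTACGT").validate()


def test_depth_zero_warns_and_empties():
    spec = SimulationSpec(seed=0, library_depth=0, scaffold_len=5000)
    genome, truth = make_genome(spec)
    with pytest.warns(UserWarning):
        libs, _ = simulate_libraries(genome, spec, truth)
    assert libs["perfect"] == [] and libs["imperfect"] == []


def test_every_read_has_exactly_one_truth_record(sim_small):
    truth = sim_small.truth.reads
    for lib, reads in sim_small.libraries.items():
        ids = truth.loc[truth["library"] == lib, "read_id"]
        assert ids.is_unique
        assert set(ids) == {rid for rid, _, _ in reads}


def test_planted_abundance_recovery_correlation(sim_full):
    """Pearson correlation between planted expected counts and recovered
    clean-tag counts exceeds 0.99 at 1e5 reads."""
    from collections import Counter

    for lib in ("perfect", "imperfect"):
        obs = Counter(ins for _, ins in sim_full.cleaned[lib].inserts)
        sp = sim_full.truth.species
        planted = sp[sp["class"].isin(["miRNA", "novel_mature", "novel_star"])]
        exp = planted[f"expected_{lib}"].to_numpy(float)
        rec = np.array([obs.get(s, 0) for s in planted["seq"]], float)
        r = np.corrcoef(exp, rec)[0, 1]
        assert r > 0.99, (lib, r)


def test_differential_designs_have_planted_fold_at_least_1_5(sim_full):
    known = sim_full.truth.known
    expressed = known[(known.expected_perfect > 0) & (known.expected_imperfect > 0)]
    folds = np.maximum(expressed.expected_imperfect / expressed.expected_perfect,
                       expressed.expected_perfect / expressed.expected_imperfect)
    assert (folds[folds > 1.01] >= 1.5).all()
    assert (known[["expected_perfect", "expected_imperfect"]] >= 0).all().all()


def test_references_have_unique_ids_and_61_matures(sim_small):
    refs = sim_small.references
    assert refs["id"].is_unique
    assert (refs["class"] == "miRNA").sum() == 61
    assert refs.query("`class` == 'miRNA'")["family"].nunique() == 24


def test_make_transcripts_plants_recoverable_sites():
    mirnas = {"miR-a": "TGACAGAAGAGAGTGAGCACA"}
    tx, sites = make_transcripts(5, mirnas, n_transcripts=10,
                                 sites_per_mirna=3)
    assert len(sites) == 3
    for row in sites.itertuples():
        window = tx[row.transcript_id][row.start:row.start + 21]
        assert window == revcomp(mirnas["miR-a"])
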