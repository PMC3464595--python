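"""Read cleaning categories, tag collapsing, length histograms and overlap
statistics — unit cases plus exact round-trip against generator truth."""

from collections import Counter

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budmir.preprocess import (clean_reads, collapse, length_histogram,
                               mean_frequency, overlap_stats, tag_table)
from reference_values import TABLE3

AD3 = "TCGTATGCCGTCTTCTGCTTG"
AD5 = "GTTCAGAGTTCTACAGTCCGACGATC"
Q = "I" * 36


def _pad(seq: str) -> str:
    return (seq + "G" * 36)[:36]


def _run(reads):
    return clean_reads(iter(reads), AD3, AD5)


def test_adapter_only_read_is_insert_null():
    res = _run([("r1", _pad(AD3), Q)])
    assert res.summary.insert_null == 1
    assert res.summary.clean_total == 0


def test_sixteen_nt_insert_is_too_short():
    res = _run([("r1", _pad("ACGTACGTACGTACGT" + AD3), Q)])
    assert res.summary.short == 1


def test_clean_read_is_trimmed_to_its_insert():
    insert = "ACGTACGTACGTACGTACGTA"  # 21 nt
    res = _run([("r1", _pad(insert + AD3), Q)])
    assert res.inserts == [("r1", insert)]
    assert res.summary.clean_total == 1


def test_missing_adapter_is_adapter_null():
    res = _run([("r1", "ACGT" * 9, Q)])
    assert res.summary.adapter3_null == 1


def test_five_prime_adapter_contaminant():
    read = (AD5[-12:] + "ACGTACGTAC" + AD3)[:36]
    res = _run([("r1", read, Q)])
    assert res.summary.adapter5 == 1


def test_polya_insert_filtered():
    insert = "AAAAAAAAAAAAAAAAAAGA"  # 90% A
    res = _run([("r1", _pad(insert + AD3), Q)])
    assert res.summary.polya == 1


def test_low_quality_reads():
    bad_qual = "#" * 18 + "I" * 18
    res = _run([("r1", _pad("ACGTACGTACGTACGTACGTA" + AD3), bad_qual),
                ("r2", _pad("ACGTNCGTACGTACGTACGTA" + AD3), Q)])
    assert res.summary.high_quality == 0
    assert res.summary.total_reads == 2


def test_non_acgtn_characters_rejected_with_warning():
    with pytest.warns(UserWarning):
        res = _run([("r1", _pad("ACGRACGTACGTACGTACGTA" + AD3), Q)])
    assert res.summary.high_quality == 0


def test_ledger_conservation(sim_small):
    for lib, res in sim_small.cleaned.items():
        s = res.summary
        assert s.clean_total == s.high_quality - (
            s.adapter3_null + s.insert_null + s.adapter5 + s.short + s.polya)
        assert s.total_reads == len(sim_small.libraries[lib])


def test_roundtrip_categories_exact(sim_small):
    """With unambiguous rates the ledger equals the generator truth exactly,
    read by read."""
    truth = sim_small.truth.reads
    for lib, res in sim_small.cleaned.items():
        sub = truth[truth["library"] == lib]
        expected = dict(zip(sub["read_id"], sub["category"]))
        assert res.categories == expected


def test_roundtrip_tag_counts_exact(sim_small):
    for lib, res in sim_small.cleaned.items():
        observed = Counter(ins for _, ins in res.inserts)
        planted = sim_small.truth.planted_counts(lib).to_dict()
        assert observed == planted


def test_collapse_counts_identical_reads():
    assert collapse(["ACGT"] * 3) == Counter({"ACGT": 3})


def test_collapse_matches_naive_recount():
    import random
    rng = random.Random(0)
    reads = ["".join(rng.choice("ACGT") for _ in range(20))
             for _ in range(10_000)]
    naive: dict[str, int] = {}
    for r in reads:
        naive[r] = naive.get(r, 0) + 1
    assert dict(collapse(reads)) == naive


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.text(alphabet="ACGT", min_size=18, max_size=24),
                max_size=40))
def test_collapse_is_order_independent_and_idempotent(reads):
    c1 = collapse(reads)
    c2 = collapse(reversed(reads))
    assert c1 == c2
    # collapsing the unique tags once each yields counts of 1
    assert all(v == 1 for v in collapse(c1.keys()).values())


def test_tag_table_totals():
    df = tag_table({"a": {"ACGT" * 5: 3, "TTTT" * 5: 1}, "b": {"ACGT" * 5: 2}})
    assert df["a"].sum() == 4 and df["b"].sum() == 2
    assert len(df) == 2


def test_length_histogram_single_length():
    h = length_histogram({"A" * 21: 7})
    assert h[21] == 1.0
    assert h.sum() == pytest.approx(1.0, abs=1e-9)


def test_length_histogram_weighting_differs_when_one_tag_dominates():
    tags = {"A" * 21: 1000, "C" * 24: 1}
    hw = length_histogram(tags, weighted=True)
    hu = length_histogram(tags, weighted=False)
    assert hw[21] > 0.99
    assert hu[21] == pytest.approx(0.5)


def test_length_histogram_empty_errors():
    with pytest.raises(ValueError):
        length_histogram({})


def test_length_histogram_recovers_planted_distribution(sim_small):
    """Insert lengths of clean background reads track the generator's
    length distribution (each length within a joint 4-sigma band)."""
    truth = sim_small.truth.reads
    sub = truth[(truth["category"] == "clean")
                & truth["species"].str.startswith(("bg:", "frag:", "genomic:"))]
    lengths = sub["insert"].str.len()
    n = len(lengths)
    dist = sim_small.spec.length_dist
    for L, p in dist.items():
        obs = (lengths == L).mean()
        sigma = (p * (1 - p) / n) ** 0.5
        assert abs(obs - p) <= 4 * sigma + 1e-12, (L, obs, p)


def test_planted_half_and_half_length_split_within_three_sigma():
    """A 50/50 split between 21 and 24 nt is recovered within 3 binomial
    standard deviations at 1e5 reads."""
    from budmir.simlib import SimulationSpec, make_genome, simulate_libraries

    spec = SimulationSpec(seed=12, library_depth=100_000,
                          length_dist={21: 0.5, 24: 0.5})
    genome, truth = make_genome(spec)
    _, truth = simulate_libraries(genome, spec, truth)
    reads = truth.reads
    sub = reads[(reads["category"] == "clean")
                & reads["species"].str.startswith(("bg:", "frag:", "genomic:"))]
    lengths = sub["insert"].str.len()
    n = len(lengths)
    sigma = (0.25 / n) ** 0.5
    assert abs((lengths == 21).mean() - 0.5) <= 3 * sigma


def test_mean_frequency_reproduces_published_overlap_values():
    for unique, redundant, mf in TABLE3.values():
        assert mean_frequency(redundant, unique) == mf


def test_overlap_stats_disjoint_sets():
    a = {"A" * 20: 4, "C" * 20: 2}
    b = {"G" * 20: 5}
    df = overlap_stats(a, b)
    assert df.loc["common", "unique"] == 0
    assert df.loc["total", "unique"] == 3
    assert df.loc["a_specific", "mean_frequency"] == 3.0
    assert df.loc["b_specific", "mean_frequency"] == 5.0


def test_overlap_stats_partition_invariant(sim_small):
    tags = sim_small.tags
    df = overlap_stats(tags["perfect"], tags["imperfect"])
    assert (df.loc["common", "unique"] + df.loc["a_specific", "unique"]
            + df.loc["b_specific", "unique"]) == df.loc["total", "unique"]
    assert df.loc["total", "redundant"] == int(tags.sum().sum())
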