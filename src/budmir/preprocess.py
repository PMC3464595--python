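"""Raw-read cleaning, tag collapsing, and library-level summaries.

Small-RNA reads come off the sequencer at a fixed cycle length with the 3'
sequencing adapter read through; cleaning locates the adapter, trims it, and
sorts every read into exactly one category:

low quality, 3' adapter null (adapter never found), 5' adapter contaminant,
insert null (nothing left after trimming), shorter than the minimum insert,
poly(A) artifact, or clean.  The precedence of these categories follows the
data-cleaning ledger layout (quality first, then adapter accounting, then
length, then composition).  Clean reads are collapsed to unique tags with
per-library counts; summaries cover length distributions and the
common/specific overlap statistics between two libraries.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .diffexp import round2

#: ledger categories in report order; keys are the exact table row names
CATEGORY_NAMES = {
    "total": "Total reads",
    "high_quality": "High quality",
    "adapter3_null": "3' adapter null",
    "insert_null": "Insert null",
    "adapter5": "5' adapter contaminants",
    "short": "Smaller than 18nt",
    "polya": "Poly(A)",
    "clean": "Clean reads",
}

#: default seed lengths for adapter detection
ADAPTER3_SEED = 8
ADAPTER5_SEED = 12

_VALID = set("ACGTN")


@dataclass
class LibrarySummary:
    """Cleaning ledger for one library.

    ``clean_total`` is the number of clean (redundant) reads and is the
    normalization denominator downstream.  Invariant:
    ``clean_total = high_quality - (adapter3_null + insert_null + adapter5
    + short + polya)``.
    """

    total_reads: int = 0
    high_quality: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    adapter5: int = 0
    short: int = 0
    polya: int = 0
    clean_total: int = 0

    def removed(self) -> int:
        return (self.adapter3_null + self.insert_null + self.adapter5
                + self.short + self.polya)

    def check(self) -> None:
        assert self.clean_total == self.high_quality - self.removed()
        assert self.high_quality <= self.total_reads

    def as_series(self) -> pd.Series:
        vals = {
            CATEGORY_NAMES["total"]: self.total_reads,
            CATEGORY_NAMES["high_quality"]: self.high_quality,
            CATEGORY_NAMES["adapter3_null"]: self.adapter3_null,
            CATEGORY_NAMES["insert_null"]: self.insert_null,
            CATEGORY_NAMES["adapter5"]: self.adapter5,
            CATEGORY_NAMES["short"]: self.short,
            CATEGORY_NAMES["polya"]: self.polya,
            CATEGORY_NAMES["clean"]: self.clean_total,
        }
        return pd.Series(vals, dtype="int64")


@dataclass
class CleanResult:
    inserts: list[tuple[str, str]]  # (read id, trimmed insert)
    summary: LibrarySummary
    categories: dict[str, str] = field(default_factory=dict)  # read id -> category


def _is_high_quality(seq: str, qual: str | None,
                     min_phred: int, max_low_frac: float) -> bool:
    if "N" in seq:
        return False
    if qual:
        low = sum(1 for q in qual if ord(q) - 33 < min_phred)
        if low / len(qual) >= max_low_frac:
            return False
    return True


def clean_reads(reads: Iterable[tuple[str, str, str | None]],
                adapter3: str, adapter5: str | None = None,
                min_len: int = 18, max_len: int = 30,
                min_phred: int = 20, max_low_frac: float = 0.10,
                polya_frac: float = 0.80) -> CleanResult:
    """Trim the 3' adapter and assign every read to exactly one category.

    ``reads`` yields ``(id, sequence, quality-or-None)``.  The 3' adapter is
    located by the leftmost exact match of its first 8 nt (so adapter-dimer
    reads trim to an empty insert and land in "Insert null"); a 5' adapter
    contaminant is flagged when the last 12 nt of the 5' adapter occur
    anywhere in the read.  A read is high quality when it contains no N and
    fewer than 10% of its bases fall below Phred 20.
    """
    if not adapter3:
        raise ValueError("3' adapter must be non-empty")
    seed3 = adapter3[:ADAPTER3_SEED]
    seed5 = adapter5[-ADAPTER5_SEED:] if adapter5 else None

    summary = LibrarySummary()
    inserts: list[tuple[str, str]] = []
    categories: dict[str, str] = {}

    for rid, seq, qual in reads:
        seq = seq.upper()
        summary.total_reads += 1
        if not set(seq) <= _VALID:
            warnings.warn(f"read {rid} contains non-ACGTN characters; "
                          "rejected as low quality", stacklevel=2)
            categories[rid] = "low_quality"
            continue
        if not _is_high_quality(seq, qual, min_phred, max_low_frac):
            categories[rid] = "low_quality"
            continue
        summary.high_quality += 1

        pos = seq.find(seed3)
        if pos < 0:
            summary.adapter3_null += 1
            categories[rid] = "adapter3_null"
            continue
        insert = seq[:pos]
        if seed5 and seed5 in seq:
            summary.adapter5 += 1
            categories[rid] = "adapter5"
            continue
        if not insert:
            summary.insert_null += 1
            categories[rid] = "insert_null"
            continue
        if len(insert) < min_len:
            summary.short += 1
            categories[rid] = "short"
            continue
        if len(insert) > max_len:
            # no over-length row exists in the ledger; an adapter this close
            # to the read end is not a credible hit
            summary.adapter3_null += 1
            categories[rid] = "adapter3_null"
            continue
        if insert.count("A") / len(insert) >= polya_frac:
            summary.polya += 1
            categories[rid] = "polya"
            continue
        summary.clean_total += 1
        categories[rid] = "clean"
        inserts.append((rid, insert))

    summary.check()
    return CleanResult(inserts=inserts, summary=summary, categories=categories)


def collapse(inserts: Iterable[str]) -> Counter[str]:
    """Collapse clean inserts to unique tags with redundant read counts."""
    return Counter(inserts)


def tag_table(per_library: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Unique-tag count matrix: rows are tag sequences, one column per library.

    The redundant total of a library is its column sum; the unique total is
    the number of rows with a positive count in that column.
    """
    df = pd.DataFrame(per_library).fillna(0).astype("int64")
    df.index.name = "seq"
    return df.sort_index()


def length_histogram(counts: Mapping[str, int] | pd.Series, *,
                     weighted: bool = True,
                     min_len: int = 18, max_len: int = 30) -> pd.Series:
    """Fraction of tags (or reads, when ``weighted``) at each insert length."""
    if isinstance(counts, pd.Series):
        counts = counts[counts > 0].to_dict()
    if not counts:
        raise ValueError("empty tag set")
    hist = {length: 0 for length in range(min_len, max_len + 1)}
    for seq, n in counts.items():
        hist[len(seq)] = hist.get(len(seq), 0) + (n if weighted else 1)
    total = sum(hist.values())
    out = pd.Series({k: v / total for k, v in sorted(hist.items())})
    out.index.name = "length"
    return out


def mean_frequency(redundant: int, unique: int) -> float:
    """Mean copies per unique tag, rounded to 2 dp as reported."""
    return round2(redundant / unique)


def overlap_stats(tags_a: Mapping[str, int] | pd.Series,
                  tags_b: Mapping[str, int] | pd.Series) -> pd.DataFrame:
    """Common/specific unique counts, redundant totals, and mean frequencies.

    Classes: ``total`` (union of both libraries), ``common`` (tags seen in
    both; redundant total counts reads from both libraries), and the two
    library-specific classes.  Mean frequency is redundant/unique per class.
    """
    a = dict(tags_a[tags_a > 0].items()) if isinstance(tags_a, pd.Series) else dict(tags_a)
    b = dict(tags_b[tags_b > 0].items()) if isinstance(tags_b, pd.Series) else dict(tags_b)
    common = a.keys() & b.keys()
    rows = {}
    uni = len(a) + len(b) - len(common)
    red = sum(a.values()) + sum(b.values())
    rows["total"] = (uni, red)
    red_c = sum(a[t] for t in common) + sum(b[t] for t in common)
    rows["common"] = (len(common), red_c)
    only_a = a.keys() - common
    only_b = b.keys() - common
    rows["a_specific"] = (len(only_a), sum(a[t] for t in only_a))
    rows["b_specific"] = (len(only_b), sum(b[t] for t in only_b))
    df = pd.DataFrame(rows, index=["unique", "redundant"]).T
    df["mean_frequency"] = [
        mean_frequency(r, u) if u else 0.0 for u, r in zip(df["unique"], df["redundant"])
    ]
    df.index.name = "class"
    return df
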