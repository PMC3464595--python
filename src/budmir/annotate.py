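"""Classification of unique tags into ncRNA classes and known miRNAs.

Tags that are fragments of structural non-coding RNAs (rRNA, snRNA, snoRNA,
tRNA) are identified by exact substring containment in a reference sequence
of that class, on either strand -- sequencer reads are fragments of these
long molecules.  Known mature miRNAs, by contrast, must match a reference
mature sequence exactly over their full length: only perfectly matched tags
are accepted as conserved miRNAs.  Every tag receives exactly one class, the
first match in precedence order; whatever is left is "unannotated" and feeds
the novel-miRNA discovery stage.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._util import normalize_seq, read_fasta, revcomp

#: class precedence, mirroring the category-table row order
DEFAULT_PRECEDENCE = ("rRNA", "snRNA", "snoRNA", "tRNA", "miRNA")

NCRNA_CLASSES = ("rRNA", "snRNA", "snoRNA", "tRNA")

_ARM_SUFFIX = re.compile(r"-(3p|5p)$")


@dataclass
class ReferenceSet:
    """Reference sequences of one class.

    For ``miRNA`` references every record carries a miRNA id and a family id
    (e.g. miR156a in family MIR156); for ncRNA classes only ids are kept.
    """

    label: str
    records: pd.DataFrame  # columns: id, family, seq

    def __post_init__(self) -> None:
        if self.records["id"].duplicated().any():
            raise ValueError(f"duplicate ids in {self.label} reference")
        self.records = self.records.assign(
            seq=self.records["seq"].map(normalize_seq))


def load_reference_fasta(path: str | Path) -> dict[str, ReferenceSet]:
    """Read a reference FASTA with ``>id|family|class`` headers.

    Returns one ReferenceSet per class present in the file.  ``family`` may
    be empty for ncRNA records.
    """
    rows = []
    for name, seq in read_fasta(path):
        parts = name.split("|")
        if len(parts) != 3:
            raise ValueError(f"reference header must be id|family|class: {name!r}")
        rows.append({"id": parts[0], "family": parts[1], "class": parts[2],
                     "seq": seq})
    df = pd.DataFrame(rows)
    return {
        label: ReferenceSet(label=label,
                            records=sub.drop(columns="class").reset_index(drop=True))
        for label, sub in df.groupby("class")
    }


def _substring_index(seqs: list[str]) -> str:
    """Concatenated text (both strands) for exact fragment containment."""
    both = list(seqs) + [revcomp(s) for s in seqs]
    return "#" + "#".join(both) + "#"


def classify_tags(tags: pd.DataFrame,
                  references: dict[str, ReferenceSet],
                  precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
                  ) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each tag one class; tally unique/redundant counts per class.

    ``tags`` is the unique-tag count matrix (index: sequence, one column per
    library).  ncRNA classes match by substring containment on either
    strand; the miRNA class by full-length identity.  Returns the per-tag
    class Series and the category tally with percentage columns.
    """
    if not references:
        warnings.warn("no references supplied; every tag is unannotated",
                      stacklevel=2)
    texts = {}
    mature: set[str] = set()
    for label in precedence:
        ref = references.get(label)
        if ref is None:
            continue
        if label == "miRNA":
            mature = set(ref.records["seq"])
        else:
            texts[label] = _substring_index(list(ref.records["seq"]))

    def assign(seq: str) -> str:
        for label in precedence:
            if label == "miRNA":
                if seq in mature:
                    return "miRNA"
            elif label in texts and seq in texts[label]:
                return label
        return "unannotated"

    classes = pd.Series([assign(s) for s in tags.index], index=tags.index,
                        name="class")
    order = [c for c in precedence if c in set(references)] + ["unannotated"]
    tally_rows = []
    for label in ["total"] + order:
        mask = slice(None) if label == "total" else (classes == label).values
        sub = tags.loc[mask]
        tally_rows.append({
            "class": label,
            "unique": int((sub.sum(axis=1) > 0).sum()),
            "redundant": int(sub.sum().sum()),
        })
    tally = pd.DataFrame(tally_rows).set_index("class")
    total_u = tally.loc["total", "unique"] or 1
    total_r = tally.loc["total", "redundant"] or 1
    tally["unique_pct"] = 100.0 * tally["unique"] / total_u
    tally["redundant_pct"] = 100.0 * tally["redundant"] / total_r
    return classes, tally


def match_known_mirnas(tags: pd.DataFrame, mature: ReferenceSet) -> pd.DataFrame:
    """Exact full-length matches of tags against the mature miRNA reference.

    Returns one row per (tag, reference record): tag sequence, mirna_id,
    family_id, and the per-library counts copied from the tag matrix.
    Duplicate mature sequences under different ids are all reported, with a
    warning.
    """
    if mature.records.empty:
        raise ValueError("mature reference set is empty")
    by_seq: dict[str, list[tuple[str, str]]] = {}
    for rec in mature.records.itertuples():
        by_seq.setdefault(rec.seq, []).append((rec.id, rec.family))
    dups = {s: v for s, v in by_seq.items() if len(v) > 1}
    if dups:
        warnings.warn(
            f"{len(dups)} mature sequence(s) shared by multiple ids; "
            "all are reported", stacklevel=2)
    rows = []
    for seq in tags.index:
        for mid, fam in by_seq.get(seq, ()):
            row = {"tag": seq, "mirna_id": mid, "family_id": fam}
            row.update({lib: int(tags.at[seq, lib]) for lib in tags.columns})
            rows.append(row)
    cols = ["tag", "mirna_id", "family_id", *tags.columns]
    return pd.DataFrame(rows, columns=cols)


def member_name(mirna_id: str) -> str:
    """miRNA id with any arm suffix (-5p/-3p) stripped; defines one member."""
    return _ARM_SUFFIX.sub("", mirna_id)


def family_summary(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-family member counts and per-library redundant read totals.

    A family member is a distinct miRNA base name: arm variants (miR171b and
    miR171b-3p) count once.  Read totals simply sum the hit counts, so the
    grand total equals the summed known-miRNA tag counts.
    """
    if hits.empty:
        return pd.DataFrame(columns=["members"])
    count_cols = [c for c in hits.columns
                  if c not in ("tag", "mirna_id", "family_id")]
    grouped = hits.groupby("family_id")
    out = grouped["mirna_id"].agg(lambda ids: ids.map(member_name).nunique())
    out = out.rename("members").to_frame()
    for c in count_cols:
        out[c] = grouped[c].sum()
    out.index.name = "family_id"
    return out.sort_index()
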