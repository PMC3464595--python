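"""Plant miRNA target prediction by complementarity scanning.

Every window of a transcript (same length as the miRNA, ungapped) is scored
against the miRNA under the plant target rules of the Allen/Schwab
tradition: per duplex position a Watson-Crick pair costs 0, a G:U wobble
0.5, and a mismatch 1.0, with penalties doubled in the 5' core region
(miRNA positions 2-13).  A window is a candidate site when it has at most
``max_mismatch`` mismatched positions (G:U wobbles counted separately by
default) and a total penalty no greater than ``max_penalty``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from ._util import normalize_seq, revcomp

CORE_START = 2   # 1-based miRNA position, inclusive
CORE_END = 13

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class TargetHit:
    """One miRNA/transcript site (ungapped; site length = miRNA length)."""

    mirna_id: str
    transcript_id: str
    start: int            # 0-based on the transcript
    penalty: float
    mismatches: int
    gu_pairs: int
    mirna_seq: str        # 5'->3'
    site_seq: str         # transcript window, 5'->3'
    alignment: str        # pairing line: '|' WC, 'o' G:U, ' ' mismatch


def score_duplex(mirna: str, site: str) -> tuple[float, int, int]:
    """Penalty, mismatch count and G:U count for one miRNA/site duplex.

    ``site`` is the transcript window 5'->3'; position i of the miRNA
    (1-based from its 5' end) pairs with site position ``len - i``.  Penalty
    weights double for miRNA positions 2-13.
    """
    m = normalize_seq(mirna)
    s = normalize_seq(site)
    if len(m) != len(s):
        raise ValueError("miRNA and site must have equal length")
    penalty = 0.0
    mismatches = 0
    gu = 0
    n = len(m)
    for i in range(n):
        pos = i + 1  # 1-based from miRNA 5'
        weight = 2.0 if CORE_START <= pos <= CORE_END else 1.0
        duo = (m[i], s[n - 1 - i])
        if duo in _WC:
            continue
        if duo in _GU:
            gu += 1
            penalty += 0.5 * weight
        else:
            mismatches += 1
            penalty += 1.0 * weight
    return penalty, mismatches, gu


def _alignment_line(mirna: str, site: str) -> str:
    m, s, n = normalize_seq(mirna), normalize_seq(site), len(mirna)
    out = []
    for i in range(n):
        duo = (m[i], s[n - 1 - i])
        out.append("|" if duo in _WC else "o" if duo in _GU else " ")
    return "".join(out)


def scan_targets(mirna_id: str, mirna_seq: str,
                 transcripts: Mapping[str, str],
                 max_mismatch: int = 3, max_penalty: float = 4.0,
                 count_gu_as_mismatch: bool = False) -> list[TargetHit]:
    """All candidate sites of one miRNA across a transcript set.

    A hit needs ``mismatches <= max_mismatch`` (fewer than four mismatches at
    the default) and ``penalty <= max_penalty``.  Hits are sorted by
    (penalty, transcript id, position) so the most plausible sites lead.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    m = normalize_seq(mirna_seq)
    if not 18 <= len(m) <= 26:
        raise ValueError(f"miRNA length {len(m)} outside 18-26 nt")
    hits: list[TargetHit] = []
    for tid in sorted(transcripts):
        seq = normalize_seq(transcripts[tid])
        for start in range(len(seq) - len(m) + 1):
            window = seq[start:start + len(m)]
            penalty, mism, gu = score_duplex(m, window)
            if count_gu_as_mismatch:
                mism += gu
            if mism <= max_mismatch and penalty <= max_penalty:
                hits.append(TargetHit(
                    mirna_id=mirna_id, transcript_id=tid, start=start,
                    penalty=penalty, mismatches=mism, gu_pairs=gu,
                    mirna_seq=m, site_seq=window,
                    alignment=_alignment_line(m, window)))
    hits.sort(key=lambda h: (h.penalty, h.transcript_id, h.start))
    return hits


def hits_table(hits: list[TargetHit]) -> pd.DataFrame:
    """Report layout; positions are 1-based in reports."""
    return pd.DataFrame([
        {
            "mirna": h.mirna_id,
            "transcript": h.transcript_id,
            "position": h.start + 1,
            "penalty": h.penalty,
            "mismatches": h.mismatches,
            "gu_pairs": h.gu_pairs,
            "mirna_seq": h.mirna_seq,
            "site_seq": h.site_seq,
        }
        for h in hits
    ], columns=["mirna", "transcript", "position", "penalty", "mismatches",
                "gu_pairs", "mirna_seq", "site_seq"])


def perfect_site(mirna_seq: str) -> str:
    """The transcript sequence a perfectly complementary site would have."""
    return revcomp(normalize_seq(mirna_seq))
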