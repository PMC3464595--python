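"""Novel miRNA discovery from genome-mapped tags and hairpin folding.

Unannotated tags are mapped to the genome (exact, full length, both
strands); each locus seeds two flanking windows that are folded with the
in-package energy model, and a candidate precursor is accepted only when it
behaves like a genuine Dicer substrate:

(a) the mature tag sits wholly on one arm of the stem, outside the terminal
    loop;
(b) the star strand implied by a 2 nt 3'-overhang duplex exists in the tag
    set with at least one read;
(c) the mature/star duplex has at most 4 mismatched positions and no
    asymmetric bulge larger than 2 nt;
(d) the precursor folds at or below the free-energy gate (default
    -18 kcal/mol);
(e) the precursor, trimmed to the minimal hairpin containing the duplex, is
    at least 50 nt long.

Rejection is a result, not an error: every failed criterion is recorded as
a machine-readable reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from ._util import revcomp
from .fold import FoldResult, MAX_LEN, fold

#: paired bases under the duplex rules (DNA alphabet; G:U wobble allowed)
_PAIRED = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class GenomeLocus:
    scaffold: str
    start: int            # 0-based half-open
    end: int
    strand: str
    tag: str

    def as_report(self) -> str:
        """1-based inclusive ``scaffold:start:end:strand`` report form."""
        return f"{self.scaffold}:{self.start + 1}:{self.end}:{self.strand}"


@dataclass
class HairpinThresholds:
    """Acceptance gates for a candidate precursor (all configurable)."""

    mfe_max: float = -18.0        # kcal/mol under the in-package model
    max_mismatch: int = 4         # duplex mismatches
    max_bulge: int = 2            # nt of asymmetric bulge within the duplex
    min_precursor: int = 50       # nt, after trimming to the duplex hairpin
    min_star_count: int = 1       # reads supporting the star
    min_mature_count: int = 5     # reads required to seed a candidate
    max_loci: int = 20            # tags mapping more often are repeats
    flank: int = 250              # nt of genomic context folded


@dataclass
class HairpinCandidate:
    """One evaluated precursor; ``accepted`` iff all criteria passed."""

    locus: GenomeLocus | None
    precursor: str
    precursor_start: int          # within the evaluated window
    mature: str
    mature_count: int
    star: str
    star_count: int
    arm: str                      # '5p' or '3p', '' if undetermined
    fold: FoldResult | None
    accepted: bool
    reasons: list[str] = field(default_factory=list)
    duplex_mismatches: int | None = None

    @property
    def length(self) -> int:
        return len(self.precursor)


def map_to_genome(tags: list[str], genome: Mapping[str, str],
                  max_loci: int = 20) -> list[GenomeLocus]:
    """Exact full-length loci of each tag on both strands of the genome.

    Tags hitting more than ``max_loci`` loci are dropped as repeats.  A tag
    equal to its own reverse complement yields distinct +/- loci at the same
    coordinates.
    """
    out: list[GenomeLocus] = []
    for tag in tags:
        loci: list[GenomeLocus] = []
        rc = revcomp(tag)
        for scaffold in sorted(genome):
            seq = genome[scaffold]
            for query, strand in ((tag, "+"), (rc, "-")):
                pos = seq.find(query)
                while pos >= 0:
                    loci.append(GenomeLocus(scaffold, pos, pos + len(tag),
                                            strand, tag))
                    pos = seq.find(query, pos + 1)
        if len(loci) <= max_loci:
            out.extend(loci)
    return out


def extract_windows(locus: GenomeLocus, genome: Mapping[str, str],
                    flank: int = 250, pad: int = 20,
                    ) -> list[tuple[int, str, int]]:
    """Two candidate precursor windows around a locus.

    Window A extends ``flank`` nt downstream of the tag (3'-arm candidates)
    and ``pad`` upstream; window B is the mirror image.  Both are clipped at
    scaffold edges.  Returns ``(genome_start, window_seq, tag_offset)``
    tuples oriented along the tag's strand (window sequence is
    reverse-complemented for minus-strand loci).
    """
    seq = genome[locus.scaffold]
    n = len(seq)
    spans = [(max(0, locus.start - pad), min(n, locus.end + flank)),
             (max(0, locus.start - flank), min(n, locus.end + pad))]
    out = []
    for a, b in spans:
        b = min(b, a + MAX_LEN)  # keep foldable
        a = max(a, b - MAX_LEN)
        window = seq[a:b]
        if locus.strand == "-":
            window = revcomp(window)
            offset = b - locus.end
        else:
            offset = locus.start - a
        out.append((a, window, offset))
    return out


def evaluate_candidate(window: str, mature_offset: int, mature_len: int,
                       tag_counts: Mapping[str, int],
                       thresholds: HairpinThresholds | None = None,
                       locus: GenomeLocus | None = None) -> HairpinCandidate:
    """Apply the full stem-loop criteria to one window/mature placement.

    The window is folded once to locate the duplex geometry; the precursor
    is then trimmed to the minimal hairpin containing the duplex, refolded,
    and gated on its free energy.
    """
    th = thresholds or HairpinThresholds()
    a = mature_offset
    b = a + mature_len - 1
    mature = window[a:b + 1]
    mature_count = int(tag_counts.get(mature, 0))
    reasons: list[str] = []

    def rejected(reason: str, **kw) -> HairpinCandidate:
        reasons.append(reason)
        return HairpinCandidate(
            locus=locus, precursor=window, precursor_start=0, mature=mature,
            mature_count=mature_count, star=kw.get("star", ""),
            star_count=kw.get("star_count", 0), arm=kw.get("arm", ""),
            fold=kw.get("fold"), accepted=False, reasons=reasons,
            duplex_mismatches=kw.get("mismatches"))

    wfold = fold(window)

    # (a) mature wholly on one arm, outside the terminal loop.  The arm is
    # the majority side of the mature's partners; a couple of bases paired
    # off into the flank by the window fold are treated as unpaired rather
    # than as evidence the mature straddles the loop.
    partners = [wfold.pairs[p] for p in range(a, b + 1) if wfold.pairs[p] >= 0]
    if any(a <= q <= b for q in partners):
        return rejected("mature pairs with itself (terminal loop)", fold=wfold)
    above = sum(q > b for q in partners)
    below = sum(q < a for q in partners)
    if min(above, below) > 4:
        return rejected("mature spans the terminal loop", fold=wfold)
    arm = "5p" if above >= below else "3p"

    # a stem is an anti-diagonal: p + partner(p) is nearly constant.  Use the
    # median diagonal of the on-arm partners to discard stray long-range
    # pairs the window fold may have formed with the flank.
    diags = sorted(p + wfold.pairs[p] for p in range(a, b + 1)
                   if wfold.pairs[p] >= 0 and (arm == "5p") == (wfold.pairs[p] > b))
    median_diag = diags[len(diags) // 2] if diags else -1

    def partner(p: int) -> int:
        """Fold partner restricted to the mature's duplex (-1 otherwise)."""
        q = wfold.pairs[p]
        if q < 0 or (arm == "5p") != (q > b):
            return -1
        if abs(p + q - median_diag) > 2 * th.max_bulge + 2:
            return -1
        return q

    pairs = tuple(partner(p) if a <= p <= b else wfold.pairs[p]
                  for p in range(len(window)))
    on_arm = sum(1 for p in range(a, b + 1) if pairs[p] >= 0)
    if on_arm < (mature_len - 2) - th.max_mismatch:
        return rejected("mature mostly unpaired", fold=wfold)

    # (b) star defined by the 2-nt 3'-overhang duplex on the stem diagonal:
    # mature position p pairs star position diag - p, and both strands
    # overhang by 2 nt at their 3' ends
    d = median_diag - a + 2
    c = median_diag - (b - 2)
    if c > d:
        return rejected("inverted duplex geometry", arm=arm, fold=wfold)
    c = max(0, c)
    d = min(len(window) - 1, d)
    star = window[c:d + 1]
    if not (d < a or c > b):
        return rejected("mature and star overlap", arm=arm, fold=wfold)
    star_count = int(tag_counts.get(star, 0))
    if star_count < th.min_star_count:
        return rejected("no miRNA* read support", arm=arm, star=star,
                        fold=wfold)

    # (c) duplex mismatches and bulge asymmetry
    mismatches = 0
    for k in range(mature_len - 2):
        p1, p2 = a + k, d - 2 - k
        if not 0 <= p2 < len(window) or (window[p1], window[p2]) not in _PAIRED:
            mismatches += 1
    if mismatches > th.max_mismatch:
        return rejected(f"duplex mismatches > {th.max_mismatch}", arm=arm,
                        star=star, star_count=star_count, fold=wfold,
                        mismatches=mismatches)
    for k in range(a, b + 1):
        if pairs[k] >= 0 and abs(k + pairs[k] - median_diag) > th.max_bulge:
            return rejected(f"asymmetric bulge > {th.max_bulge} nt", arm=arm,
                            star=star, star_count=star_count, fold=wfold,
                            mismatches=mismatches)

    # (e) trim to the minimal hairpin containing the duplex
    pstart, pend = min(a, c), max(b, d)
    precursor = window[pstart:pend + 1]
    if len(precursor) < th.min_precursor:
        return rejected(f"precursor shorter than {th.min_precursor} nt",
                        arm=arm, star=star, star_count=star_count, fold=wfold,
                        mismatches=mismatches)

    # (d) energy gate on the trimmed precursor
    pfold = fold(precursor)
    accepted = pfold.mfe <= th.mfe_max
    if not accepted:
        reasons.append(f"MFE above threshold {th.mfe_max} kcal/mol")
    return HairpinCandidate(
        locus=locus, precursor=precursor, precursor_start=pstart,
        mature=mature, mature_count=mature_count, star=star,
        star_count=star_count, arm=arm, fold=pfold, accepted=accepted,
        reasons=reasons, duplex_mismatches=mismatches)


def discover(tag_counts: Mapping[str, int], genome: Mapping[str, str],
             thresholds: HairpinThresholds | None = None,
             ) -> list[HairpinCandidate]:
    """Full discovery pass: seed tags, map, fold windows, evaluate, dedupe.

    Seeds are tags with at least ``min_mature_count`` reads.  For each locus
    the best window verdict is kept (accepted beats rejected, then lower
    MFE); overlapping accepted candidates on one strand collapse to the one
    with the higher mature count, so a star tag seeding the same hairpin as
    its mature does not duplicate the locus.
    """
    th = thresholds or HairpinThresholds()
    seeds = sorted(s for s, n in tag_counts.items() if n >= th.min_mature_count)
    loci = map_to_genome(seeds, genome, max_loci=th.max_loci)
    candidates: list[HairpinCandidate] = []
    for locus in loci:
        best: HairpinCandidate | None = None
        windows = extract_windows(locus, genome, flank=th.flank)
        if th.flank > 80:
            # long flanks can fold over a genuine hairpin; a short-flank
            # pass lets the local stem-loop dominate
            windows += extract_windows(locus, genome, flank=80)
        for wstart, window, offset in windows:
            cand = evaluate_candidate(window, offset, len(locus.tag),
                                      tag_counts, th, locus=locus)
            if cand.accepted and cand.locus is not None:
                # precursor coordinates back onto the genome
                if locus.strand == "+":
                    gs = wstart + cand.precursor_start
                else:
                    gs = wstart + len(window) - (cand.precursor_start
                                                 + len(cand.precursor))
                cand.locus = GenomeLocus(locus.scaffold, gs,
                                         gs + len(cand.precursor),
                                         locus.strand, locus.tag)
            if best is None or _better(cand, best):
                best = cand
        if best is not None:
            candidates.append(best)

    return _dedupe(candidates)


def _better(a: HairpinCandidate, b: HairpinCandidate) -> bool:
    if a.accepted != b.accepted:
        return a.accepted
    ae = a.fold.mfe if a.fold else 0.0
    be = b.fold.mfe if b.fold else 0.0
    return ae < be


def _dedupe(candidates: list[HairpinCandidate]) -> list[HairpinCandidate]:
    accepted = [c for c in candidates if c.accepted]
    rejected = [c for c in candidates if not c.accepted]
    accepted.sort(key=lambda c: (-c.mature_count, c.locus.scaffold
                                 if c.locus else "", c.locus.start if c.locus else 0))
    kept: list[HairpinCandidate] = []
    for cand in accepted:
        clash = False
        for other in kept:
            if (cand.locus and other.locus
                    and cand.locus.scaffold == other.locus.scaffold
                    and cand.locus.strand == other.locus.strand
                    and cand.locus.start < other.locus.end
                    and other.locus.start < cand.locus.end):
                clash = True
                break
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.locus.scaffold, c.locus.start) if c.locus
              else ("", 0))
    return kept + rejected


def first_nt_bias(matures: list[str]) -> pd.DataFrame:
    """Per-length first-nucleotide fractions (columns A, C, G, U).

    Mirrors the standard accuracy diagnostic: genuine plant miRNAs of
    21-22 nt start with a 5' U far more often than chance.
    """
    if not matures:
        return pd.DataFrame(columns=list("ACGU"))
    rows: dict[int, dict[str, int]] = {}
    for m in matures:
        first = m[0].upper().replace("T", "U")
        rows.setdefault(len(m), {b: 0 for b in "ACGU"})
        rows[len(m)][first] += 1
    df = pd.DataFrame(rows).T.sort_index()[list("ACGU")]
    df.index.name = "length"
    return df.div(df.sum(axis=1), axis=0)


def candidates_table(candidates: list[HairpinCandidate]) -> pd.DataFrame:
    """Report table mirroring the novel-miRNA summary layout."""
    rows = []
    for c in candidates:
        rows.append({
            "mature": c.mature,
            "length_mature": len(c.mature),
            "counts": f"{c.mature_count}/{c.star_count}",
            "location": c.locus.as_report() if c.locus else "",
            "length_precursor": c.length,
            "arm": c.arm,
            "mfe": c.fold.mfe if c.fold else float("nan"),
            "accepted": c.accepted,
            "reasons": ";".join(c.reasons),
        })
    return pd.DataFrame(rows, columns=["mature", "length_mature", "counts",
                                       "location", "length_precursor", "arm",
                                       "mfe", "accepted", "reasons"])
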