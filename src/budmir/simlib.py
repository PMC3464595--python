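"""Synthetic small-RNA dataset generator with full ground truth.

Emulates a two-condition (perfect vs imperfect flower bud) small-RNA
sequencing experiment end to end: a genome with planted miRNA hairpin loci,
reference sets of mature miRNAs and structural ncRNAs, and two fixed-length
read libraries containing planted miRNA tags (including differential and
condition-specific ones), novel-hairpin mature + low-count star tags, ncRNA
fragments, and the contaminant classes a cleaning ledger tracks (adapter
nulls, 5' adapter carry-over, adapter dimers, short inserts, poly(A)
artifacts, low-quality reads).  Everything is driven by one seeded RNG, so a
given spec is byte-reproducible, and every read is traceable to exactly one
truth record.

Planted hairpins are built so the mature and its star form a proper Dicer
duplex: star = reverse complement of the mature minus its last two bases,
plus a 2 nt 3' overhang, with a controlled number of stem mismatches.  Star
reads are emitted at a few percent of the mature abundance, matching the low
star counts real libraries show.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from ._util import revcomp, write_fasta, write_fastq

PERFECT, IMPERFECT = "perfect", "imperfect"
LIBRARIES = (PERFECT, IMPERFECT)

#: Illumina small-RNA adapters (the platform's published sequences; the
#: study itself does not state which were used)
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

#: insert length distribution peaked at 21 and 24 nt, as plant small-RNA
#: libraries are (miRNAs ~21 nt, heterochromatic siRNAs ~24 nt).  Capped at
#: 28 nt: with 36-cycle reads an insert longer than that leaves no room for
#: the adapter seed, so such species would be undetectable by construction.
DEFAULT_LENGTH_DIST = {
    18: 0.02, 19: 0.03, 20: 0.05, 21: 0.30, 22: 0.08, 23: 0.07, 24: 0.33,
    25: 0.05, 26: 0.04, 27: 0.02, 28: 0.01,
}

#: per-category contamination rates (fractions of total reads), shaped like
#: a real cleaning ledger
DEFAULT_CONTAMINATION = {
    "low_quality": 0.019,
    "adapter3_null": 0.0024,
    "insert_null": 0.0003,
    "adapter5": 0.0016,
    "short": 0.0022,
    "polya": 0.0003,
}


@dataclass(frozen=True)
class HairpinDesign:
    """One planted novel-miRNA locus."""

    name: str
    mature: str                      # 20-23 nt, genome-sense
    arm: str = "5p"                  # which arm carries the mature
    loop_len: int = 13               # unpaired nt between the duplex arms
    n_mismatch: int = 1              # planted stem mismatches (<= 4)
    abundance: tuple[float, float] = (2000.0, 2000.0)  # expected reads/library
    strand: str = "+"

    def validate(self) -> None:
        if not 18 <= len(self.mature) <= 26:
            raise ValueError(
                f"hairpin {self.name}: mature length {len(self.mature)} "
                "is outside what a stem can hold (18-26 nt)")
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"hairpin {self.name}: arm must be 5p or 3p")
        if self.loop_len < 3:
            raise ValueError(f"hairpin {self.name}: loop must be >= 3 nt")
        if not 0 <= self.n_mismatch <= 4:
            raise ValueError(f"hairpin {self.name}: at most 4 stem mismatches")
        if min(self.abundance) < 0:
            raise ValueError(f"hairpin {self.name}: abundances must be >= 0")


@dataclass(frozen=True)
class KnownMirnaDesign:
    """One planted known mature miRNA."""

    mirna_id: str
    family: str
    seq: str
    abundance: tuple[float, float]   # expected reads (perfect, imperfect)

    @property
    def fold(self) -> float:
        a, b = self.abundance
        if min(a, b) == 0:
            return float("inf")
        return max(a / b, b / a)


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the scenario the pipeline is validated on: two
    libraries of 1e5 reads, 5 planted hairpins with star reads at 2% of the
    mature abundance, 61 known matures in 24 families of which three are
    3-fold differential and two condition-specific, an ncRNA background and
    ledger-like contamination rates.
    """

    seed: int = 0
    n_scaffolds: int = 3
    scaffold_len: int = 60_000
    planted_hairpins: list[HairpinDesign] | None = None
    planted_known_mirnas: list[KnownMirnaDesign] | None = None
    ncrna_fraction: float = 0.13
    known_mirna_fraction: float = 0.11
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    contamination: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINATION))
    library_depth: int = 100_000
    read_length: int = 36
    star_fraction: float = 0.02
    length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    n_background_species: int = 1500
    n_genomic_background: int = 8
    degraded_quality: bool = False

    def resolved(self) -> "SimulationSpec":
        """Fill in default hairpin / known-miRNA designs (seed-dependent)."""
        rng = np.random.default_rng((self.seed, 0xD0))
        spec = self
        if spec.planted_hairpins is None:
            spec = replace(spec, planted_hairpins=default_hairpins(rng, self))
        if spec.planted_known_mirnas is None:
            spec = replace(
                spec, planted_known_mirnas=default_known_mirnas(rng, spec))
        for h in spec.planted_hairpins:
            h.validate()
        for k in spec.planted_known_mirnas:
            a, b = k.abundance
            if a < 0 or b < 0:
                raise ValueError(f"{k.mirna_id}: negative abundance")
        return spec


# ---------------------------------------------------------------------------
# random-sequence helpers (all avoid adapter seeds so cleaning categories
# stay unambiguous and planted category counts are exactly recoverable)

def _forbidden_seeds(spec: SimulationSpec) -> tuple[str, ...]:
    return (spec.adapter3[:8], spec.adapter5[-12:])


def _random_seq(rng: np.random.Generator, length: int,
                forbidden: tuple[str, ...] = ()) -> str:
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if not any(f in seq or f in revcomp(seq) for f in forbidden):
            return seq
    raise RuntimeError("could not sample a sequence avoiding adapter seeds")


def _assign_lengths(weights: np.ndarray, dist: dict[int, float],
                    rng: np.random.Generator) -> np.ndarray:
    """Assign one insert length per species so the *read-mass* spectrum
    matches ``dist``.

    Species weights are heavy-tailed, so drawing lengths i.i.d. per species
    would not reproduce the planted distribution at the read level; instead
    each length has a weight budget and species (largest first) draw lengths
    with probability proportional to the remaining budget.
    """
    lengths = sorted(dist)
    budget = np.array([dist[L] for L in lengths], dtype=float)
    base = budget / budget.sum()
    budget = base * float(weights.sum())
    out = np.empty(len(weights), dtype=np.int64)
    for idx in np.argsort(-weights, kind="stable"):
        w = float(weights[idx])
        eligible = budget >= w          # never overshoot a length's budget
        p = np.where(eligible, budget, 0.0)
        if p.sum() <= 0:
            p = np.clip(budget, 0.0, None)
        if p.sum() <= 0:
            p = base.copy()
        p = p / p.sum()
        j = int(rng.choice(len(lengths), p=p))
        out[idx] = lengths[j]
        budget[j] -= w
    return out


# ---------------------------------------------------------------------------
# hairpin construction

#: bases that neither Watson-Crick nor wobble pair with the key
_NONPAIRING = {"A": "CG", "C": "ACT", "G": "AG", "T": "CT"}


def star_sequence(mature: str, overhang: str) -> str:
    """Star strand of a canonical Dicer duplex with 2 nt 3' overhangs.

    The star pairs with all but the last two mature bases, then carries its
    own 2 nt 3' overhang (``overhang``).
    """
    if len(overhang) != 2:
        raise ValueError("star 3' overhang must be 2 nt")
    return revcomp(mature[:-2]) + overhang


#: margin below the -18 kcal/mol gate a planted precursor must clear, so
#: trimming and flanking context cannot push it over the threshold
_DESIGN_MFE = -20.0


def _design_folds(precursor: str, mature_start: int, mature_len: int,
                  n_mismatch: int) -> bool:
    """Does the precursor's MFE fold realize the designed duplex?

    Requires the energy margin, all paired mature positions on the designed
    stem diagonal (within 2 nt), and enough of the duplex actually paired.
    """
    from .fold import fold as _fold  # deferred: simlib is import-light
    f = _fold(precursor)
    if f.mfe > _DESIGN_MFE:
        return False
    diag = len(precursor) - 3
    paired = 0
    for p in range(mature_start, mature_start + mature_len):
        q = f.pairs[p]
        if q < 0:
            continue
        if abs(p + q - diag) > 2:
            return False
        paired += 1
    return paired >= (mature_len - 2) - 2 * n_mismatch - 1


def build_precursor(design: HairpinDesign,
                    rng: np.random.Generator,
                    forbidden: tuple[str, ...] = (),
                    validate: bool = True,
                    max_tries: int = 60) -> tuple[str, str]:
    """Precursor sequence and the star read for one hairpin design.

    The mature/star duplex is exact except for ``n_mismatch`` planted stem
    mutations (never within 3 nt of the duplex ends, so the overhang anchors
    stay paired; mutated bases are chosen so they cannot pair at all).  The
    arrangement (overhang, mismatch placement, loop sequence) is resampled
    until the precursor's minimum-energy fold realizes the designed duplex;
    a design for which no arrangement works is rejected as infeasible.
    """
    design.validate()
    mature = design.mature.upper()
    L = len(mature)
    for _ in range(max_tries):
        overhang = _random_seq(rng, 2)
        star = list(star_sequence(mature, overhang))
        # star positions 0 .. L-3 pair the mature; keep both ends anchored
        mutable = list(range(3, L - 5))
        rng.shuffle(mutable)
        for pos in sorted(mutable[:design.n_mismatch]):
            partner = mature[L - 3 - pos]
            star[pos] = rng.choice(list(_NONPAIRING[partner]))
        star_read = "".join(star)
        loop = _random_seq(rng, design.loop_len, forbidden)
        if design.arm == "5p":
            precursor = mature + loop + star_read
            mstart = 0
        else:
            precursor = star_read + loop + mature
            mstart = len(star_read) + len(loop)
        if any(f in precursor or f in revcomp(precursor) for f in forbidden):
            continue
        if not validate or _design_folds(precursor, mstart, L,
                                         design.n_mismatch):
            return precursor, star_read
    raise ValueError(
        f"infeasible hairpin design {design.name}: no arrangement of "
        "mismatches/loop folds into the designed mature/star duplex at "
        f"{_DESIGN_MFE} kcal/mol")


def default_hairpins(rng: np.random.Generator,
                     spec: SimulationSpec) -> list[HairpinDesign]:
    """Five hairpins, mostly 21-22 nt matures with a 5' U bias.

    Default abundances are expressed for a 1e5-read library and scale
    linearly with the requested depth.
    """
    forbidden = _forbidden_seeds(spec)
    scale = spec.library_depth / 1e5
    designs = []
    arms = ["5p", "3p", "5p", "3p", "5p"]
    lengths = [21, 21, 22, 21, 23]
    for i in range(5):
        while True:  # resample matures whose stem would be too weak
            first = "T" if rng.random() < 0.7 else rng.choice(list("ACG"))
            mature = first + _random_seq(rng, lengths[i] - 1, forbidden)
            design = HairpinDesign(
                name=f"novel-{i + 1}", mature=mature, arm=arms[i],
                loop_len=int(rng.integers(11, 16)),
                n_mismatch=int(rng.integers(0, 3)),
                abundance=(float(rng.integers(800, 3000)) * scale,) * 2,
                strand="+" if i % 2 == 0 else "-")
            try:
                build_precursor(design, np.random.default_rng(rng.integers(2**31)),
                                forbidden, max_tries=20)
            except ValueError:
                continue
            designs.append(design)
            break
    return designs


def default_known_mirnas(rng: np.random.Generator,
                         spec: SimulationSpec) -> list[KnownMirnaDesign]:
    """61 matures in 24 families; 3 are 3-fold differential, 2 specific."""
    forbidden = _forbidden_seeds(spec)
    scale = spec.library_depth / 1e5
    n_families = 24
    members_per_family = [1] * n_families
    for _ in range(61 - n_families):  # distribute the remaining members
        members_per_family[int(rng.integers(0, n_families))] += 1
    designs: list[KnownMirnaDesign] = []
    for fam_i, n_members in enumerate(members_per_family):
        fam = f"MIR{900 + fam_i}"
        for m_i in range(n_members):
            length = int(rng.choice([20, 21, 21, 21, 22, 22, 24]))
            first = "T" if rng.random() < 0.6 else rng.choice(list("ACG"))
            seq = first + _random_seq(rng, length - 1, forbidden)
            base = 10 ** rng.uniform(0.7, 3.0) * scale  # 5 .. 1000 per 1e5
            designs.append(KnownMirnaDesign(
                mirna_id=f"miR{900 + fam_i}{chr(97 + m_i)}", family=fam,
                seq=seq, abundance=(base, base)))
    # three 3-fold differential (up in the imperfect library), well expressed
    for j, k in enumerate((0, 1, 2)):
        d = designs[k]
        base = 300.0 * (j + 1) * scale
        designs[k] = replace(d, abundance=(base, 3.0 * base))
    # two condition-specific
    designs[3] = replace(designs[3], abundance=(150.0 * scale, 0.0))
    designs[4] = replace(designs[4], abundance=(0.0, 150.0 * scale))
    return designs


# ---------------------------------------------------------------------------
# genome + references

@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    hairpins: pd.DataFrame       # name, scaffold, start, end, strand, arm, ...
    known: pd.DataFrame          # mirna_id, family, seq, expected per library
    reads: pd.DataFrame | None = None      # read_id, library, category, species
    species: pd.DataFrame | None = None    # species, class, seq

    def planted_counts(self, library: str) -> pd.Series:
        """Realized clean-read counts per species sequence in one library."""
        df = self.reads
        assert df is not None
        sub = df[(df["library"] == library) & (df["category"] == "clean")]
        return sub.groupby("insert").size()


def make_genome(spec: SimulationSpec) -> tuple[dict[str, str], TruthTable]:
    """Random scaffolds with each planted hairpin inserted exactly once.

    The background is i.i.d. uniform nucleotides; after assembly every
    mature is verified to occur exactly once genome-wide (both strands), and
    the genome is rebuilt with fresh background in the rare collision case.
    """
    spec = spec.resolved()
    assert spec.planted_hairpins is not None
    rng = np.random.default_rng((spec.seed, 0x9E))
    forbidden = _forbidden_seeds(spec)

    precursors = {}
    for design in spec.planted_hairpins:
        precursors[design.name] = build_precursor(design, rng, forbidden)

    for _attempt in range(20):
        genome = {
            f"scaffold_{i + 1}": "".join(
                rng.choice(list("ACGT"), size=spec.scaffold_len))
            for i in range(spec.n_scaffolds)
        }
        rows = []
        ok = True
        for design in spec.planted_hairpins:
            precursor, star = precursors[design.name]
            scaffold = f"scaffold_{int(rng.integers(0, spec.n_scaffolds)) + 1}"
            start = int(rng.integers(100, spec.scaffold_len - len(precursor) - 100))
            inserted = precursor if design.strand == "+" else revcomp(precursor)
            s = genome[scaffold]
            genome[scaffold] = s[:start] + inserted + s[start + len(inserted):]
            rows.append({
                "name": design.name, "scaffold": scaffold, "start": start,
                "end": start + len(precursor), "strand": design.strand,
                "arm": design.arm, "mature": design.mature, "star": star,
                "precursor": precursor,
                "abundance_perfect": design.abundance[0],
                "abundance_imperfect": design.abundance[1],
            })
        # uniqueness check: each mature occurs exactly once genome-wide
        for design in spec.planted_hairpins:
            hits = 0
            for s in genome.values():
                hits += s.count(design.mature) + revcomp(s).count(design.mature)
            if hits != 1:
                ok = False
        if ok:
            break
    else:
        raise RuntimeError("could not build a collision-free genome")

    hairpins = pd.DataFrame(rows)
    known = pd.DataFrame([
        {"mirna_id": k.mirna_id, "family": k.family, "seq": k.seq,
         "expected_perfect": k.abundance[0],
         "expected_imperfect": k.abundance[1]}
        for k in (spec.planted_known_mirnas or [])
    ])
    return genome, TruthTable(hairpins=hairpins, known=known)


def make_references(spec: SimulationSpec) -> pd.DataFrame:
    """ncRNA + mature miRNA reference records (id, family, class, seq)."""
    spec = spec.resolved()
    rng = np.random.default_rng((spec.seed, 0x5EF))
    forbidden = _forbidden_seeds(spec)
    rows = []
    plan = [("rRNA", 4, (900, 1800)), ("tRNA", 8, (70, 90)),
            ("snRNA", 4, (100, 200)), ("snoRNA", 4, (70, 150))]
    for label, n, (lo, hi) in plan:
        for i in range(n):
            rows.append({
                "id": f"{label.lower()}-{i + 1}", "family": "",
                "class": label,
                "seq": _random_seq(rng, int(rng.integers(lo, hi)), forbidden)})
    for k in spec.planted_known_mirnas or []:
        rows.append({"id": k.mirna_id, "family": k.family, "class": "miRNA",
                     "seq": k.seq})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# libraries

def _build_read(insert: str, adapter3: str, read_length: int,
                rng: np.random.Generator) -> str:
    tail = insert + adapter3
    while len(tail) < read_length:
        tail += "".join(rng.choice(list("ACGT"), size=read_length - len(tail)))
    return tail[:read_length]


def simulate_libraries(genome: dict[str, str], spec: SimulationSpec,
                       truth: TruthTable | None = None,
                       ) -> tuple[dict[str, list[tuple[str, str, str]]], TruthTable]:
    """Two FASTQ-ready read lists plus the per-read truth table.

    Reads are ``insert + 3' adapter`` padded with random sequence to the
    fixed read length, constant high quality (Phred 40) unless
    ``degraded_quality``.  Planted species counts are multinomial at the
    requested depth; contaminant classes are injected at the spec rates.
    """
    spec = spec.resolved()
    assert spec.planted_hairpins is not None and spec.planted_known_mirnas is not None
    rng = np.random.default_rng((spec.seed, 0x11B))
    forbidden = _forbidden_seeds(spec)
    if truth is None:
        _, truth = make_genome(spec)
    if spec.library_depth == 0:
        warnings.warn("library depth is 0; emitting empty libraries",
                      stacklevel=2)
        truth.reads = pd.DataFrame(
            columns=["read_id", "library", "category", "species", "class",
                     "insert"])
        truth.species = pd.DataFrame(columns=["species", "class", "seq"])
        return {lib: [] for lib in LIBRARIES}, truth

    # --- species pools shared by both libraries -------------------------
    # weights are fixed first; insert lengths are then budget-assigned so
    # the read-level length spectrum matches spec.length_dist
    ncrna_refs = make_references(spec)
    ncrna_refs = ncrna_refs[ncrna_refs["class"] != "miRNA"]
    n_frag = 400
    frag_weights = np.ones(n_frag) / n_frag
    genomic_weights = np.linspace(3.0, 1.0,
                                  num=max(spec.n_genomic_background, 1))
    genomic_weights /= genomic_weights.sum()
    # Zipf-ish weights so a handful of background tags are well expressed
    bg_weights = 1.0 / np.arange(1, spec.n_background_species + 1) ** 1.1
    bg_weights /= bg_weights.sum()

    cont_total = sum(spec.contamination.values())
    planted_frac = sum(
        (k.abundance[0] + k.abundance[1]) / 2
        for k in spec.planted_known_mirnas) / spec.library_depth
    planted_frac += sum(
        (1 + spec.star_fraction) * (h.abundance[0] + h.abundance[1]) / 2
        for h in spec.planted_hairpins) / spec.library_depth
    rest0 = max(1e-9, 1.0 - cont_total - planted_frac - spec.ncrna_fraction)
    mass = np.concatenate([
        spec.ncrna_fraction * frag_weights,
        rest0 * 0.02 * genomic_weights,
        rest0 * 0.98 * bg_weights,
    ])
    pool_lengths = _assign_lengths(mass, spec.length_dist, rng)

    ncrna_fragments: list[tuple[str, str, str]] = []   # (id, class, insert)
    for i in range(n_frag):
        length = int(pool_lengths[i])
        for _ in range(50):
            ref = ncrna_refs.iloc[int(rng.integers(0, len(ncrna_refs)))]
            if length >= len(ref["seq"]):
                continue
            start = int(rng.integers(0, len(ref["seq"]) - length))
            frag = ref["seq"][start:start + length]
            if any(f in frag for f in forbidden):
                continue
            ncrna_fragments.append((f"frag:{ref['id']}:{start}",
                                    ref["class"], frag))
            break

    genomic: list[tuple[str, str]] = []
    hairpin_spans = {
        (r.scaffold, r.start, r.end) for r in truth.hairpins.itertuples()}
    names = sorted(genome)
    for i in range(spec.n_genomic_background):
        length = int(pool_lengths[n_frag + i])
        while True:
            scaffold = names[int(rng.integers(0, len(names)))]
            start = int(rng.integers(0, len(genome[scaffold]) - length))
            if any(sc == scaffold and start < e and start + length > s
                   for sc, s, e in hairpin_spans):
                continue
            frag = genome[scaffold][start:start + length]
            if any(f in frag or f in revcomp(frag) for f in forbidden):
                continue
            if sum(g.count(frag) + revcomp(g).count(frag)
                   for g in genome.values()) != 1:
                continue
            genomic.append((f"genomic:{scaffold}:{start}", frag))
            break

    background: list[tuple[str, str]] = []
    for i in range(spec.n_background_species):
        length = int(pool_lengths[n_frag + spec.n_genomic_background + i])
        background.append((f"bg:{i}", _random_seq(rng, length, forbidden)))

    libraries: dict[str, list[tuple[str, str, str]]] = {}
    read_rows = []
    species_rows = {}

    for lib_i, lib in enumerate(LIBRARIES):
        reads: list[tuple[str, str, str]] = []
        # expected count per emission species
        species: list[tuple[str, str, str, float]] = []  # id, class, insert, w
        for k in spec.planted_known_mirnas:
            species.append((k.mirna_id, "miRNA", k.seq, k.abundance[lib_i]))
        for h, row in zip(spec.planted_hairpins, truth.hairpins.itertuples()):
            species.append((h.name, "novel_mature", h.mature, h.abundance[lib_i]))
            star_w = spec.star_fraction * h.abundance[lib_i]
            species.append((f"{h.name}*", "novel_star", row.star, star_w))
        depth = spec.library_depth
        cont_rates = dict(spec.contamination)
        cont_total = sum(cont_rates.values())
        planted_frac = sum(s[3] for s in species) / depth
        ncrna_frac = spec.ncrna_fraction
        rest = 1.0 - cont_total - planted_frac - ncrna_frac
        if rest <= 0:
            raise ValueError("planted abundances exceed the library depth")
        for (sid, cls, frag), w in zip(ncrna_fragments, frag_weights):
            species.append((sid, cls, frag, ncrna_frac * depth * w))
        for (sid, frag), w in zip(genomic, genomic_weights):
            species.append((sid, "unannotated", frag, rest * depth * 0.02 * w))
        for (sid, frag), w in zip(background, bg_weights):
            species.append((sid, "unannotated", frag, rest * depth * 0.98 * w))
        for name in sorted(cont_rates):
            species.append((f"contaminant:{name}", name, "", cont_rates[name] * depth))

        weights = np.array([s[3] for s in species], dtype=float)
        counts = rng.multinomial(depth, weights / weights.sum())

        emitted: list[tuple[str, str, str]] = []   # species id, category, insert
        for (sid, cls, insert, _w), n in zip(species, counts):
            for _ in range(n):
                emitted.append((sid, cls, insert))

        order = rng.permutation(len(emitted))
        for out_i, idx in enumerate(order):
            sid, cls, insert = emitted[idx]
            rid = f"{lib}_{out_i}"
            qual_hi = "I" * spec.read_length
            if cls == "low_quality":
                seq = _build_read(_random_seq(rng, 21, forbidden),
                                  spec.adapter3, spec.read_length, rng)
                qual = ("#" * (spec.read_length // 2)
                        + "I" * (spec.read_length - spec.read_length // 2))
                category = "low_quality"
            elif cls == "adapter3_null":
                seq = _random_seq(rng, spec.read_length, forbidden)
                qual, category = qual_hi, "adapter3_null"
            elif cls == "insert_null":
                # adapter dimer: the 3' adapter starts at position 0
                seq = _build_read("", spec.adapter3, spec.read_length, rng)
                qual, category = qual_hi, "insert_null"
            elif cls == "adapter5":
                core = _random_seq(rng, 10, forbidden)
                seq = (spec.adapter5[-12:] + core + spec.adapter3)[:spec.read_length]
                qual, category = qual_hi, "adapter5"
            elif cls == "short":
                seq = _build_read(_random_seq(rng, int(rng.integers(8, 17)),
                                              forbidden),
                                  spec.adapter3, spec.read_length, rng)
                qual, category = qual_hi, "short"
            elif cls == "polya":
                length = int(rng.integers(18, 26))
                n_other = max(1, int(length * 0.1))
                ins = list("A" * length)
                for p in rng.choice(length, size=n_other, replace=False):
                    ins[p] = rng.choice(list("CGT"))
                seq = _build_read("".join(ins), spec.adapter3,
                                  spec.read_length, rng)
                qual, category = qual_hi, "polya"
            else:
                seq = _build_read(insert, spec.adapter3, spec.read_length, rng)
                qual = qual_hi
                category = "clean"
                if spec.degraded_quality and rng.random() < 0.05:
                    qual = "#" * spec.read_length
                    category = "low_quality"
            reads.append((rid, seq, qual))
            read_rows.append({"read_id": rid, "library": lib,
                              "category": category, "species": sid,
                              "class": cls, "insert": insert if category == "clean" else ""})
        libraries[lib] = reads
        for sid, cls, insert, w in species:
            species_rows.setdefault(sid, {"species": sid, "class": cls,
                                          "seq": insert})
            species_rows[sid][f"expected_{lib}"] = w

    truth.reads = pd.DataFrame(read_rows)
    truth.species = pd.DataFrame(list(species_rows.values()))
    return libraries, truth


def make_transcripts(seed: int, mirnas: dict[str, str],
                     n_transcripts: int = 50, transcript_len: int = 500,
                     sites_per_mirna: int = 2, n_mismatch: int = 0,
                     ) -> tuple[dict[str, str], pd.DataFrame]:
    """Random transcripts with planted miRNA target sites.

    Each miRNA gets ``sites_per_mirna`` planted sites: the reverse
    complement of the miRNA with ``n_mismatch`` substitutions outside the
    seed-adjacent ends, written into a random transcript at a recorded
    position.  Returns the transcript dict and a truth table (mirna_id,
    transcript_id, start, n_mismatch).
    """
    rng = np.random.default_rng((seed, 0x7C))
    transcripts = {
        f"tx_{i + 1}": _random_seq(rng, transcript_len)
        for i in range(n_transcripts)
    }
    names = sorted(transcripts)
    rows = []
    for mid in sorted(mirnas):
        mseq = mirnas[mid].upper().replace("U", "T")
        for _ in range(sites_per_mirna):
            site = list(revcomp(mseq))
            positions = rng.choice(np.arange(2, len(site) - 2),
                                   size=n_mismatch, replace=False)
            for p in positions:
                # mismatch against the miRNA base pairing this site position
                partner = mseq[len(site) - 1 - int(p)]
                site[int(p)] = rng.choice(list(_NONPAIRING[partner]))
            for _try in range(100):  # avoid clobbering a planted site
                tid = names[int(rng.integers(0, len(names)))]
                start = int(rng.integers(0, transcript_len - len(site)))
                if all(r["transcript_id"] != tid
                       or start >= r["start"] + len(site)
                       or start + len(site) <= r["start"] for r in rows):
                    break
            s = transcripts[tid]
            transcripts[tid] = (s[:start] + "".join(site)
                                + s[start + len(site):])
            rows.append({"mirna_id": mid, "transcript_id": tid,
                         "start": start, "n_mismatch": n_mismatch})
    return transcripts, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk dataset

def write_dataset(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a complete dataset; returns the path map.

    Files: genome FASTA, reference FASTA (``id|family|class`` headers), two
    FASTQ libraries, truth tables as TSV, planted hairpin loci as BED
    (0-based half-open).
    """
    spec = spec.resolved()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = make_genome(spec)
    libraries, truth = simulate_libraries(genome, spec, truth)
    refs = make_references(spec)

    paths = {
        "genome": out / "genome.fa",
        "references": out / "references.fa",
        "perfect": out / "perfect.fastq",
        "imperfect": out / "imperfect.fastq",
        "truth_reads": out / "truth_reads.tsv",
        "truth_hairpins": out / "truth_hairpins.tsv",
        "truth_known": out / "truth_known.tsv",
        "hairpin_bed": out / "hairpins.bed",
    }
    write_fasta(paths["genome"], sorted(genome.items()))
    write_fasta(paths["references"],
                [(f"{r['id']}|{r['family']}|{r['class']}", r["seq"])
                 for _, r in refs.iterrows()])
    for lib in LIBRARIES:
        write_fastq(paths[lib], libraries[lib])
    assert truth.reads is not None
    truth.reads.to_csv(paths["truth_reads"], sep="\t", index=False)
    truth.hairpins.to_csv(paths["truth_hairpins"], sep="\t", index=False)
    truth.known.to_csv(paths["truth_known"], sep="\t", index=False)
    bed = truth.hairpins[["scaffold", "start", "end", "name", "strand"]].copy()
    bed.insert(4, "score", 0)
    bed.to_csv(paths["hairpin_bed"], sep="\t", index=False, header=False)
    return paths
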