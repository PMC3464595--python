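# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Read cleaning

Reads are emitted by the platform at a fixed cycle length (36 nt by
default) with the 3' adapter read through, so trimming is mandatory. A read
is assigned to exactly one category, in this precedence order (mirroring
the cleaning-ledger row order): low quality → 3' adapter null → 5' adapter
contaminant → insert null → shorter than 18 nt → poly(A) → clean.

* **High quality** is not a universally standardized notion; here a read is
  high quality if it contains no N and fewer than 10% of its bases are
  below Phred 20 (conventional Illumina small-RNA practice; both knobs are
  arguments).
* **Adapter search** is the leftmost exact match of the first 8 nt of the
  3' adapter. Leftmost matters: an adapter dimer contains the adapter at
  position 0 *and* downstream, and must trim to an empty insert ("Insert
  null"), which a rightmost search would misclassify.
* **5' adapter contaminants** are detected by the last 12 nt of the 5'
  adapter occurring anywhere in the read. The 12-mer seed keeps the chance
  of an accidental hit in 1e5 random reads far below one read.
* **Poly(A)** inserts are those with ≥80% A — the category exists to drop
  oligo-dT artifacts, and a threshold rather than an exact-homopolymer rule
  catches sequencing errors inside them.
* An insert trimming to longer than the maximum length (possible only with
  non-default read geometries) is tallied under "3' adapter null": the
  ledger has no over-length row, and an adapter match that close to the
  read end is not credible.

The ledger satisfies `clean = high_quality − Σ removals` and
`total = high_quality + low_quality` by construction, and both identities
are asserted.

## Annotation

ncRNA classes match by substring containment (reads are fragments of long
rRNA/tRNA/sn(o)RNA molecules), on either strand; mature miRNAs match by
full-length identity only — shifted or variant reads stay unannotated
rather than inflating the known-miRNA tally. Precedence is
rRNA → snRNA → snoRNA → tRNA → miRNA, matching the category-table row
order. Family member counts collapse arm variants: `miR171b` and
`miR171b-3p` are one member. This convention is what reconciles a 6-row
family listing with a 5-member count in the reference aggregation, and it
is the biologically sensible unit (one hairpin, two arms).

## RNA folding

The energy model is deliberately reduced and fully self-contained:

* stacking free energies for the 21 distinct stack types over
  {CG, GC, GU, UG, AU, UA}, Freier/Turner-style values in kcal/mol; the
  table satisfies the physical duplex-rotation identity
  `E[p][q] = E[flip(q)][flip(p)]`, which a test asserts;
* linear loop penalties — hairpin `5.0 + 0.15·(L−3)`, bulge `3.6 + 0.3·t`,
  internal `2.1 + 0.4·t + 0.3·|n1−n2|` (t unpaired nt total), multiloop
  `3.4 + 0.4·branch + 0.1·unpaired`;
* hairpin loops ≥3 nt; interior loops searched up to 30 unpaired nt;
  no dangles, no coaxial stacking, pseudoknots out of scope.

The optimum over nested structures is computed by a Zuker-style DP
(`V`/`WM` matrices plus an external array), integer centi-kcal arithmetic,
numba-compiled; traceback breaks ties in a fixed order so the reported
structure is deterministic. An independent evaluator scores any given
structure by explicit loop decomposition; exhaustive enumeration over that
evaluator is the oracle the DP is tested against (equality on hundreds of
random sequences up to 22 nt, where enumeration is feasible).

Reverse-complement symmetry is exact only for Watson–Crick pairs (a G:U
pair maps to an unpairable A·C under reverse complement), so the symmetry
test disables wobble. Published precursor energies from mFold are not
bit-reproducible under a different model; the −18 kcal/mol acceptance gate
is therefore applied under this model and is configurable.

## Hairpin discovery

Unannotated tags with ≥5 reads (the seed threshold is configurable; 5 is
consistent with the smallest mature counts reported for accepted novel
miRNAs) are mapped exactly, full length, both strands; tags with more than
20 loci are dropped as repeats. Each locus seeds two windows
(±20/+flank and −flank/+20, flank default 250 so precursors up to ~380 nt
are reachable), clipped at scaffold edges and oriented along the tag
strand. Because a 250 nt flank occasionally folds *over* a genuine small
hairpin, each locus is additionally evaluated at flank 80; the best verdict
across windows is kept. Coordinates are 0-based half-open internally and
1-based inclusive `scaffold:start:end:strand` in reports.

Candidate evaluation works from the window fold:

1. the mature must not pair with itself, and its partners must lie
   (by clear majority) on one side — that side defines the arm;
2. a stem is an anti-diagonal (`p + partner(p)` ≈ constant), so the median
   diagonal of the mature's partners defines the duplex registration;
   partners far off that diagonal are flank artifacts and are treated as
   unpaired;
3. the star is the 2 nt 3'-overhang image of the mature on that diagonal:
   star end = partner(mature 5' end) + 2, star start = partner(mature 3'
   end − 2); it must not overlap the mature and must have ≥1 read;
4. mismatches are counted along the registration (complementarity of
   mature position k with star end −2−k), limit 4; fold partners deviating
   from the registration by more than 2 nt are an asymmetric bulge and
   reject the candidate;
5. the precursor is trimmed to the minimal hairpin containing the duplex,
   must be ≥50 nt, is refolded, and must reach ≤ −18 kcal/mol.

Rejections carry machine-readable reasons. Accepted candidates at
overlapping loci on one strand are deduplicated keeping the higher mature
count, which resolves the star-seeded duplicate of every true locus.
Multi-locus identical matures remain separate candidates.

## Differential expression

Normalized expression is reads per million of the library's clean-read
total. The zero-revision rule (0 → 0.01 RPM) keeps fold-changes finite for
condition-specific miRNAs; pairs below 1 RPM in both libraries are excluded
as too low for inference. The test statistic is the Audic–Claverie
conditional distribution of one count given the other, i.e. a negative
binomial with x+1 successes and success probability 1/(1+r), r = N2/N1,
evaluated on the **raw integer counts** (the factorials require integers;
feeding normalized values into the formula would be ill-defined).

Two-sidedness: the lower tail C = P(γ≤y|x) and upper tail D = P(γ≥y|x)
share the boundary term γ=y, so doubling `min(C, D)` is not invariant under
exchanging the libraries. The package doubles the smallest tail over both
orientations, `min(1, 2·min(C, D, C', D'))`, which is exactly symmetric,
differs from the one-orientation version by at most one boundary term, and
holds its size empirically (type-I error ≈ 0.057 at α = 0.05 under a
Poisson null with unequal library sizes). Tails are computed by vectorized
log-gamma summation; when the complement `1 − P(γ<y)` loses precision (y
far above the conditional mode) the upper tail is summed directly. Both
single-orientation tails remain available via `ac_tails`.

Printed p-values in the reference differential table are not reproducible
from the formula on raw counts (they are orders of magnitude too large)
and the accompanying text's claim that normalized values enter the
factorial formula is self-contradictory; the implementation is validated
against a brute-force summation oracle and distributional properties
instead. The "1.5-fold" significance cut is applied to the linear RPM
ratio by default; an |log2FC| variant is exposed.

Multiple-testing correction is intentionally absent (matching the original
procedure) — a caveat for real use.

## Target scanning

Ungapped windows only: the original screen was a mismatch-count filter on
alignment hits, so gaps are off the default path. Scoring follows the
plant target rules: WC 0, G:U 0.5, mismatch 1.0, doubled at miRNA positions
2–13; hits need <4 mismatches (G:U counted separately by default; a flag
counts them as mismatches) and penalty ≤4 (configurable). The scanner is
tested for identity against a naive all-window enumerator with
independently re-derived scoring.

## Synthetic data generator

The generator defines the validation conditions: two libraries of 1e5
reads; 61 known matures in 24 families with log-uniform abundances, three
planted at 3.0-fold (up in the imperfect library) and two
condition-specific; five hairpin loci (matures 20–23 nt, 70% starting with
U, both arms and strands) with star reads at 2% of mature abundance,
matching the low star counts real libraries show; an ncRNA fragment
background (13% of reads); insert lengths peaked at 21/24 nt; and
contamination rates shaped like a real cleaning ledger (~2% low quality,
fractions of a percent for the adapter categories). Platform adapters are
the published Illumina small-RNA sequences, as the study itself names none.

Properties the generator guarantees (and tests rely on):

* **Determinism** — one seeded RNG drives everything; identical specs give
  byte-identical files.
* **Category unambiguity** — random sequence is rejection-sampled so no
  background insert contains the 3'-adapter 8-mer or 5'-adapter 12-mer
  seed, which is what makes the cleaning round-trip exact.
* **Duplex constructibility** — star = revcomp(mature minus its last 2 nt)
  plus a 2 nt 3' overhang; planted mismatches never sit within 3 nt of the
  duplex ends. Each precursor is folded at build time and the arrangement
  resampled until its MFE structure realizes the designed registration
  with a −20 kcal/mol margin; designs for which no arrangement works (e.g.
  an AU-only stem) are rejected as infeasible. Default matures are
  resampled until feasible.
* **Length spectrum at read level** — species insert lengths are
  budget-assigned against the heavy-tailed abundance weights so the
  *read-weighted* length distribution matches the planted one (i.i.d.
  per-species lengths would not).
* The insert length distribution caps at 28 nt by default: with 36-cycle
  reads a longer insert leaves no room for the adapter seed and would be
  undetectable by construction.

Not emulated: position-specific sequencing error profiles (only a uniform
degraded-quality mode), isomiR/shifted reads, RNA editing, true genomic
repeat structure, and real reference content. Passing the end-to-end tests
therefore demonstrates correctness of the pipeline logic under clean,
unambiguous conditions — not performance on real libraries with isomiRs
and repeat-derived multimappers.

## Problem sizes used in validation

Unit tests run on 2e4-read libraries (where the cleaning round-trip is
checked exactly, read by read); the end-to-end scenario uses 1e5-read
libraries, 3×60 kb scaffolds, 5 hairpins and 61 known matures; the folding
oracle uses 200 random sequences of 15–22 nt (exhaustive enumeration is
exponential, and 22 nt is where it stays comfortable); the count-test
oracle uses 500 random tuples plus 1000 null simulations. These sizes were
chosen so the whole suite validates every claim in about a minute on one
core while keeping all statistical bounds meaningful.
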