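# budmir

Small-RNA sequencing analysis of two-condition plant libraries: read
cleaning and tag collapsing, ncRNA and known-miRNA annotation, hairpin-based
novel miRNA discovery with miRNA\* support, exact count-based differential
expression, and plant miRNA target scanning — plus a synthetic-data
generator that produces fully ground-truthed inputs for every stage.

The package reimplements, as a tested and reusable library, the analysis
applied to perfect vs. imperfect (pistil-aborting) Japanese apricot
(*Prunus mume*) flower-bud small-RNA libraries: which microRNAs are
expressed in each bud type, which are novel, and which change when the
pistil aborts.

## What it computes

**Cleaning and collapsing.** Fixed-length reads are trimmed at the 3'
sequencing adapter and sorted into exactly one ledger category (low quality,
3' adapter null, 5' adapter contaminant, insert null, <18 nt, poly(A),
clean). Clean 18–30 nt inserts are collapsed to unique tags with per-library
counts; the clean-read total *N* of each library is the normalization
denominator.

**Annotation.** Tags that are substrings of rRNA/snRNA/snoRNA/tRNA
references (either strand) are removed in precedence order; a tag is a known
miRNA only if it is *identical* to a mature reference sequence. Families
aggregate members (arm variants like `-3p` count once) and read totals.

**Novel miRNA discovery.** Unannotated tags are mapped exactly to the
genome; flanking windows are folded with an in-package nearest-neighbor
energy model (Watson–Crick and G:U stacks, linear loop penalties, Zuker-style
dynamic program, exact to the model by construction and verified against
exhaustive enumeration). A candidate is accepted only if the mature sits on
one arm of a stem, the star strand implied by a 2 nt 3'-overhang duplex has
read support, the duplex has ≤4 mismatches and no asymmetric bulge >2 nt,
the trimmed precursor is ≥50 nt, and its fold is at or below −18 kcal/mol.

**Differential expression.** Counts are normalized to reads per million
(`count / N × 1e6`); zero values are revised to 0.01; tags below 1 RPM in
both libraries are excluded. Significance uses the Audic–Claverie
conditional law

```
p(y | x) = r^y (x+y)! / ( x! y! (1+r)^(x+y+1) ),   r = N2/N1
```

with two-sided p-value `min(1, 2·min(C, D, C', D'))`, where C/D are the
lower/upper tails and C'/D' the tails of the swapped comparison (this makes
the statistic exactly symmetric in the two libraries). A miRNA is called
differential at linear fold > 1.5 and p < 0.05.

**Target scanning.** Each transcript window is scored against the miRNA:
Watson–Crick 0, G:U wobble 0.5, mismatch 1.0, doubled at miRNA positions
2–13; hits need <4 mismatches and penalty ≤ 4.

## Worked example

`python examples/04_differential_expression.py` recomputes the reference
differential table from raw counts and the two clean-read totals
(N1 = 21,985,053; N2 = 24,239,332):

```
   name  count_perfect  norm_perfect  count_imperfect  norm_imperfect  log2fc mode sig
 miR319             21          0.96              171            7.05    2.88   Up  **
miR319a            121          5.50             1172           48.35    3.14   Up  **
miR6274             60          2.73                0            0.01   -8.09 Down  **
miR171d              0          0.01             2097           86.51   13.08   Up  **
miR482c          30342       1380.12                0            0.01  -17.07 Down  **
...
```

`norm_*` are reads per million; the 0 → 0.01 entries show the zero-revision
rule producing the large finite fold-changes of condition-specific miRNAs;
`Up` means higher in the imperfect (pistil-aborting) buds.

Other examples: `01_simulate_dataset.py` (ground-truthed simulation),
`02_clean_and_collapse.py` (ledger + length spectrum),
`03_hairpin_discovery.py` (folding + stem-loop criteria),
`05_target_scan.py` (site scoring with alignments).

## Command line

A thin CLI mirrors the stages:

```
budmir simulate --seed 1 --depth 100000 --outdir data/
budmir clean --fastq data/perfect.fastq --adapter3 TCGTATGCCGTCTTCTGCTTG --out-prefix perfect
budmir annotate --tags perfect.clean.fa --tags imperfect.clean.fa --references data/references.fa --out-prefix ann
budmir predict-hairpins --tags unannotated.fa --genome data/genome.fa --mfe-max -18 --out novel.tsv
budmir diffexp --counts counts.tsv --n1 21985053 --n2 24239332 --out table6.tsv
budmir targets --mirnas mirnas.fa --transcripts tx.fa --out targets.tsv
budmir run-all --config pipeline.yaml
```

Exit codes: 0 success, 2 configuration error, 3 stage failure.

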