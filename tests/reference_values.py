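"""Published reference values from the Japanese-apricot flower-bud
small-RNA study this pipeline reimplements: clean-read totals, the
differential-expression table, known-miRNA normalization spot checks, family
aggregation rows, and overlap mean frequencies.  Raw counts are inputs; every
derived number is recomputed by the package in the tests."""

# clean-read totals (normalization denominators)
N1_PERFECT = 21_985_053
N2_IMPERFECT = 24_239_332

# differential table rows:
# (name, count_perfect, norm_perfect, count_imperfect, norm_imperfect,
#  log2fc, mode)
TABLE6 = [
    ("miR319", 21, 0.96, 171, 7.05, 2.88, "Up"),
    ("miR319a", 121, 5.50, 1172, 48.35, 3.14, "Up"),
    ("miR319e", 1, 0.05, 40, 1.65, 5.18, "Up"),
    ("miR160a", 110, 5.00, 808, 33.33, 2.74, "Up"),
    ("miR393a", 2, 0.09, 77, 3.18, 5.13, "Up"),
    ("miR394a", 24, 1.09, 301, 12.42, 3.51, "Up"),
    ("miR395a", 14, 0.64, 94, 3.88, 2.61, "Up"),
    ("miR6274", 60, 2.73, 0, 0.01, -8.09, "Down"),
    ("miR6268", 178, 8.10, 66, 2.72, -1.57, "Down"),
    ("miR6295", 0, 0.01, 42, 1.73, 7.44, "Up"),
    ("miR319b", 0, 0.01, 71, 2.93, 8.19, "Up"),
    ("miR171d", 0, 0.01, 2097, 86.51, 13.08, "Up"),
    ("miR482c", 30342, 1380.12, 0, 0.01, -17.07, "Down"),
]

# known-miRNA table spot checks: (name, count, total, normalized)
TABLE4_SPOT = [
    ("miR156a", 45_352, N1_PERFECT, 2062.86),
    ("miR156a", 61_361, N2_IMPERFECT, 2531.46),
    ("miR157a", 735_314, N1_PERFECT, 33_446.09),
    ("miR166a", 281_639, N2_IMPERFECT, 11_619.09),
]

# family-aggregation input rows: (family, mirna_id, count_perfect,
# count_imperfect); member counts collapse arm variants (-3p/-5p)
TABLE4_FAMILY_ROWS = [
    ("MIR156", "miR156a", 45_352, 61_361),
    ("MIR156", "miR156b", 26_572, 29_886),
    ("MIR156", "miR156c", 145_205, 210_543),
    ("MIR156", "miR156f", 118, 188),
    ("MIR156", "miR156h", 0, 4),
    ("MIR156", "miR156k", 25, 46),
    ("MIR156", "miR157a", 735_314, 658_343),
    ("MIR156", "miR157d", 8_866, 8_738),
    ("MIR159", "miR159a", 18_682, 38_726),
    ("MIR159", "miR319", 21, 171),
    ("MIR159", "miR319a", 121, 1_172),
    ("MIR159", "miR319c", 6, 7),
    ("MIR159", "miR319e", 1, 40),
    ("MIR159", "miR319g", 0, 5),
    ("MIR171", "miR171", 483, 630),
    ("MIR171", "miR171b", 1_578, 1_994),
    ("MIR171", "miR171d", 1, 0),
    ("MIR171", "miR171f", 13, 15),
    ("MIR171", "miR171b-3p", 2_195, 2_831),
    ("MIR171", "miR171l", 4, 9),
]
MIR156_PERFECT_TOTAL = 961_452
MIR156_IMPERFECT_TOTAL = 969_109
FAMILY_MEMBER_COUNTS = {"MIR156": 8, "MIR159": 6, "MIR171": 5}

# overlap table: class -> (unique, redundant, mean frequency)
TABLE3 = {
    "total": (10_590_449, 46_224_385, 4.36),
    "common": (1_729_699, 35_758_031, 20.67),
    "a_specific": (4_587_847, 5_437_697, 1.19),
    "b_specific": (4_272_903, 5_028_657, 1.18),
}
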