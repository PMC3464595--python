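"""Generate a small ground-truthed two-library dataset and look at its truth.

The generator plants known miRNAs (some differential), novel hairpin loci
with low-count star reads, ncRNA fragments and ledger-style contaminants,
then emits fixed-length reads with adapter read-through.
"""

from budmir.simlib import SimulationSpec, write_dataset
import pandas as pd

spec = SimulationSpec(seed=11, library_depth=20_000)
paths = write_dataset(spec, "example-dataset")

print("files written:")
for key, path in paths.items():
    print(f"  {key:15s} {path}")

truth = pd.read_csv(paths["truth_reads"], sep="\t")
print("\nreads per category (both libraries):")
print(truth.groupby(["library", "category"]).size().unstack(fill_value=0))

hairpins = pd.read_csv(paths["truth_hairpins"], sep="\t")
print("\nplanted hairpin loci (mature arm and strand are ground truth the")
print("discovery stage must recover):")
print(hairpins[["name", "scaffold", "start", "end", "strand", "arm"]])
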