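"""Session fixtures: ground-truthed synthetic datasets shared across tests.

Two scales are used: a small dataset (2e4 reads/library) for exact
round-trip checks, and the full validation scenario (1e5 reads/library, 5
planted hairpins, 3 planted 3-fold differential miRNAs) for end-to-end truth
recovery.  Both are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from budmir.preprocess import CleanResult, clean_reads, collapse, tag_table
from budmir.simlib import (SimulationSpec, make_genome, make_references,
                           simulate_libraries)


@dataclass
class SimDataset:
    spec: SimulationSpec          # resolved
    genome: dict
    truth: object
    libraries: dict
    cleaned: dict[str, CleanResult]
    tags: object                  # tag_table DataFrame
    references: object            # reference records DataFrame


def _build(seed: int, depth: int) -> SimDataset:
    spec = SimulationSpec(seed=seed, library_depth=depth)
    rspec = spec.resolved()
    genome, truth = make_genome(spec)
    libraries, truth = simulate_libraries(genome, spec, truth)
    cleaned = {}
    counters = {}
    for lib in ("perfect", "imperfect"):
        res = clean_reads(iter(libraries[lib]), rspec.adapter3, rspec.adapter5)
        cleaned[lib] = res
        counters[lib] = collapse(ins for _, ins in res.inserts)
    return SimDataset(spec=rspec, genome=genome, truth=truth,
                      libraries=libraries, cleaned=cleaned,
                      tags=tag_table(counters),
                      references=make_references(spec))


@pytest.fixture(scope="session")
def sim_small() -> SimDataset:
    """2e4 reads/library; rates make every cleaning category unambiguous."""
    return _build(seed=3, depth=20_000)


@pytest.fixture(scope="session")
def sim_full() -> SimDataset:
    """The validation scenario: 1e5 reads/library, seed 1."""
    return _build(seed=1, depth=100_000)


@pytest.fixture(scope="session")
def discovery_full(sim_full):
    """Hairpin discovery on the unannotated tags of the full dataset."""
    from budmir.annotate import ReferenceSet, classify_tags
    from budmir.hairpin import HairpinThresholds, discover

    refs = {
        label: ReferenceSet(label=label,
                            records=sub[["id", "family", "seq"]]
                            .reset_index(drop=True))
        for label, sub in sim_full.references.groupby("class")
    }
    classes, _ = classify_tags(sim_full.tags, refs)
    unannotated = sim_full.tags[(classes == "unannotated").values]
    counts = unannotated.sum(axis=1).to_dict()
    return discover(counts, sim_full.genome, HairpinThresholds())
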