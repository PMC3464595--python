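"""End-to-end orchestration: clean -> collapse -> classify -> known miRNA ->
hairpin discovery -> differential expression -> target scan.

Every stage reads and writes the documented plain-text contracts (FASTQ /
FASTA in, TSV out), so stages are independently testable and a rerun with
the same config and seed produces byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, hairpin, preprocess, targets
from ._util import read_fasta, read_fastq, write_collapsed_fasta
from .diffexp import call_differential, de_table
from .simlib import LIBRARIES

log = logging.getLogger("budmir")


class ConfigError(ValueError):
    """Raised when the pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one full run."""

    library_perfect: str
    library_imperfect: str
    genome: str
    references: str
    transcripts: str | None = None
    outdir: str = "budmir-out"
    adapter3: str = ""
    adapter5: str = ""
    min_len: int = 18
    max_len: int = 30
    mfe_max: float = -18.0
    flank: int = 250
    min_mature_count: int = 5
    fold_threshold: float = 1.5
    alpha: float = 0.05
    max_mismatch_targets: int = 3
    max_penalty: float = 4.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        missing = {"library_perfect", "library_imperfect", "genome",
                   "references"} - kwargs.keys()
        if missing:
            raise ConfigError(f"config missing required keys: {sorted(missing)}")
        return cls(extra=extra, **kwargs)

    def validate(self) -> None:
        if not self.adapter3:
            raise ConfigError("adapter3 must be set")
        for name in ("library_perfect", "library_imperfect", "genome",
                     "references"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        if self.transcripts and not Path(self.transcripts).exists():
            raise ConfigError(f"transcripts path does not exist: {self.transcripts}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.fold_threshold < 1:
            raise ConfigError("fold_threshold must be >= 1")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns the report path map.

    Any stage failure is re-raised as ``RuntimeError`` naming the stage.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stage = "setup"
    try:
        # ------------------------------------------------------ clean
        stage = "clean"
        summaries = {}
        counters = {}
        lib_paths = {"perfect": config.library_perfect,
                     "imperfect": config.library_imperfect}
        for lib in LIBRARIES:
            res = preprocess.clean_reads(
                read_fastq(lib_paths[lib]), config.adapter3,
                config.adapter5 or None, config.min_len, config.max_len)
            summaries[lib] = res.summary
            counters[lib] = preprocess.collapse(
                ins for _, ins in res.inserts)
            log.info("%s: %d reads, %d clean, %d unique tags", lib,
                     res.summary.total_reads, res.summary.clean_total,
                     len(counters[lib]))
            write_collapsed_fasta(out / f"clean_{lib}.fa", counters[lib])
        ledger = pd.DataFrame({lib: summaries[lib].as_series()
                               for lib in LIBRARIES})
        paths["table1"] = out / "table1_cleaning.tsv"
        ledger.to_csv(paths["table1"], sep="\t")

        tags = preprocess.tag_table(counters)
        n1 = summaries["perfect"].clean_total
        n2 = summaries["imperfect"].clean_total

        # ------------------------------------------------- summaries
        stage = "summaries"
        hist = pd.DataFrame({
            f"{lib}_{kind}": preprocess.length_histogram(
                tags[lib], weighted=(kind == "redundant"),
                min_len=config.min_len, max_len=config.max_len)
            for lib in LIBRARIES for kind in ("redundant", "unique")})
        paths["fig1"] = out / "fig1_length_distribution.tsv"
        hist.to_csv(paths["fig1"], sep="\t")
        overlap = preprocess.overlap_stats(tags["perfect"], tags["imperfect"])
        paths["table3"] = out / "table3_overlap.tsv"
        overlap.to_csv(paths["table3"], sep="\t")

        # ------------------------------------------------- annotate
        stage = "annotate"
        refs = annotate.load_reference_fasta(config.references)
        classes, tally = annotate.classify_tags(tags, refs)
        paths["table2"] = out / "table2_categories.tsv"
        tally.to_csv(paths["table2"], sep="\t", float_format="%.2f")
        log.info("category tally:\n%s", tally)

        hits = pd.DataFrame()
        fam = pd.DataFrame()
        if "miRNA" in refs:
            hits = annotate.match_known_mirnas(tags, refs["miRNA"])
            fam = annotate.family_summary(hits)
        paths["table4"] = out / "table4_known_mirnas.tsv"
        hits.to_csv(paths["table4"], sep="\t", index=False)
        paths["families"] = out / "fig3_family_summary.tsv"
        fam.to_csv(paths["families"], sep="\t")

        # ------------------------------------------------- hairpins
        stage = "hairpin"
        genome = dict(read_fasta(config.genome))
        unannotated = tags[classes == "unannotated"]
        tag_counts = unannotated.sum(axis=1).to_dict()
        th = hairpin.HairpinThresholds(
            mfe_max=config.mfe_max, flank=config.flank,
            min_mature_count=config.min_mature_count)
        candidates = hairpin.discover(tag_counts, genome, th)
        accepted = [c for c in candidates if c.accepted]
        log.info("hairpin discovery: %d candidates, %d accepted",
                 len(candidates), len(accepted))
        paths["table5"] = out / "table5_novel_mirnas.tsv"
        hairpin.candidates_table(candidates).to_csv(
            paths["table5"], sep="\t", index=False, float_format="%.2f")
        bias = hairpin.first_nt_bias([c.mature for c in accepted])
        paths["fig6"] = out / "fig6_first_nt_bias.tsv"
        bias.to_csv(paths["fig6"], sep="\t", float_format="%.4f")

        # ------------------------------------------------- diffexp
        stage = "diffexp"
        counts: list[tuple[str, int, int]] = []
        seen = set()
        for row in hits.itertuples():
            if row.mirna_id in seen:
                continue
            seen.add(row.mirna_id)
            counts.append((row.mirna_id, int(row.perfect), int(row.imperfect)))
        for c in accepted:
            name = f"novel:{c.locus.as_report()}" if c.locus else c.mature
            counts.append((name,
                           int(tags["perfect"].get(c.mature, 0)),
                           int(tags["imperfect"].get(c.mature, 0))))
        records = call_differential(counts, n1, n2,
                                    fold_threshold=config.fold_threshold,
                                    alpha=config.alpha)
        table6 = de_table(records)
        paths["table6"] = out / "table6_differential.tsv"
        table6.to_csv(paths["table6"], sep="\t", index=False)
        sig = table6[table6["sig"] != ""]
        log.info("differential: %d/%d significant", len(sig), len(table6))

        # ------------------------------------------------- targets
        stage = "targets"
        if config.transcripts:
            transcripts = dict(read_fasta(config.transcripts))
            sig_names = set(sig["name"])
            seqs = {}
            for row in hits.itertuples():
                if row.mirna_id in sig_names:
                    seqs[row.mirna_id] = row.tag
            for c in accepted:
                name = f"novel:{c.locus.as_report()}" if c.locus else c.mature
                if name in sig_names:
                    seqs[name] = c.mature
            all_hits = []
            for name in sorted(seqs):
                all_hits.extend(targets.scan_targets(
                    name, seqs[name], transcripts,
                    max_mismatch=config.max_mismatch_targets,
                    max_penalty=config.max_penalty))
            paths["targets"] = out / "targets.tsv"
            targets.hits_table(all_hits).to_csv(
                paths["targets"], sep="\t", index=False)

        # ------------------------------------------------- run log
        stage = "log"
        from . import __version__
        lines = [f"budmir {__version__}", f"seed: {config.seed}"]
        for k, v in sorted(vars(config).items()):
            if k != "extra":
                lines.append(f"{k}: {v}")
        lines.append(f"N1: {n1}")
        lines.append(f"N2: {n2}")
        paths["runlog"] = out / "run_log.txt"
        paths["runlog"].write_text("\n".join(lines) + "\n")
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return paths
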