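"""End-to-end orchestration over conditions and replicates.

``run(config)`` composes the whole analysis: load genome and annotation,
enumerate and flag TA sites, process each replicate's reads into inserts, map
them, tabulate and normalize per-gene counts, classify essentiality per
replicate, build per-condition consensus calls, and compare conditions.  All
outputs are deterministic functions of the inputs and config; every tabular
output carries a header comment with the config hash, and ``provenance.json``
records versions and all design-decision toggles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, classify_replicate, consensus_calls
from .compare import (ConditionCalls, core_essential, export_json,
                      membership_matrix, summary_table, upset_table)
from .genome import (Genome, enumerate_ta_sites, gene_ta_profile, load_annotation,
                     load_genome, mark_duplicated_sites)
from .mapping import GenomeIndex, map_and_tally
from .reads import ProcessingConfig, ProcessingStats, _iter_fastq, _open_text, iter_inserts
from .tabulation import apply_gene_filters, count_gene_reads, normalize

logger = logging.getLogger("tnscreen")


@dataclass
class RunConfig:
    """Declarative description of one multi-condition run."""

    genome_path: str
    annotation_path: str
    conditions: dict[str, list[str]]   # condition name -> replicate FASTQ paths
    outdir: str
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    topology: str = "circular"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("need at least one condition")
        for name, fastqs in self.conditions.items():
            if not fastqs:
                raise ValueError(f"condition {name!r} has no replicates")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "processing" in d and isinstance(d["processing"], dict):
            d["processing"] = ProcessingConfig(**d["processing"])
        if "classifier" in d and isinstance(d["classifier"], dict):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        """Digest of the analysis parameters (not output location or verbosity)."""
        d = asdict(self)
        d.pop("outdir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    condition_calls: list[ConditionCalls]
    calls_tables: dict[str, pd.DataFrame]
    summary: pd.DataFrame
    core: frozenset | None
    outdir: Path
    provenance: dict


def _write_tsv(df: pd.DataFrame, path, config_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _setup_logging(level: str) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline for every condition and replicate.

    Any stage failure aborts with the stage name, condition, and replicate in
    the exception message.
    """
    _setup_logging(config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()

    logger.info("loading genome and annotation")
    genome = load_genome(config.genome_path, topology=config.topology)
    genes = load_annotation(config.annotation_path, genome)
    ta_index = mark_duplicated_sites(enumerate_ta_sites(genome), genome)
    profiles = gene_ta_profile(genes, ta_index)
    exclusions = apply_gene_filters(profiles)
    ginx = GenomeIndex(genome, ta_index)
    logger.info("genome: %d replicons, %d genes, %d TA sites (%d duplicated)",
                len(genome.replicons), len(genes), ta_index.n_sites,
                ta_index.n_duplicated)

    # Caches shared across replicates: read extraction and insert placement
    # are pure functions of read content.
    extract_memo: dict = {}

    condition_calls: list[ConditionCalls] = []
    calls_tables: dict[str, pd.DataFrame] = {}
    for cond_name, fastqs in config.conditions.items():
        rep_cats, rep_z = [], []
        for r, fastq in enumerate(fastqs, start=1):
            tag = f"{cond_name}_rep{r}"
            logger.info("processing %s (%s)", tag, fastq)
            try:
                stats = ProcessingStats()
                with _open_text(fastq) as fh:
                    inserts = iter_inserts(_iter_fastq(fh), config.processing,
                                           stats, memo=extract_memo)
                    table = map_and_tally(inserts, ginx)
            except Exception as exc:
                raise RuntimeError(
                    f"stage read_processing/mapping failed for condition "
                    f"{cond_name!r} replicate {r}: {exc}") from exc
            logger.info("%s: %d reads, %d accepted, %d unique-mapped at %d sites",
                        tag, stats.n_input, stats.n_accepted,
                        table.total_unique_mapped, table.n_sites)
            try:
                raw = count_gene_reads(table, genes, ta_index)
                counts = normalize(raw, genes, table.total_unique_mapped, exclusions)
                cats, z, fit = classify_replicate(counts, config.classifier)
            except Exception as exc:
                raise RuntimeError(
                    f"stage tabulation/classification failed for condition "
                    f"{cond_name!r} replicate {r}: {exc}") from exc

            stats.to_json(outdir / f"{tag}.processing_stats.json")
            table.write_stats_json(outdir / f"{tag}.mapping_stats.json")
            _write_tsv(table.df, outdir / f"{tag}.insertion_table.tsv", chash,
                       index=False)
            _write_tsv(counts, outdir / f"{tag}.gene_counts.tsv", chash)
            with open(outdir / f"{tag}.fit.json", "w") as fh:
                json.dump(fit.as_dict(), fh, indent=2)
            rep_cats.append(cats)
            rep_z.append(z)

        calls = consensus_calls(rep_cats, rep_z)
        _write_tsv(calls, outdir / f"{cond_name}.calls.tsv", chash)
        calls_tables[cond_name] = calls
        condition_calls.append(ConditionCalls(
            condition_name=cond_name, calls=calls["consensus"].to_dict()))

    summary = summary_table(condition_calls)
    _write_tsv(summary, outdir / "summary.tsv", chash)
    patterns = membership_matrix(condition_calls)
    _write_tsv(upset_table(patterns), outdir / "upset.tsv", chash, index=False)
    export_json(condition_calls, outdir / "comparison.json")
    core = core_essential(condition_calls) if len(condition_calls) >= 2 else None

    provenance = {
        "tnscreen_version": __version__,
        "config_hash": chash,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "design_toggles": {
            "duplicate_kmer_orientations": "both",
            "first95_rule": "floor(0.95*len), strict <, strand-aware",
            "rpk_gene_length": "full annotated length",
            "half_unique_rule": "strict < (exactly half passes)",
            "outlier_rule": f"tukey k={config.classifier.tukey_k}, one pass",
            "zero_read_rule": "Essential, excluded from fit",
            "multi_hit_rule": ">1 combined occurrence on either strand",
            "normalization_total": "all replicons jointly",
        },
        "versions": {
            "python": sys.version.split()[0],
            "numpy": __import__("numpy").__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    return RunResult(condition_calls=condition_calls, calls_tables=calls_tables,
                     summary=summary, core=core, outdir=outdir,
                     provenance=provenance)
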