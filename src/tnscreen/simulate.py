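"""Synthetic Tn-seq data with a full truth ledger.

The generator produces everything the analysis consumes — a multi-replicon
genome with annotated genes, a pooled mutant library with per-gene fitness
classes, and per-replicate junction reads — while recording the exact truth
at every level so each pipeline stage can be tested against it.

Model, in the order it runs:

1. **Genome**: i.i.d. bases at a configurable GC content; non-overlapping
   genes of varying length placed on both strands; every gene is guaranteed
   at least 5 TA sites (segments are redrawn otherwise).
2. **Library**: a fraction of TA sites (``insertion_density``) receives a
   mutant with pre-selection abundance ~ Exponential(1) — the spread of
   clone sizes after pooling.  Selection acts multiplicatively on abundance
   *before* any reads are drawn: insertions in the first 95% of an essential
   gene leave no survivors (abundance 0), growth-defect genes are depleted by
   ``defect_depletion``, growth-advantage genes enriched by
   ``advantage_enrichment``; intergenic and trailing-5% insertions are
   untouched.  Replicates are then independent multinomial draws of
   ``reads_per_replicate`` reads over the post-selection abundances, so
   replicate-to-replicate noise is purely counting noise.
3. **Reads**: each sampled insertion emits a forward read with the layout
   ``[revcomp(junction)][IR remnant][genomic insert starting TA][adapter]
   [filler]`` at uniform base quality; strand is a fair coin.  Optionally a
   fraction of reads carries a low-quality tail inside the insert (to
   exercise the quality gate) and substitution errors at a configurable rate.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import phred_string, revcomp
from .genome import Gene, Genome, Replicon, enumerate_ta_sites, first95_mask

CLASS_ESSENTIAL = "essential"
CLASS_DEFECT = "defect"
CLASS_NEUTRAL = "neutral"
CLASS_ADVANTAGE = "advantage"
CLASSES = (CLASS_ESSENTIAL, CLASS_DEFECT, CLASS_NEUTRAL, CLASS_ADVANTAGE)
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults emulate the screened organism: a ~4.3 Mb chromosome plus a small
    plasmid at 64% GC, ~4,000 genes, three replicates of 2x10^6 junction
    reads, and half of all TA sites carrying a mutant.  Class fractions
    (essential / growth defect / neutral / growth advantage) approximate the
    observed proportions of a dense bacterial screen without copying any one
    dataset.
    """

    seed: int = 0
    replicon_lengths: tuple[int, ...] = (4_270_000, 128_000)
    gc_fraction: float = 0.64
    n_genes: int = 4000
    gene_len_range: tuple[int, int] = (200, 1600)
    class_fractions: tuple[float, float, float, float] = (0.13, 0.03, 0.82, 0.02)
    defect_depletion: float = 0.05
    advantage_enrichment: float = 4.0
    reads_per_replicate: int = 2_000_000
    n_replicates: int = 3
    insertion_density: float = 0.5
    # read layout, mirroring ProcessingConfig
    adapter_seq: str = "AGATCGGAAGAGC"
    junction_seq: str = "CGGGGACTTATCATCCAACCTGT"
    ir_remnant_seq: str = "ACGG"
    insert_len: int = 14
    read_length: int = 75
    base_quality: int = 30
    error_rate: float = 0.0
    low_quality_fraction: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        for rate in (self.gc_fraction, self.insertion_density, self.error_rate,
                     self.low_quality_fraction):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if not (14 <= self.insert_len <= 18):
            raise ValueError("insert_len must be in [14, 18]")
        if self.gene_len_range[0] > self.gene_len_range[1] or self.gene_len_range[0] < 50:
            raise ValueError("bad gene length range")

    @property
    def replicon_ids(self) -> tuple[str, ...]:
        if len(self.replicon_lengths) == 2:
            return ("chromosome", "plasmid")
        return tuple(f"replicon{i + 1}" for i in range(len(self.replicon_lengths)))


@dataclass
class SimulatedGenome:
    genome: Genome
    genes: list[Gene]
    gene_classes: dict[str, str]


@dataclass
class TruthLedger:
    """Exact per-site truth: gene membership, fitness class, planted
    abundance, and the per-replicate read draw."""

    gene_table: pd.DataFrame   # gene_id, replicon, start, end, strand, class
    site_table: pd.DataFrame   # replicon, position, gene_id, class, first95,
                               # mutagenized, abundance
    read_counts: np.ndarray    # (n_sites, n_replicates) multinomial draws

    def write_tsv(self, path) -> None:
        df = self.site_table.copy()
        for r in range(self.read_counts.shape[1]):
            df[f"reads_rep{r + 1}"] = self.read_counts[:, r]
        df.to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedLibrary:
    ledger: TruthLedger
    config: SimConfig


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _ta_count(arr: np.ndarray, start: int, end: int, L: int) -> int:
    """TA sites whose T lies in [start, end) (the A may sit one past end)."""
    stop = min(end + 1, L)
    seg = arr[start:stop]
    return int(((seg[:-1] == ord("T")) & (seg[1:] == ord("A"))).sum())


def simulate_genome(config: SimConfig) -> SimulatedGenome:
    """Draw the genome and gene set; deterministic given the config seed.

    Genes are packed without overlap, strands are random, gaps between genes
    are multinomially distributed.  Raises on infeasible packing (total gene
    length above ~92% of the genome).
    """
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.gene_len_range
    total_len = sum(config.replicon_lengths)

    # allocate genes to replicons proportional to length
    n_per = [int(round(config.n_genes * L / total_len)) for L in config.replicon_lengths]
    n_per[0] += config.n_genes - sum(n_per)

    replicons: list[Replicon] = []
    genes: list[Gene] = []
    gene_counter = 0
    for rid, L, n in zip(config.replicon_ids, config.replicon_lengths, n_per):
        arr = _random_bases(rng, L, config.gc_fraction)
        lengths = rng.integers(lo, hi + 1, size=n)
        if lengths.sum() > 0.92 * L:
            raise ValueError(
                f"cannot pack {n} genes totalling {int(lengths.sum())} bp into "
                f"replicon {rid!r} of {L} bp")
        gaps = rng.multinomial(L - int(lengths.sum()), np.full(n + 1, 1 / (n + 1)))
        strands = rng.choice(np.array(["+", "-"]), size=n)

        pos = 0
        intervals = []
        for glen, gap in zip(lengths, gaps[:-1]):
            pos += int(gap)
            intervals.append((pos, pos + int(glen)))
            pos += int(glen)

        # guarantee >= 5 TA sites per gene by redrawing deficient segments
        for _ in range(20):
            deficient = [iv for iv in intervals if _ta_count(arr, *iv, L) < 5]
            if not deficient:
                break
            for start, end in deficient:
                for _ in range(200):
                    arr[start:end] = _random_bases(rng, end - start, config.gc_fraction)
                    if _ta_count(arr, start, end, L) >= 5:
                        break
                else:
                    raise ValueError("could not place >= 5 TA sites in a gene segment")
        else:
            raise ValueError("TA-site guarantee did not converge")

        replicons.append(Replicon(id=rid, seq=arr.tobytes().decode("ascii"),
                                  topology="circular"))
        for (start, end), strand in zip(intervals, strands):
            gene_counter += 1
            genes.append(Gene(gene_id=f"g{gene_counter:05d}", replicon_id=rid,
                              start=start, end=end, strand=str(strand),
                              product="simulated protein"))

    classes = rng.choice(len(CLASSES), size=config.n_genes, p=config.class_fractions)
    gene_classes = {g.gene_id: CLASSES[c] for g, c in zip(genes, classes)}
    return SimulatedGenome(genome=Genome(replicons=tuple(replicons)),
                           genes=genes, gene_classes=gene_classes)


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def simulate_library(sim: SimulatedGenome, config: SimConfig,
                     condition_seed: int = 0) -> SimulatedLibrary:
    """Plant mutants, apply selection, and draw per-replicate read counts.

    ``condition_seed`` separates independent selections of the same genome
    (different growth conditions re-select the same parent library).
    Sites too close to a replicon end to yield a full-length insert are never
    mutagenized (read extraction there is undefined on a linear view).
    """
    rng = np.random.default_rng([config.seed, 2, condition_seed])
    index = enumerate_ta_sites(sim.genome)

    recs = []
    for rep in sim.genome.replicons:
        L = len(rep)
        positions = index.positions(rep.id)
        gene_id = np.full(len(positions), "", dtype=object)
        gene_cls = np.full(len(positions), INTERGENIC, dtype=object)
        in95 = np.zeros(len(positions), dtype=bool)
        for gene in (g for g in sim.genes if g.replicon_id == rep.id):
            lo, hi = np.searchsorted(positions, [gene.start, gene.end])
            gene_id[lo:hi] = gene.gene_id
            gene_cls[lo:hi] = sim.gene_classes[gene.gene_id]
            in95[lo:hi] = first95_mask(positions[lo:hi], gene)
        safe = (positions >= config.insert_len - 2) & (positions <= L - config.insert_len)
        recs.append(pd.DataFrame({
            "replicon": rep.id, "position": positions, "gene_id": gene_id,
            "cls": gene_cls, "first95": in95, "safe": safe,
        }))
    sites = pd.concat(recs, ignore_index=True)

    n = len(sites)
    mutagenized = (rng.random(n) < config.insertion_density) & sites["safe"].to_numpy()
    abundance = rng.exponential(1.0, size=n)
    abundance[~mutagenized] = 0.0

    multiplier = np.ones(n)
    cls = sites["cls"].to_numpy()
    in95 = sites["first95"].to_numpy()
    multiplier[(cls == CLASS_ESSENTIAL) & in95] = 0.0
    multiplier[(cls == CLASS_DEFECT) & in95] = config.defect_depletion
    multiplier[(cls == CLASS_ADVANTAGE) & in95] = config.advantage_enrichment
    abundance *= multiplier

    p = abundance / abundance.sum()
    read_counts = np.stack(
        [rng.multinomial(config.reads_per_replicate, p)
         for _ in range(config.n_replicates)], axis=1)

    sites = sites.drop(columns="safe")
    sites["mutagenized"] = mutagenized
    sites["abundance"] = abundance

    gene_table = pd.DataFrame([{
        "gene_id": g.gene_id, "replicon": g.replicon_id, "start": g.start,
        "end": g.end, "strand": g.strand, "class": sim.gene_classes[g.gene_id],
    } for g in sim.genes])

    ledger = TruthLedger(gene_table=gene_table, site_table=sites,
                         read_counts=read_counts)
    return SimulatedLibrary(ledger=ledger, config=config)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _site_inserts(seq: str, pos: int, n: int) -> tuple[str, str]:
    """(forward, reverse) genomic inserts of length ``n`` at TA site ``pos``."""
    fwd = seq[pos:pos + n]
    rev = revcomp(seq[pos - n + 2:pos + 2])
    return fwd, rev


def simulate_reads(library: SimulatedLibrary, sim: SimulatedGenome,
                   out_paths: list, config: SimConfig | None = None) -> list[dict]:
    """Write one FASTQ per replicate; returns per-replicate truth summaries.

    Each read is ``[revcomp(junction)][IR remnant][insert][adapter][filler]``
    padded with random filler to ``read_length``, at uniform base quality.
    With ``low_quality_fraction`` > 0 that fraction of reads gets a Q2 tail
    starting 2 bases into the insert, which downstream processing must reject
    at the quality gate.  Deterministic given (config, seed).
    """
    config = config or library.config
    if len(out_paths) != config.n_replicates:
        raise ValueError("need one output path per replicate")

    seqs = {r.id: r.seq for r in sim.genome.replicons}
    sites = library.ledger.site_table
    counts = library.ledger.read_counts

    prefix = revcomp(config.junction_seq) + config.ir_remnant_seq
    core_len = len(prefix) + config.insert_len + len(config.adapter_seq)
    read_len = max(config.read_length, core_len)
    fill_len = read_len - core_len

    q_good = phred_string([config.base_quality] * read_len)
    low_start = len(prefix) + 2
    q_low = q_good[:low_start] + phred_string([2] * (read_len - low_start))

    # Per-site read templates are fixed across replicates: reads from one
    # insertion event are PCR copies of the same junction fragment.
    rng_fill = np.random.default_rng([config.seed, 3])
    active = np.flatnonzero(counts.sum(axis=1) > 0)
    fillers = _BASES[rng_fill.integers(0, 4, size=(len(active), 2, fill_len))]
    templates = {}
    for row, i in enumerate(active):
        rid = sites.iat[i, 0]
        pos = int(sites.iat[i, 1])
        fwd_ins, rev_ins = _site_inserts(seqs[rid], pos, config.insert_len)
        fill_f = fillers[row, 0].tobytes().decode("ascii")
        fill_r = fillers[row, 1].tobytes().decode("ascii")
        templates[i] = (prefix + fwd_ins + config.adapter_seq + fill_f,
                        prefix + rev_ins + config.adapter_seq + fill_r)

    summaries = []
    for r, path in enumerate(out_paths):
        rng = np.random.default_rng([config.seed, 4, r])
        n_low_total = 0
        n_reads = 0
        chunks: list[str] = []
        with open(path, "w") as fh:
            for i in active:
                c = int(counts[i, r])
                if c == 0:
                    continue
                n_fwd = int(rng.binomial(c, 0.5))
                fwd_t, rev_t = templates[i]
                for strand, template, k in (("f", fwd_t, n_fwd),
                                            ("r", rev_t, c - n_fwd)):
                    if k == 0:
                        continue
                    n_low = (int(rng.binomial(k, config.low_quality_fraction))
                             if config.low_quality_fraction > 0 else 0)
                    n_low_total += n_low
                    for j in range(k):
                        seq = template
                        if config.error_rate > 0:
                            seq = _mutate(seq, config.error_rate, rng)
                        qual = q_low if j < n_low else q_good
                        chunks.append(f"@r{r + 1}_{i}_{strand}{j}\n{seq}\n+\n{qual}\n")
                n_reads += c
                if len(chunks) >= 50_000:
                    fh.write("".join(chunks))
                    chunks = []
            fh.write("".join(chunks))
        summaries.append({"path": str(path), "n_reads": n_reads,
                          "n_low_quality": n_low_total})
    return summaries


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for h in hits:
        choices = _BASES[_BASES != arr[h]]
        arr[h] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# File writers and the one-call convenience wrapper
# ---------------------------------------------------------------------------

def write_genome_fasta(sim: SimulatedGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rep in sim.genome.replicons:
            fh.write(f">{rep.id}\n")
            for i in range(0, len(rep.seq), width):
                fh.write(rep.seq[i:i + width] + "\n")


def write_genome_gff3(sim: SimulatedGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sim.genes:
            attrs = f"ID={g.gene_id};product={g.product}"
            fh.write(f"{g.replicon_id}\ttnscreen_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


@dataclass
class SimulationResult:
    sim_genome: SimulatedGenome
    library: SimulatedLibrary
    read_summaries: list[dict]
    paths: dict


def simulate_all(config: SimConfig, out_dir, condition_seed: int = 0,
                 prefix: str = "") -> SimulationResult:
    """Simulate genome, library, and reads; write everything under ``out_dir``.

    Emits ``genome.fasta``, ``genes.gff3``, ``<prefix>rep<i>.fastq``,
    ``<prefix>truth_ledger.tsv``, ``<prefix>gene_classes.tsv`` and
    ``sim_config.json`` (the exact reproduction record).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_genome(config)
    fasta = out_dir / "genome.fasta"
    gff = out_dir / "genes.gff3"
    write_genome_fasta(sim, fasta)
    write_genome_gff3(sim, gff)

    library = simulate_library(sim, config, condition_seed=condition_seed)
    fastqs = [out_dir / f"{prefix}rep{r + 1}.fastq" for r in range(config.n_replicates)]
    summaries = simulate_reads(library, sim, fastqs, config)

    ledger_path = out_dir / f"{prefix}truth_ledger.tsv"
    library.ledger.write_tsv(ledger_path)
    classes_path = out_dir / f"{prefix}gene_classes.tsv"
    library.ledger.gene_table.to_csv(classes_path, sep="\t", index=False)
    with open(out_dir / "sim_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2)

    return SimulationResult(
        sim_genome=sim, library=library, read_summaries=summaries,
        paths={"fasta": fasta, "gff": gff, "fastqs": fastqs,
               "ledger": ledger_path, "gene_classes": classes_path})
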