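"""Junction-read processing: from raw FASTQ to candidate genomic inserts.

Library geometry: the transposon-genome junction is liberated with MmeI,
which cuts ~20 bp beyond its recognition site inside the transposon's
inverted repeat (IR).  After end repair and adapter ligation, a forward read
has the layout::

    [revcomp(junction)] [IR remnant, 4 bp] [genomic insert, TA...] [adapter] ...

The genomic insert starts with the TA the transposon sits in and, given the
MmeI geometry, is expected to be 14 bp (tolerated range 14-18 bp).
Processing mirrors the orientation dance of the trimming tools this protocol
is normally run through: trim at the adapter, reverse complement, trim at the
junction, reverse complement back, drop the IR remnant, quality-truncate, and
gate on the TA start and the length window.

Rejection is never silent: every read ends up either accepted or in exactly
one rejection counter of :class:`ProcessingStats`.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import PHRED_OFFSET, revcomp

#: Hard biological bounds on the MmeI tag length; config values stay inside.
_ABS_MIN_INSERT = 14
_ABS_MAX_INSERT = 18

#: Rejection reasons, in the order they can fire.
REJECTION_REASONS = ("no_junction", "quality_fail", "non_ta_start", "length_out_of_range")


@dataclass(frozen=True)
class ProcessingConfig:
    """Trimming parameters.

    ``junction_seq`` is the IR segment containing the MmeI recognition site,
    written in transposon orientation; the default is a mariner-style
    inverted-repeat end carrying the MmeI site (TCCAAC).  ``adapter_seq``
    defaults to the universal Illumina adapter prefix.  Both are plain
    configuration: the exact construct sequences belong to the experiment,
    not the algorithm.  Note the junction anchor should be long relative to
    ``max_mismatches``; a very short junction with a generous mismatch budget
    matches spuriously inside genomic inserts.
    """

    adapter_seq: str = "AGATCGGAAGAGC"
    junction_seq: str = "CGGGGACTTATCATCCAACCTGT"
    ir_remnant_len: int = 4
    max_mismatches: int = 2
    min_insert_len: int = 14
    max_insert_len: int = 18
    qual_threshold: int = 20
    qual_window: int = 1

    def __post_init__(self) -> None:
        if not self.adapter_seq or not self.junction_seq:
            raise ValueError("adapter_seq and junction_seq must be non-empty")
        if self.ir_remnant_len < 0 or self.qual_window < 1:
            raise ValueError("ir_remnant_len must be >= 0 and qual_window >= 1")
        if not (0 < self.min_insert_len <= self.max_insert_len):
            raise ValueError("need 0 < min_insert_len <= max_insert_len")


@dataclass(frozen=True)
class RawRead:
    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.read_id!r}: sequence/quality length mismatch")


@dataclass(frozen=True)
class Insert:
    """An accepted genomic insert: TA-initial, 14-18 bp."""

    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"insert {self.read_id!r}: sequence/quality length mismatch")
        if not self.seq.startswith("TA"):
            raise ValueError(f"insert {self.read_id!r} does not start with TA")
        if not (_ABS_MIN_INSERT <= len(self.seq) <= _ABS_MAX_INSERT):
            raise ValueError(f"insert {self.read_id!r}: length {len(self.seq)} outside 14-18")


@dataclass
class ProcessingStats:
    """Counters reconciling every input read to one outcome."""

    n_input: int = 0
    n_accepted: int = 0
    no_adapter_action: int = 0  # informational: adapter not found, whole read kept
    rejected: dict = field(default_factory=lambda: {r: 0 for r in REJECTION_REASONS})
    _sum_insert_len: int = 0

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    @property
    def mean_insert_len(self) -> float:
        return self._sum_insert_len / self.n_accepted if self.n_accepted else float("nan")

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_accepted": self.n_accepted,
            "no_adapter_action": self.no_adapter_action,
            "rejected": dict(self.rejected),
            "mean_insert_len": self.mean_insert_len,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Approximate matching and truncation primitives
# ---------------------------------------------------------------------------

def find_approx(seq: str, pattern: str, max_mismatches: int) -> int | None:
    """Leftmost position where ``pattern`` matches ``seq`` within a Hamming budget.

    The full pattern must fit; indels are not considered.  Returns None when
    no alignment has at most ``max_mismatches`` mismatches.
    """
    m = len(pattern)
    if m == 0:
        raise ValueError("pattern must be non-empty")
    n = len(seq)
    if n < m:
        return None
    # Exact occurrences bound the scan: only an earlier, inexact match can win.
    exact = seq.find(pattern)
    if exact == 0 or max_mismatches == 0:
        return exact if exact != -1 else None
    stop = exact if exact != -1 else n - m + 1
    for i in range(stop):
        mm = 0
        for j in range(m):
            if seq[i + j] != pattern[j]:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return i
    return exact if exact != -1 else None


def quality_truncate(seq: str, qual: str, config: ProcessingConfig) -> tuple[str, str]:
    """Truncate before the first sliding window whose mean quality drops below
    the threshold (window 1 by default: before the first low-quality base)."""
    w = config.qual_window
    scores = [ord(c) - PHRED_OFFSET for c in qual]
    for i in range(len(scores) - w + 1):
        if sum(scores[i:i + w]) / w < config.qual_threshold:
            return seq[:i], qual[:i]
    return seq, qual


# ---------------------------------------------------------------------------
# Insert extraction
# ---------------------------------------------------------------------------

def _extract(seq: str, qual: str, config: ProcessingConfig):
    """Core extraction; returns (insert_seq, insert_qual, reason, adapter_found).

    Exactly one of insert_seq / reason is non-None.
    """
    # (1) truncate at the adapter; no match keeps the whole read (the junction
    #     match below is the mandatory anchor).
    a = find_approx(seq, config.adapter_seq, config.max_mismatches)
    adapter_found = a is not None
    if adapter_found:
        seq, qual = seq[:a], qual[:a]
    # (2) reverse complement; (3) trim at the junction; (4) back to + sense.
    seq, qual = revcomp(seq), qual[::-1]
    j = find_approx(seq, config.junction_seq, config.max_mismatches)
    if j is None:
        return None, None, "no_junction", adapter_found
    seq, qual = revcomp(seq[:j]), qual[:j][::-1]
    # (5) drop the IR remnant between the MmeI site and genomic DNA.
    seq, qual = seq[config.ir_remnant_len:], qual[config.ir_remnant_len:]
    # (6) quality truncation, then (7) the TA / length gates.
    tseq, tqual = quality_truncate(seq, qual, config)
    if len(tseq) < len(seq) and len(tseq) < config.min_insert_len:
        return None, None, "quality_fail", adapter_found
    if not tseq.startswith("TA"):
        return None, None, "non_ta_start", adapter_found
    if not (config.min_insert_len <= len(tseq) <= config.max_insert_len):
        return None, None, "length_out_of_range", adapter_found
    return tseq, tqual, None, adapter_found


def extract_insert(read: RawRead, config: ProcessingConfig = ProcessingConfig()):
    """Extract the genomic insert from one read.

    Returns an :class:`Insert` on success, or the rejection reason (one of
    :data:`REJECTION_REASONS`) as a string.
    """
    seq, qual, reason, _ = _extract(read.seq, read.qual, config)
    if reason is not None:
        return reason
    return Insert(read_id=read.read_id, seq=seq, qual=qual)


# ---------------------------------------------------------------------------
# FASTQ streaming
# ---------------------------------------------------------------------------

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(handle) -> Iterator[tuple[str, str, str]]:
    it = FastqGeneralIterator(handle)
    i = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {i}: {exc}") from exc
        yield rec
        i += 1


def iter_inserts(records: Iterable[tuple[str, str, str]],
                 config: ProcessingConfig,
                 stats: ProcessingStats,
                 memo: dict | None = None) -> Iterator[Insert]:
    """Stream (id, seq, qual) records through extraction, updating ``stats``.

    ``memo`` optionally caches outcomes keyed on (seq, qual) — extraction is a
    pure function of the read content, and amplified libraries contain many
    identical reads.
    """
    for read_id, seq, qual in records:
        stats.n_input += 1
        key = (seq, qual)
        if memo is not None and key in memo:
            out = memo[key]
        else:
            out = _extract(seq, qual, config)
            if memo is not None:
                memo[key] = out
        iseq, iqual, reason, adapter_found = out
        if not adapter_found:
            stats.no_adapter_action += 1
        if reason is not None:
            stats.rejected[reason] += 1
            continue
        stats.n_accepted += 1
        stats._sum_insert_len += len(iseq)
        yield Insert(read_id=read_id, seq=iseq, qual=iqual)


def process_fastq(path, config: ProcessingConfig = ProcessingConfig()
                  ) -> tuple[list[Insert], ProcessingStats]:
    """Process a FASTQ file (optionally gzipped) into accepted inserts.

    Order-preserving; ``stats`` totals reconcile (accepted + rejected ==
    input).  Malformed records raise with the record index.
    """
    stats = ProcessingStats()
    with _open_text(path) as fh:
        inserts = list(iter_inserts(_iter_fastq(fh), config, stats, memo={}))
    return inserts, stats


def write_inserts_tsv(inserts: Iterable[Insert], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tseq\tqual\n")
        for ins in inserts:
            fh.write(f"{ins.read_id}\t{ins.seq}\t{ins.qual}\n")


def read_inserts_tsv(path) -> list[Insert]:
    inserts = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: not an inserts TSV")
        for line in fh:
            read_id, seq, qual = line.rstrip("\n").split("\t")
            inserts.append(Insert(read_id=read_id, seq=seq, qual=qual))
    return inserts
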