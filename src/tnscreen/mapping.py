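"""Exact mapping of genomic inserts to TA sites.

Inserts are 14-18 bp and must match the genome with 100% identity at a
unique location, so the engine is an exact-match lookup rather than a general
aligner.  Every genomic occurrence of a TA-initial insert necessarily starts
at a TA dinucleotide (forward strand) or ends at one (reverse strand), so the
per-site 14-mer context already held by the :class:`~tnscreen.genome.TASiteIndex`
doubles as a complete occurrence index for insert-shaped queries.  Arbitrary
queries fall back to a direct string scan; both paths agree.

Both orientations of one insertion event collapse to the same TA site: a
reverse-strand hit ending at the TA at position ``p`` is reported as site
``p`` with strand ``-``.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import revcomp
from .genome import KMER_LEN, Genome, TASiteIndex, enumerate_ta_sites

#: Sentinel outcomes of :func:`map_insert`.
MULTI = "multi"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class MappedInsertion:
    read_id: str
    replicon_id: str
    site_position: int
    strand: str


class GenomeIndex:
    """Occurrence lookup for 14-18-mers on both strands of the genome."""

    def __init__(self, genome: Genome, ta_index: TASiteIndex | None = None):
        self.genome = genome
        self._seqs = {r.id: r.seq for r in genome.replicons}
        ta_index = ta_index if ta_index is not None else enumerate_ta_sites(genome)
        self.ta_index = ta_index
        # fwd: 14-mer starting at the site's T -> [(replicon, site)]
        # rev: revcomp of the 14 bases ending at the site's A -> [(replicon, site)]
        self._fwd: dict[str, list] = defaultdict(list)
        self._rev: dict[str, list] = defaultdict(list)
        for rid, pos, fwd, rev, _ in ta_index.iter_sites():
            if fwd is not None:
                self._fwd[fwd].append((rid, pos))
            if rev is not None:
                self._rev[rev].append((rid, pos))
        self._fwd = dict(self._fwd)
        self._rev = dict(self._rev)

    # -- generic occurrence listing -------------------------------------

    def occurrences(self, query: str) -> list[tuple[str, int, str]]:
        """All (replicon, start, strand) where ``query`` occurs, both strands.

        ``start`` is the 0-based leftmost genomic coordinate of the match on
        the forward strand of the replicon.
        """
        n = len(query)
        if query.startswith("TA") and KMER_LEN <= n <= 18:
            return self._occurrences_ta(query)
        return self._occurrences_scan(query)

    def _occurrences_ta(self, query: str) -> list[tuple[str, int, str]]:
        n = len(query)
        hits = []
        for rid, p in self._fwd.get(query[:KMER_LEN], ()):
            if self._seqs[rid][p:p + n] == query:
                hits.append((rid, p, "+"))
        # A reverse-strand occurrence ends at the TA: genome[p-n+2 : p+2] is
        # revcomp(query), and the query's first 14-mer equals the site's rev k-mer.
        for rid, p in self._rev.get(query[:KMER_LEN], ()):
            start = p - n + 2
            if start >= 0 and revcomp(self._seqs[rid][start:p + 2]) == query:
                hits.append((rid, start, "-"))
        return hits

    def _occurrences_scan(self, query: str) -> list[tuple[str, int, str]]:
        hits = []
        rc = revcomp(query)
        for rid, seq in self._seqs.items():
            for pattern, strand in ((query, "+"), (rc, "-")):
                start = seq.find(pattern)
                while start != -1:
                    hits.append((rid, start, strand))
                    start = seq.find(pattern, start + 1)
        # Palindromes occur identically on both strands at one locus: both
        # orientations are reported, as for the TA fast path.
        return sorted(hits)


def build_index(genome: Genome, ta_index: TASiteIndex | None = None) -> GenomeIndex:
    """Build the exact-match occurrence index for a genome."""
    return GenomeIndex(genome, ta_index)


def map_insert(insert, index: GenomeIndex):
    """Place one insert: a unique occurrence yields a :class:`MappedInsertion`;
    more than one (across both strands) yields :data:`MULTI`; none,
    :data:`UNMAPPED`."""
    occ = index.occurrences(insert.seq)
    if len(occ) == 0:
        return UNMAPPED
    if len(occ) > 1:
        return MULTI
    rid, start, strand = occ[0]
    site = start if strand == "+" else start + len(insert.seq) - 2
    return MappedInsertion(read_id=insert.read_id, replicon_id=rid,
                           site_position=site, strand=strand)


class InsertionTable:
    """Per-(replicon, site) read counts plus library-level totals."""

    def __init__(self):
        self._counts: dict[tuple[str, int], list] = {}
        self.total_multi = 0
        self.total_unmapped = 0

    def add(self, mapped: MappedInsertion) -> None:
        key = (mapped.replicon_id, mapped.site_position)
        cell = self._counts.get(key)
        if cell is None:
            cell = self._counts[key] = [0, 0]
        cell[0 if mapped.strand == "+" else 1] += 1

    @property
    def total_unique_mapped(self) -> int:
        return sum(f + r for f, r in self._counts.values())

    @property
    def n_sites(self) -> int:
        return len(self._counts)

    def reads_total(self, replicon_id: str, position: int) -> int:
        cell = self._counts.get((replicon_id, position))
        return cell[0] + cell[1] if cell else 0

    def site_totals(self, replicon_id: str) -> dict[int, int]:
        """position -> reads_total for one replicon."""
        return {pos: f + r for (rid, pos), (f, r) in self._counts.items()
                if rid == replicon_id}

    @property
    def df(self) -> pd.DataFrame:
        rows = [
            {"replicon": rid, "position": pos, "reads_fwd": f, "reads_rev": r,
             "reads_total": f + r}
            for (rid, pos), (f, r) in sorted(self._counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["replicon", "position", "reads_fwd", "reads_rev", "reads_total"])

    def reads_per_site(self) -> np.ndarray:
        return np.array([f + r for f, r in self._counts.values()], dtype=np.int64)

    def stats_dict(self) -> dict:
        return {
            "total_unique_mapped": self.total_unique_mapped,
            "total_multi": self.total_multi,
            "total_unmapped": self.total_unmapped,
            "n_insertion_sites": self.n_sites,
        }

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def write_stats_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.stats_dict(), fh, indent=2)

    @classmethod
    def from_tsv(cls, path) -> "InsertionTable":
        table = cls()
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            table._counts[(row.replicon, int(row.position))] = [
                int(row.reads_fwd), int(row.reads_rev)]
        return table


def tally_insertions(mapped: Iterable) -> InsertionTable:
    """Aggregate mapping outcomes (MappedInsertion | "multi" | "unmapped")."""
    table = InsertionTable()
    for m in mapped:
        if m is MULTI or m == MULTI:
            table.total_multi += 1
        elif m is UNMAPPED or m == UNMAPPED:
            table.total_unmapped += 1
        else:
            table.add(m)
    return table


def map_and_tally(inserts: Iterable, index: GenomeIndex,
                  memo: bool = True) -> InsertionTable:
    """Stream inserts through mapping into an :class:`InsertionTable`.

    With ``memo``, mapping outcomes are cached per insert sequence (mapping is
    a pure function of the sequence), which matters for deep libraries where
    most reads repeat a site already seen.
    """
    table = InsertionTable()
    cache: dict[str, tuple] = {}
    for ins in inserts:
        if memo and ins.seq in cache:
            res = cache[ins.seq]
        else:
            occ = index.occurrences(ins.seq)
            if len(occ) == 0:
                res = UNMAPPED
            elif len(occ) > 1:
                res = MULTI
            else:
                rid, start, strand = occ[0]
                site = start if strand == "+" else start + len(ins.seq) - 2
                res = (rid, site, strand)
            if memo:
                cache[ins.seq] = res
        if res == UNMAPPED:
            table.total_unmapped += 1
        elif res == MULTI:
            table.total_multi += 1
        else:
            rid, site, strand = res
            cell = table._counts.get((rid, site))
            if cell is None:
                cell = table._counts[(rid, site)] = [0, 0]
            cell[0 if strand == "+" else 1] += 1
    return table
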