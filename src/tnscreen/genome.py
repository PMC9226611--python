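"""Genome, annotation, and TA-site models for mariner/Himar1 Tn-seq.

The mariner (Himar1) transposon inserts exclusively at TA dinucleotides, so
the universe of candidate insertion sites for a screen is the set of TA
positions in the genome.  This module loads the genome and its annotation,
enumerates TA sites, flags sites whose flanking 14-mers are not unique in the
genome (reads from such sites cannot be placed unambiguously), computes
per-gene TA-site profiles used by the downstream exclusion and "first 95%"
rules, and provides two small sequence utilities: per-replicon length/GC
statistics and a proteome scan for c-type cytochrome heme-attachment motifs
(CX(2-4)CH).

Coordinates are 0-based half-open everywhere inside the package; GFF3's
1-based inclusive convention is converted at the boundary in
:func:`load_annotation`.  A TA "site" is identified by the position of its T
on the forward strand.  TA is its own reverse complement, so one site per
position covers insertions recovered from either strand.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import DNA_ALPHABET, revcomp

#: Length of the genomic tag carried by an MmeI junction read; site identity
#: (the "duplicated site" test) is judged on this length.
KMER_LEN = 14

#: Fraction of the gene length, measured from the start codon, inside which
#: insertions are considered disruptive.  Insertions in the trailing 5% of a
#: gene are ignored downstream because they often leave a functional product.
FIRST_FRACTION = 0.95


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Replicon:
    """One sequence record of the genome (chromosome or plasmid)."""

    id: str
    seq: str
    topology: str = "circular"  # "circular" | "linear"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"replicon {self.id!r} has an empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"replicon {self.id!r}: bad topology {self.topology!r}")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"replicon {self.id!r} contains non-ACGTN characters: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Genome:
    """Ordered collection of replicons with unique ids."""

    replicons: tuple[Replicon, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError("replicon ids are not unique")
        if not self.replicons:
            raise ValueError("genome has no replicons")

    def __getitem__(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def __contains__(self, replicon_id: str) -> bool:
        return any(r.id == replicon_id for r in self.replicons)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.replicons)


@dataclass(frozen=True)
class Gene:
    """A gene interval, 0-based half-open, with strand."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id!r}: bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class _RepliconSites:
    positions: np.ndarray          # sorted 0-based T positions
    fwd_kmers: list                # str or None (undefined at a linear edge)
    rev_kmers: list
    duplicated: np.ndarray         # bool per site


@dataclass
class TASiteIndex:
    """All TA positions per replicon with 14-mer context and uniqueness flags.

    ``fwd_kmer`` is the 14-mer starting at the T; ``rev_kmer`` is the reverse
    complement of the 14 bases ending at the A.  Both are the genomic tags a
    junction read from that site would carry, one per transposon orientation.
    On circular replicons k-mers wrap across the origin; on linear replicons a
    site within 12 bp of the relevant end has that k-mer undefined.
    """

    per_replicon: dict[str, _RepliconSites] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return sum(len(s.positions) for s in self.per_replicon.values())

    @property
    def n_duplicated(self) -> int:
        return int(sum(s.duplicated.sum() for s in self.per_replicon.values()))

    def positions(self, replicon_id: str) -> np.ndarray:
        return self.per_replicon[replicon_id].positions

    def duplicated(self, replicon_id: str) -> np.ndarray:
        return self.per_replicon[replicon_id].duplicated

    def fwd_kmers(self, replicon_id: str) -> list:
        return self.per_replicon[replicon_id].fwd_kmers

    def rev_kmers(self, replicon_id: str) -> list:
        return self.per_replicon[replicon_id].rev_kmers

    def iter_sites(self):
        """Yield (replicon_id, position, fwd_kmer, rev_kmer, duplicated)."""
        for rid, s in self.per_replicon.items():
            for i, p in enumerate(s.positions):
                yield rid, int(p), s.fwd_kmers[i], s.rev_kmers[i], bool(s.duplicated[i])


@dataclass(frozen=True)
class GeneTAProfile:
    """Per-gene TA-site bookkeeping feeding the exclusion rules."""

    gene_id: str
    n_ta_total: int
    n_ta_unique: int
    n_ta_first95: int
    n_ta_unique_first95: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_ta_unique <= self.n_ta_total):
            raise ValueError(f"{self.gene_id}: n_ta_unique out of range")
        if self.n_ta_first95 > self.n_ta_total:
            raise ValueError(f"{self.gene_id}: n_ta_first95 > n_ta_total")


@dataclass(frozen=True)
class MotifHit:
    """Count of heme-binding motifs (CX(2-4)CH) in one protein."""

    protein_id: str
    n_motifs: int

    def __post_init__(self) -> None:
        if self.n_motifs < 0:
            raise ValueError("n_motifs must be >= 0")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_genome(fasta_path, topology: str | Mapping[str, str] = "circular") -> Genome:
    """Load a (multi-record) FASTA file into a :class:`Genome`.

    Parameters
    ----------
    fasta_path : path-like
        FASTA file, one record per replicon, in file order.
    topology : str or mapping
        Either a single topology applied to every replicon (bacterial
        replicons are circular by default) or a mapping ``{record id:
        "circular"|"linear"}``.

    Sequences are uppercased; characters outside ``ACGTN`` raise a
    :class:`ValueError` naming the offending record.
    """
    replicons = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        topo = topology if isinstance(topology, str) else topology.get(record.id, "circular")
        try:
            replicons.append(Replicon(id=record.id, seq=seq, topology=topo))
        except ValueError as exc:
            raise ValueError(f"FASTA record {record.id!r}: {exc}") from exc
    if not replicons:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return Genome(replicons=tuple(replicons))


def load_annotation(gff_path, genome: Genome,
                    feature_types: Sequence[str] = ("gene", "CDS")) -> list[Gene]:
    """Load gene intervals from a GFF3 file.

    Features of the first type in ``feature_types`` that is present are used
    (``gene`` preferred over ``CDS``).  GFF3 1-based inclusive coordinates are
    converted to 0-based half-open.  Genes on replicons absent from
    ``genome``, coordinates outside the replicon, and duplicate IDs all raise
    :class:`ValueError`.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    genes: list[Gene] = []
    for ftype in feature_types:
        feats = list(db.features_of_type(ftype, order_by=("seqid", "start")))
        if feats:
            break
    else:
        feats = []
    seen: set[str] = set()
    for f in feats:
        gene_id = f.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene ID {gene_id!r} in {gff_path}")
        seen.add(gene_id)
        if f.seqid not in genome:
            raise ValueError(
                f"gene {gene_id!r} is on replicon {f.seqid!r}, absent from the genome"
            )
        start, end = f.start - 1, f.end  # 1-based inclusive -> 0-based half-open
        if not (0 <= start < end <= len(genome[f.seqid])):
            raise ValueError(
                f"gene {gene_id!r}: interval [{f.start}, {f.end}] outside replicon {f.seqid!r}"
            )
        product = f.attributes.get("product", [""])[0]
        genes.append(Gene(gene_id=gene_id, replicon_id=f.seqid,
                          start=start, end=end, strand=f.strand, product=product))
    return genes


# ---------------------------------------------------------------------------
# TA-site enumeration and uniqueness
# ---------------------------------------------------------------------------

def _ta_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    mask = (arr[:-1] == ord("T")) & (arr[1:] == ord("A"))
    return np.flatnonzero(mask).astype(np.int64)


def _fwd_kmer(seq: str, p: int, circular: bool) -> str | None:
    L = len(seq)
    if p + KMER_LEN <= L:
        return seq[p:p + KMER_LEN]
    if circular:
        return seq[p:] + seq[:p + KMER_LEN - L]
    return None


def _rev_kmer(seq: str, p: int, circular: bool) -> str | None:
    s = p + 2 - KMER_LEN
    if s >= 0:
        return revcomp(seq[s:p + 2])
    if circular:
        return revcomp(seq[s:] + seq[:p + 2])
    return None


def enumerate_ta_sites(genome: Genome) -> TASiteIndex:
    """Enumerate every forward-strand TA position per replicon.

    Overlapping TAs (as in ``TATA``) each count.  TA is palindromic, so a
    single forward-strand position represents insertions on either strand.
    Duplicated flags are initialised to False; call
    :func:`mark_duplicated_sites` to fill them in.
    """
    index = TASiteIndex()
    for rep in genome.replicons:
        circular = rep.topology == "circular"
        positions = _ta_positions(rep.seq)
        fwd = [_fwd_kmer(rep.seq, int(p), circular) for p in positions]
        rev = [_rev_kmer(rep.seq, int(p), circular) for p in positions]
        index.per_replicon[rep.id] = _RepliconSites(
            positions=positions, fwd_kmers=fwd, rev_kmers=rev,
            duplicated=np.zeros(len(positions), dtype=bool),
        )
    return index


def mark_duplicated_sites(index: TASiteIndex, genome: Genome) -> TASiteIndex:
    """Flag sites whose 14-mer context is shared with any other site.

    A site is duplicated when its forward or reverse k-mer occurs as the
    forward or reverse k-mer of any *other* site, across all replicons: a
    read from either transposon orientation at such a site could equally have
    come from elsewhere.  A site with an undefined k-mer (linear-replicon
    edge) is treated as duplicated for that orientation.  Mutates and returns
    ``index``.
    """
    counts: Counter = Counter()
    for _, _, fwd, rev, _ in index.iter_sites():
        if fwd is not None:
            counts[fwd] += 1
        if rev is not None:
            counts[rev] += 1
    for sites in index.per_replicon.values():
        dup = sites.duplicated
        for i, (fwd, rev) in enumerate(zip(sites.fwd_kmers, sites.rev_kmers)):
            if fwd is None or rev is None:
                dup[i] = True
                continue
            own_fwd = 1 + (fwd == rev)
            own_rev = 1 + (fwd == rev)
            if counts[fwd] - own_fwd > 0 or counts[rev] - own_rev > 0:
                dup[i] = True
    return index


# ---------------------------------------------------------------------------
# Per-gene profiles
# ---------------------------------------------------------------------------

def first95_mask(positions: np.ndarray, gene: Gene) -> np.ndarray:
    """Boolean mask of sites falling in the first 95% of the gene.

    Offsets are strand-aware: ``p - start`` on the + strand and
    ``(end - 2) - p`` on the - strand (the TA nearest the stop codon of a
    - strand gene has the largest offset).  A site is inside the first 95%
    when its offset is strictly below ``floor(0.95 * length)``.
    """
    if gene.strand == "+":
        offsets = positions - gene.start
    else:
        offsets = (gene.end - 2) - positions
    return offsets < int(np.floor(FIRST_FRACTION * gene.length))


def gene_ta_profile(genes: Iterable[Gene], index: TASiteIndex) -> list[GeneTAProfile]:
    """Compute TA-site counts per gene (total, unique, first-95%).

    A site belongs to a gene when its T position lies in ``[start, end)``;
    a site inside two overlapping genes counts for both.
    """
    profiles = []
    for gene in genes:
        sites = index.per_replicon[gene.replicon_id]
        lo, hi = np.searchsorted(sites.positions, [gene.start, gene.end])
        pos = sites.positions[lo:hi]
        dup = sites.duplicated[lo:hi]
        in95 = first95_mask(pos, gene)
        profiles.append(GeneTAProfile(
            gene_id=gene.gene_id,
            n_ta_total=int(len(pos)),
            n_ta_unique=int((~dup).sum()),
            n_ta_first95=int(in95.sum()),
            n_ta_unique_first95=int((in95 & ~dup).sum()),
        ))
    return profiles


# ---------------------------------------------------------------------------
# Sequence statistics and motif scan
# ---------------------------------------------------------------------------

def genome_stats(genome: Genome) -> pd.DataFrame:
    """Per-replicon length (bp) and GC content (percent).

    GC is (G+C)/(A+C+G+T); N bases are excluded from the denominator.
    """
    rows = []
    for rep in genome.replicons:
        arr = np.frombuffer(rep.seq.encode("ascii"), dtype=np.uint8)
        gc = int(((arr == ord("G")) | (arr == ord("C"))).sum())
        acgt = int(np.isin(arr, [ord(b) for b in "ACGT"]).sum())
        rows.append({
            "replicon": rep.id,
            "length_bp": len(rep),
            "gc_percent": 100.0 * gc / acgt if acgt else float("nan"),
        })
    return pd.DataFrame(rows)


#: Heme-attachment motif of c-type cytochromes: C, 2-4 arbitrary residues, C, H.
#: The lazy quantifier takes the shortest spacer first at each scan position;
#: re.finditer yields non-overlapping matches left to right.
_HEME_MOTIF = re.compile(r"C.{2,4}?CH")


def scan_heme_motifs(proteins: Mapping[str, str]) -> list[MotifHit]:
    """Count non-overlapping CX(2-4)CH motifs in each protein sequence."""
    return [
        MotifHit(protein_id=pid, n_motifs=sum(1 for _ in _HEME_MOTIF.finditer(seq.upper())))
        for pid, seq in proteins.items()
    ]


def load_proteins(fasta_path) -> dict[str, str]:
    """Load a protein FASTA into an id -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------

def write_ta_sites_tsv(index: TASiteIndex, path) -> None:
    rows = [
        {"replicon": rid, "position": pos, "duplicated": int(dup)}
        for rid, pos, _, _, dup in index.iter_sites()
    ]
    pd.DataFrame(rows, columns=["replicon", "position", "duplicated"]).to_csv(
        path, sep="\t", index=False)


def write_gene_ta_profile_tsv(profiles: Iterable[GeneTAProfile], path) -> None:
    pd.DataFrame([p.__dict__ for p in profiles]).to_csv(path, sep="\t", index=False)


def write_motif_hits_tsv(hits: Iterable[MotifHit], path) -> None:
    pd.DataFrame([h.__dict__ for h in hits]).to_csv(path, sep="\t", index=False)
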