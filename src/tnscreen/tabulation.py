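"""Per-gene read counts, exclusion filters, and RpK normalization.

A gene's raw read count sums the uniquely-mapped reads at *non-duplicated* TA
sites lying in the first 95% of the gene (strand-aware); insertions in the
trailing 5% are ignored because they often fail to disrupt function.  Counts
become reads-per-kilobase (RpK = raw / (length/1000)), are normalized to a
library size of 10^7 uniquely mapped reads, and enter the classifier as
log2(normalized RpK).

Genes are excluded (with precedence) when they have no TA sites at all, no TA
sites in the first 95%, or fewer than half of their TA sites unique —
strictly fewer, so exactly half passes.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome import Gene, GeneTAProfile, TASiteIndex, first95_mask
from .mapping import InsertionTable

#: Library size all RpK values are scaled to.
NORM_TOTAL = 10_000_000

EXCLUSION_NONE = "none"
EXCLUSIONS = ("no_ta", "no_ta_first95", "under_half_unique")


def apply_gene_filters(profiles: Iterable[GeneTAProfile]) -> dict[str, str]:
    """Assign each gene an exclusion reason (or ``"none"``).

    Precedence: no_ta > no_ta_first95 > under_half_unique.
    """
    out = {}
    for p in profiles:
        if p.n_ta_total == 0:
            out[p.gene_id] = "no_ta"
        elif p.n_ta_first95 == 0:
            out[p.gene_id] = "no_ta_first95"
        elif p.n_ta_unique < p.n_ta_total / 2:
            out[p.gene_id] = "under_half_unique"
        else:
            out[p.gene_id] = EXCLUSION_NONE
    return out


def count_gene_reads(table: InsertionTable, genes: Iterable[Gene],
                     index: TASiteIndex) -> dict[str, int]:
    """Raw per-gene reads: unique (non-duplicated) sites in the first 95%.

    A site inside two overlapping genes contributes to both.
    """
    genes = list(genes)
    totals_by_rep: dict[str, dict[int, int]] = {}
    counts: dict[str, int] = {}
    for gene in genes:
        if gene.replicon_id not in totals_by_rep:
            totals_by_rep[gene.replicon_id] = table.site_totals(gene.replicon_id)
        site_reads = totals_by_rep[gene.replicon_id]
        sites = index.per_replicon[gene.replicon_id]
        lo, hi = np.searchsorted(sites.positions, [gene.start, gene.end])
        pos = sites.positions[lo:hi]
        keep = first95_mask(pos, gene) & ~sites.duplicated[lo:hi]
        counts[gene.gene_id] = int(sum(site_reads.get(int(p), 0) for p in pos[keep]))
    return counts


def normalize(gene_reads: Mapping[str, int], genes: Iterable[Gene],
              total_unique_mapped: int,
              exclusions: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Build the per-gene counts table with RpK, normalized RpK, and log2.

    ``norm_rpk = rpk * (10^7 / total_unique_mapped)``; the RpK denominator is
    the full annotated gene length.  ``log2_norm_rpk`` is NaN for zero-read
    and excluded genes.  ``total_unique_mapped`` covers all replicons jointly
    and must be positive.
    """
    if total_unique_mapped <= 0:
        raise ValueError("total_unique_mapped must be > 0")
    exclusions = exclusions or {}
    rows = []
    scale = NORM_TOTAL / total_unique_mapped
    for gene in genes:
        raw = int(gene_reads.get(gene.gene_id, 0))
        excluded = exclusions.get(gene.gene_id, EXCLUSION_NONE)
        rpk = raw / (gene.length / 1000)
        norm = rpk * scale
        log2 = math.log2(norm) if raw > 0 and excluded == EXCLUSION_NONE else float("nan")
        rows.append({
            "gene_id": gene.gene_id,
            "gene_length_bp": gene.length,
            "raw_reads": raw,
            "rpk": rpk,
            "norm_rpk": norm,
            "log2_norm_rpk": log2,
            "excluded": excluded,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def write_gene_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_gene_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
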