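"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (quadratic scans, per-position loops)
and shares no code with the package internals it checks.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_ta_positions(seq: str) -> list[int]:
    return [i for i in range(len(seq) - 1) if seq[i:i + 2] == "TA"]


def brute_site_kmers(seq: str, pos: int, circular: bool, k: int = 14):
    """(fwd, rev) k-mer context of a TA site, None when undefined."""
    L = len(seq)
    ext = seq + seq if circular else seq
    fwd = ext[pos:pos + k] if (circular or pos + k <= L) else None
    start = pos + 2 - k
    if start >= 0:
        rev = rc(seq[start:pos + 2])
    elif circular:
        rev = rc(seq[start + L:] + seq[:pos + 2])
    else:
        rev = None
    return fwd, rev


def brute_duplicated_flags(replicons: list[tuple[str, str, bool]]) -> dict:
    """All-pairs duplicate test over every site's orientation k-mers.

    ``replicons``: list of (id, seq, circular).  Returns {(id, pos): bool}.
    """
    sites = []
    for rid, seq, circular in replicons:
        for pos in brute_ta_positions(seq):
            fwd, rev = brute_site_kmers(seq, pos, circular)
            sites.append((rid, pos, fwd, rev))
    flags = {}
    for i, (rid, pos, fwd, rev) in enumerate(sites):
        dup = fwd is None or rev is None
        if not dup:
            for j, (_, _, f2, r2) in enumerate(sites):
                if i == j:
                    continue
                if fwd in (f2, r2) or rev in (f2, r2):
                    dup = True
                    break
        flags[(rid, pos)] = dup
    return flags


def brute_occurrences(replicons: dict[str, str], query: str) -> list[tuple]:
    """Every (replicon, start, strand) where query matches exactly."""
    hits = []
    q_rc = rc(query)
    for rid, seq in replicons.items():
        for i in range(len(seq) - len(query) + 1):
            window = seq[i:i + len(query)]
            if window == query:
                hits.append((rid, i, "+"))
            if window == q_rc:
                hits.append((rid, i, "-"))
    return sorted(hits)


def brute_find_approx(seq: str, pattern: str, max_mm: int):
    """Leftmost alignment with Hamming distance <= max_mm, else None."""
    for i in range(len(seq) - len(pattern) + 1):
        if sum(a != b for a, b in zip(seq[i:i + len(pattern)], pattern)) <= max_mm:
            return i
    return None


def brute_gene_profile(seq: str, start: int, end: int, strand: str,
                       dup_flags: dict, rid: str):
    """(n_total, n_unique, n_first95) by scanning every position of the gene."""
    import math

    cutoff = math.floor(0.95 * (end - start))
    n_total = n_unique = n_first95 = 0
    for p in range(start, end):
        if seq[p:p + 2] != "TA":
            continue
        n_total += 1
        if not dup_flags[(rid, p)]:
            n_unique += 1
        offset = p - start if strand == "+" else (end - 2) - p
        if offset < cutoff:
            n_first95 += 1
    return n_total, n_unique, n_first95
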