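"""Cross-condition set analysis of consensus essentiality calls.

"Essential" for set algebra means consensus Essential only — not
GrowthDefect, not Uncertain.  A gene Uncertain in one condition simply does
not count as essential there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .classify import (CATEGORIES, ESSENTIAL, EXCLUDED, GROWTH_ADVANTAGE,
                       GROWTH_DEFECT, NON_ESSENTIAL, UNCERTAIN, Z_CATEGORIES)


@dataclass(frozen=True)
class ConditionCalls:
    """Consensus category per gene for one growth condition."""

    condition_name: str
    calls: Mapping[str, str]

    def essential_set(self) -> frozenset[str]:
        return frozenset(g for g, c in self.calls.items() if c == ESSENTIAL)


@dataclass(frozen=True)
class MembershipPattern:
    """One cell of an UpSet decomposition: which conditions a gene set is
    essential in, with the genes carrying that exact pattern."""

    conditions: tuple[str, ...]
    pattern: tuple[bool, ...]
    genes: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.genes)


def summarize_condition(calls: ConditionCalls) -> dict[str, int]:
    """Counts per category (the five call categories; Excluded separately)."""
    counts = {c: 0 for c in (ESSENTIAL, GROWTH_DEFECT, NON_ESSENTIAL,
                             GROWTH_ADVANTAGE, UNCERTAIN, EXCLUDED)}
    for cat in calls.calls.values():
        if cat not in counts:
            raise ValueError(f"unknown category {cat!r}")
        counts[cat] += 1
    return counts


def core_essential(conditions: Sequence[ConditionCalls]) -> frozenset[str]:
    """Genes essential in every condition (the core essential genome)."""
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    sets = [c.essential_set() for c in conditions]
    return frozenset.intersection(*sets)


def membership_matrix(conditions: Sequence[ConditionCalls]) -> list[MembershipPattern]:
    """UpSet-style decomposition of the union of essential genes.

    Every gene essential in at least one condition lands in exactly one
    pattern; pattern counts sum to the size of the union.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    names = tuple(c.condition_name for c in conditions)
    sets = [c.essential_set() for c in conditions]
    union = sorted(frozenset.union(*sets))
    buckets: dict[tuple[bool, ...], list[str]] = {}
    for gene in union:
        pattern = tuple(gene in s for s in sets)
        buckets.setdefault(pattern, []).append(gene)
    return [
        MembershipPattern(conditions=names, pattern=pattern, genes=tuple(genes))
        for pattern, genes in sorted(buckets.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]


def condition_specific(conditions: Sequence[ConditionCalls],
                       target_names: Sequence[str],
                       background_names: Sequence[str]) -> frozenset[str]:
    """Genes essential in every target condition and in no background condition.

    Target and background condition lists must be disjoint.
    """
    if set(target_names) & set(background_names):
        raise ValueError("target and background conditions overlap")
    by_name = {c.condition_name: c for c in conditions}
    targets = [by_name[n].essential_set() for n in target_names]
    if not targets:
        raise ValueError("need at least one target condition")
    result = frozenset.intersection(*targets)
    for n in background_names:
        result -= by_name[n].essential_set()
    return frozenset(result)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def summary_table(conditions: Sequence[ConditionCalls]) -> pd.DataFrame:
    """Per-condition category counts, one row per condition."""
    rows = []
    for cond in conditions:
        row = {"condition": cond.condition_name}
        row.update(summarize_condition(cond))
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition")


def write_summary_tsv(conditions: Sequence[ConditionCalls], path) -> None:
    summary_table(conditions).to_csv(path, sep="\t")


def upset_table(patterns: Sequence[MembershipPattern]) -> pd.DataFrame:
    rows = []
    for p in patterns:
        row = {name: int(flag) for name, flag in zip(p.conditions, p.pattern)}
        row["count"] = p.count
        row["genes"] = ",".join(p.genes)
        rows.append(row)
    return pd.DataFrame(rows)


def write_upset_tsv(patterns: Sequence[MembershipPattern], path) -> None:
    upset_table(patterns).to_csv(path, sep="\t", index=False)


def export_json(conditions: Sequence[ConditionCalls], path) -> None:
    """JSON export (per-condition summaries, core set, membership patterns)
    suitable for external plotting."""
    patterns = membership_matrix(conditions)
    payload = {
        "conditions": [c.condition_name for c in conditions],
        "summaries": {c.condition_name: summarize_condition(c) for c in conditions},
        "core_essential": sorted(core_essential(conditions)) if len(conditions) >= 2 else None,
        "membership": [
            {"pattern": dict(zip(p.conditions, p.pattern)), "count": p.count,
             "genes": list(p.genes)}
            for p in patterns
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
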