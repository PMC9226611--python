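"""Essentiality classification from log2(normalized RpK) distributions.

Per replicate, the log2(normalized RpK) values of all countable genes form a
roughly normal distribution.  Outliers are removed (one-pass Tukey fences at
Q1 - k*IQR and Q3 + k*IQR with k = 3, the conventional "far outlier" rule;
the trimming rule is a free design choice and is recorded in run metadata),
the mean and standard deviation of the retained values are computed, and each
gene is placed by its z-score:

===========================  ==========================
z < -3                       Essential
-3 <= z < -2                 GrowthDefect
-2 <= z <= 2                 NonEssential
z > 2                        GrowthAdvantage
===========================  ==========================

The Essential region therefore lies below the interval covering 99.7% of a
normal distribution.  Genes with zero reads never enter the fit (log2(0) is
undefined) and are called Essential categorically: transposon insertion in a
truly essential gene is lethal, so surviving mutants leave no reads.  Genes
excluded upstream (no TA sites, etc.) are carried through as ``Excluded``.

Replicates are combined by unanimity: a gene keeps a category only when every
replicate agrees; otherwise it is ``Uncertain``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ESSENTIAL = "Essential"
GROWTH_DEFECT = "GrowthDefect"
NON_ESSENTIAL = "NonEssential"
GROWTH_ADVANTAGE = "GrowthAdvantage"
UNCERTAIN = "Uncertain"
EXCLUDED = "Excluded"

#: The four z-interval categories in increasing order of insertion frequency.
Z_CATEGORIES = (ESSENTIAL, GROWTH_DEFECT, NON_ESSENTIAL, GROWTH_ADVANTAGE)
CATEGORIES = Z_CATEGORIES + (UNCERTAIN, EXCLUDED)


@dataclass(frozen=True)
class ClassifierConfig:
    """SD thresholds and outlier-trimming parameters."""

    essential_z: float = -3.0
    defect_z: float = -2.0
    advantage_z: float = 2.0
    outlier_method: str = "tukey"
    tukey_k: float = 3.0

    def __post_init__(self) -> None:
        if not (self.essential_z < self.defect_z < 0 < self.advantage_z):
            raise ValueError("need essential_z < defect_z < 0 < advantage_z")
        if self.outlier_method != "tukey":
            raise ValueError(f"unknown outlier method {self.outlier_method!r}")
        if self.tukey_k <= 0:
            raise ValueError("tukey_k must be positive")


@dataclass(frozen=True)
class FitResult:
    """Normal fit of the retained log2(normalized RpK) values."""

    mean: float
    sd: float
    n_retained: int
    n_outliers_removed: int

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError("sd must be positive")
        if self.n_retained < 2:
            raise ValueError("need at least 2 retained values")

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "n_retained": self.n_retained,
                "n_outliers_removed": self.n_outliers_removed}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def remove_outliers(values: Sequence[float],
                    config: ClassifierConfig = ClassifierConfig()
                    ) -> tuple[np.ndarray, int]:
    """One-pass Tukey-fence trim; returns (retained values, n removed).

    Quartiles use linear interpolation.  With all values identical the IQR is
    zero and the fences collapse onto the value, so nothing is removed.
    Requires at least 4 finite values.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise ValueError("need at least 4 finite values for outlier removal")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - config.tukey_k * iqr, q3 + config.tukey_k * iqr
    retained = arr[(arr >= lo) & (arr <= hi)]
    return retained, int(arr.size - retained.size)


def fit_normal(retained: Sequence[float], n_outliers_removed: int = 0) -> FitResult:
    """Sample mean and SD (n-1 denominator) of the retained values.

    Fewer than 2 values or zero variance raise :class:`ValueError`.
    """
    arr = np.asarray(retained, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to fit")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: cannot fit a normal distribution")
    return FitResult(mean=float(np.mean(arr)), sd=sd,
                     n_retained=int(arr.size), n_outliers_removed=n_outliers_removed)


def fit_replicate(values: Sequence[float],
                  config: ClassifierConfig = ClassifierConfig()) -> FitResult:
    """Convenience: outlier trim then normal fit."""
    retained, removed = remove_outliers(values, config)
    return fit_normal(retained, n_outliers_removed=removed)


def classify_gene(value: float, fit: FitResult,
                  config: ClassifierConfig = ClassifierConfig(),
                  zero_reads: bool = False) -> str:
    """Category for one gene.  ``zero_reads`` overrides the z-score entirely."""
    if zero_reads:
        return ESSENTIAL
    z = (value - fit.mean) / fit.sd
    if z < config.essential_z:
        return ESSENTIAL
    if z < config.defect_z:
        return GROWTH_DEFECT
    if z <= config.advantage_z:
        return NON_ESSENTIAL
    return GROWTH_ADVANTAGE


def classify_replicate(counts: pd.DataFrame,
                       config: ClassifierConfig = ClassifierConfig()
                       ) -> tuple[pd.Series, pd.Series, FitResult]:
    """Classify every gene of one replicate's counts table.

    ``counts`` is the output of :func:`tnscreen.tabulation.normalize`.
    Returns (categories, z-scores, fit); z is NaN where no value exists.
    """
    excluded = counts["excluded"] != "none"
    values = counts.loc[~excluded & (counts["raw_reads"] > 0), "log2_norm_rpk"]
    fit = fit_replicate(values.to_numpy(), config)

    z = (counts["log2_norm_rpk"] - fit.mean) / fit.sd
    cats = pd.Series(NON_ESSENTIAL, index=counts.index, dtype=object)
    cats[z < config.essential_z] = ESSENTIAL
    cats[(z >= config.essential_z) & (z < config.defect_z)] = GROWTH_DEFECT
    cats[z > config.advantage_z] = GROWTH_ADVANTAGE
    cats[counts["raw_reads"] == 0] = ESSENTIAL
    cats[excluded] = EXCLUDED
    return cats, z, fit


def consensus(per_replicate: Sequence[str]) -> str:
    """Unanimous category, else Uncertain; order-invariant.  Empty input errors."""
    if len(per_replicate) == 0:
        raise ValueError("need at least one replicate call")
    first = per_replicate[0]
    return first if all(c == first for c in per_replicate[1:]) else UNCERTAIN


def consensus_calls(replicate_cats: Sequence[pd.Series],
                    replicate_z: Sequence[pd.Series] | None = None) -> pd.DataFrame:
    """Combine per-replicate categories into a calls table with a consensus column."""
    if not replicate_cats:
        raise ValueError("need at least one replicate")
    data = {}
    for i, cats in enumerate(replicate_cats, start=1):
        data[f"rep{i}_category"] = cats
        if replicate_z is not None:
            data[f"rep{i}_z"] = replicate_z[i - 1]
    df = pd.DataFrame(data)
    cat_cols = [c for c in df.columns if c.endswith("_category")]
    df["consensus"] = [consensus(tuple(row)) for row in df[cat_cols].to_numpy()]
    return df


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t")
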