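"""Differential-expression filtering of the weighted miRNA count table.

Implements the DESeq2 conventions for size-factor (median-of-ratios)
normalization, baseMean, and log2 fold change of group means, plus the
display filter |fold change| > 1.5 and baseMean > 5 used to select
differential miRNAs for heatmap/MA-plot presentation. No dispersion
estimation or hypothesis testing is performed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .quant import CountTable

GROUP_CONTROL = "control"
GROUP_COCULTURE = "coculture"

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_BASEMEAN_THRESHOLD = 5.0


@dataclass(frozen=True)
class DeResult:
    feature: str
    base_mean: float
    log2fc: float  # coculture vs control
    passes_filter: bool


def size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature with all-positive counts, the ratio of each sample's
    count to the feature's geometric mean across samples is formed; the
    per-sample median of those ratios is the size factor.
    """
    counts = table.counts
    if counts.shape[1] < 2:
        raise ValueError("size factors require >= 2 samples")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no feature has positive counts in every sample")
    positive = counts[all_positive]
    geomean = np.exp(np.log(positive).mean(axis=1))
    ratios = positive.div(geomean, axis=0)
    return ratios.median(axis=0).rename("size_factor")


def de_table(
    table: CountTable,
    groups: Mapping[str, str],
    pseudocount: float = 0.5,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    basemean_threshold: float = DEFAULT_BASEMEAN_THRESHOLD,
) -> list[DeResult]:
    """Normalize, compute baseMean/log2FC and apply the display filter.

    ``groups`` maps each sample to "control" or "coculture". baseMean is the
    grand mean of size-factor-normalized counts over all samples. log2FC is
    log2((mean_coculture + pseudocount) / (mean_control + pseudocount)).
    A feature passes when |log2FC| > log2(fc_threshold) and
    baseMean > basemean_threshold.
    """
    unknown = {g for g in groups.values()} - {GROUP_CONTROL, GROUP_COCULTURE}
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    missing = [s for s in table.counts.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    control = [s for s in table.counts.columns if groups[s] == GROUP_CONTROL]
    coculture = [s for s in table.counts.columns if groups[s] == GROUP_COCULTURE]
    if not control or not coculture:
        raise ValueError("both groups must be non-empty")

    normalized = table.counts / size_factors(table)
    base_mean = normalized.mean(axis=1)
    mean_control = normalized[control].mean(axis=1)
    mean_coculture = normalized[coculture].mean(axis=1)
    log2fc = np.log2((mean_coculture + pseudocount) / (mean_control + pseudocount))
    log2_cut = math.log2(fc_threshold)
    passes = (log2fc.abs() > log2_cut) & (base_mean > basemean_threshold)
    return [
        DeResult(feature=f, base_mean=float(base_mean[f]),
                 log2fc=float(log2fc[f]), passes_filter=bool(passes[f]))
        for f in table.counts.index
    ]


def ma_data(results: list[DeResult]) -> pd.DataFrame:
    """MA-plot coordinates: A = log2 baseMean, M = log2FC.

    Features with zero baseMean are dropped (outside the domain of log2).
    """
    rows = [
        {"feature": r.feature, "A": math.log2(r.base_mean), "M": r.log2fc}
        for r in results
        if r.base_mean > 0
    ]
    return pd.DataFrame(rows, columns=["feature", "A", "M"])


def de_results_frame(results: list[DeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature": r.feature, "base_mean": r.base_mean,
             "log2fc": r.log2fc, "passes_filter": r.passes_filter}
            for r in results
        ],
        columns=["feature", "base_mean", "log2fc", "passes_filter"],
    )
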